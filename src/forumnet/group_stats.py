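"""Rank-based group comparison: Kruskal-Wallis, Dunn pairwise, Bonferroni.

The comparison machinery is implemented here from first principles, with
midranks for ties throughout.

Kruskal-Wallis omnibus statistic over k groups pooled to N observations
with group mean ranks Rbar_i:

    H = [ 12 / (N (N+1)) * sum_i n_i Rbar_i^2  -  3 (N+1) ] / C
    C = 1 - sum_t (t^3 - t) / (N^3 - N)          (tie groups of size t)

with the upper-tail chi-square reference at k-1 degrees of freedom.  The
degenerate all-values-identical case (C = 0) is an error, not a 0/0.

Dunn's pairwise follow-up keeps the joint ranking over all groups:

    z_ij = (Rbar_i - Rbar_j) / sqrt( S * (1/n_i + 1/n_j) )
    S    = N (N+1) / 12  -  sum_t (t^3 - t) / (12 (N-1))

with two-sided normal p-values and Bonferroni control over the family:
p_adj = min(1, m * p_raw).  Because these tests compare rank means, the
*sign* of the mean-rank difference is the interpretable direction of an
effect; its magnitude is on the rank scale, not the data scale.

A "separate pairwise Kruskal-Wallis" variant (each pair re-ranked on its
own) is available for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .dyad_metrics import Dyad, DyadGroup, IntimacyLevel
from .forum_io import ForumCorpus, MemberGroup, member_group
from .network_builder import build_network, member_breadth, member_contribution

__all__ = [
    "RankTestResult",
    "PairwiseComparison",
    "ComparisonTable",
    "DegenerateDataError",
    "kruskal_wallis",
    "dunn_pairwise",
    "pairwise_kw",
    "bonferroni_adjust",
    "survivor_percentage",
    "corpus_survivor_percentage",
    "build_forum_comparison",
    "build_dyad_comparison",
]


class DegenerateDataError(ValueError):
    """All pooled observations identical: rank tests are undefined."""


@dataclasses.dataclass(frozen=True)
class RankTestResult:
    H: float
    df: int
    p: float
    mean_ranks: tuple[float, ...]
    group_sizes: tuple[int, ...]
    tie_correction: float
    n_total: int


@dataclasses.dataclass(frozen=True)
class PairwiseComparison:
    group_i: str
    group_j: str
    diff: float          # mean-rank difference Rbar_i - Rbar_j (signed)
    z: float
    p_raw: float
    p_adjusted: float
    n_i: int
    n_j: int


def _pool(samples: Sequence[Sequence[float]]):
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    return arrays, pooled


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t ** 3 - t))


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal-Wallis omnibus test with midranks and tie correction."""
    arrays, pooled = _pool(samples)
    n = pooled.size
    ranks = rankdata(pooled)
    sizes = [a.size for a in arrays]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(float(ranks[start:start + sz].mean()))
        start += sz
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (n ** 3 - n) if n > 1 else 0.0
    if correction <= 0.0:
        raise DegenerateDataError("all pooled observations are identical")
    h_raw = (
        12.0 / (n * (n + 1.0))
        * sum(sz * r * r for sz, r in zip(sizes, mean_ranks))
        - 3.0 * (n + 1.0)
    )
    h = h_raw / correction
    df = len(arrays) - 1
    p = float(chi2.sf(h, df))
    return RankTestResult(
        H=float(h), df=df, p=p,
        mean_ranks=tuple(mean_ranks), group_sizes=tuple(sizes),
        tie_correction=float(correction), n_total=int(n),
    )


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """min(1, m * p_raw); never decreases a p-value."""
    if not (0.0 <= p_raw <= 1.0):
        raise ValueError(f"p_raw must lie in [0, 1], got {p_raw}")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return min(1.0, m * p_raw)


def _resolve_family(
    labels: Sequence[str], family
) -> list[tuple[int, int]]:
    index = {lab: i for i, lab in enumerate(labels)}
    if family == "all" or family is None:
        return [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    return [(index[a], index[b]) for a, b in family]


def dunn_pairwise(
    samples: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    family="all",
) -> list[PairwiseComparison]:
    """Dunn's joint-rank pairwise z comparisons with Bonferroni control."""
    arrays, pooled = _pool(samples)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    n = pooled.size
    ranks = rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        sizes.append(a.size)
        mean_ranks.append(float(ranks[start:start + a.size].mean()))
        start += a.size
    tie = _tie_term(pooled)
    variance = n * (n + 1.0) / 12.0 - tie / (12.0 * (n - 1.0))
    pairs = _resolve_family(labels, family)
    m = len(pairs)
    out: list[PairwiseComparison] = []
    for i, j in pairs:
        diff = mean_ranks[i] - mean_ranks[j]
        se = math.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = diff / se if se > 0 else 0.0
        p_raw = float(2.0 * norm.sf(abs(z)))
        out.append(
            PairwiseComparison(
                group_i=labels[i], group_j=labels[j], diff=float(diff),
                z=float(z), p_raw=p_raw,
                p_adjusted=bonferroni_adjust(p_raw, m),
                n_i=int(sizes[i]), n_j=int(sizes[j]),
            )
        )
    return out


def pairwise_kw(
    samples: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    family="all",
) -> list[PairwiseComparison]:
    """Separate two-group Kruskal-Wallis per pair (each pair re-ranked).

    Sensitivity-analysis alternative to :func:`dunn_pairwise`; the signed
    diff is the mean-rank difference within the pair's own joint ranking,
    z is the signed square root of H.
    """
    arrays, _ = _pool(samples)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    pairs = _resolve_family(labels, family)
    m = len(pairs)
    out: list[PairwiseComparison] = []
    for i, j in pairs:
        try:
            res = kruskal_wallis([arrays[i], arrays[j]])
        except DegenerateDataError:
            diff, z, p_raw = 0.0, 0.0, 1.0
            sizes = (arrays[i].size, arrays[j].size)
        else:
            diff = res.mean_ranks[0] - res.mean_ranks[1]
            z = math.copysign(math.sqrt(res.H), diff) if res.H > 0 else 0.0
            p_raw = res.p
            sizes = res.group_sizes
        out.append(
            PairwiseComparison(
                group_i=labels[i], group_j=labels[j], diff=float(diff),
                z=float(z), p_raw=float(p_raw),
                p_adjusted=bonferroni_adjust(p_raw, m),
                n_i=int(sizes[0]), n_j=int(sizes[1]),
            )
        )
    return out


# -- survivor share ------------------------------------------------------------


def survivor_percentage(n_patients: int, n_survivors: int) -> float:
    """Share of the diagnosed (patients + survivors) registered as survivor,
    in percent; unrounded (round to one decimal for reporting)."""
    diagnosed = n_patients + n_survivors
    if diagnosed == 0:
        raise ValueError("survivor percentage undefined: no diagnosed members")
    return 100.0 * n_survivors / diagnosed


def corpus_survivor_percentage(corpus: ForumCorpus, forum: str) -> float:
    members = corpus.members_of(forum)
    n_pat = sum(m.user_type.value == "patient" for m in members)
    n_sur = sum(m.user_type.value == "survivor" for m in members)
    return survivor_percentage(n_pat, n_sur)


# -- assembled comparison tables -----------------------------------------------


@dataclasses.dataclass
class ComparisonTable:
    """Omnibus result plus pairwise rows, with run metadata."""

    metric: str
    omnibus: RankTestResult | None
    pairwise: list[PairwiseComparison]
    metadata: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison": f"{c.group_i} vs {c.group_j}",
                    "metric": self.metric,
                    "diff": c.diff,
                    "z": c.z,
                    "p_raw": c.p_raw,
                    "p_bonferroni": c.p_adjusted,
                    "n_i": c.n_i,
                    "n_j": c.n_j,
                }
                for c in self.pairwise
            ]
        )


def build_forum_comparison(
    corpus: ForumCorpus,
    forums: Sequence[str],
    metric: str = "breadth",
    population: MemberGroup = MemberGroup.PATIENT_SURVIVOR,
    *,
    attribution_mode: str = "to_creator",
    pairwise: str = "dunn",
    count_opening_posts: bool = True,
) -> ComparisonTable:
    """Cross-forum comparison of a per-member metric within one population.

    For each forum, the metric (``breadth``: distinct correspondents;
    ``contribution``: messages composed) is computed for every network
    member of the requested population; forums are then the groups of a
    Kruskal-Wallis omnibus test followed by all pairwise comparisons.
    Forums with no member of the population are dropped with a warning.
    """
    if metric not in ("breadth", "contribution"):
        raise ValueError(f"unknown metric {metric!r}")
    samples, labels = [], []
    for forum in forums:
        network = build_network(corpus, forum, attribution_mode)
        ids = [
            m for m in network.nodes()
            if member_group(network.user_type(m)) is population
        ]
        if not ids:
            warnings.warn(f"forum {forum!r}: no {population.value} members; dropped")
            continue
        if metric == "breadth":
            values = [member_breadth(network, m) for m in ids]
        else:
            values = [
                member_contribution(
                    corpus, forum, m, count_opening_posts=count_opening_posts
                )
                for m in ids
            ]
        samples.append(values)
        labels.append(forum)
    if len(samples) < 2:
        raise ValueError("need at least two forums with members of the population")
    omnibus = kruskal_wallis(samples)
    runner = dunn_pairwise if pairwise == "dunn" else pairwise_kw
    rows = runner(samples, labels)
    return ComparisonTable(
        metric=metric,
        omnibus=omnibus,
        pairwise=rows,
        metadata={
            "population": population.value,
            "attribution_mode": attribution_mode,
            "pairwise_procedure": pairwise,
            "count_opening_posts": count_opening_posts,
            "forums": list(labels),
        },
    )


_DYAD_OUTCOMES = ("duration", "intimate_indicator", "highly_intimate_indicator")


def _dyad_outcome(d: Dyad, outcome: str) -> float:
    if outcome == "duration":
        return float(d.duration_days)
    if outcome == "intimate_indicator":
        return float(d.level >= IntimacyLevel.SLIGHTLY_INTIMATE)
    return float(d.level == IntimacyLevel.HIGHLY_INTIMATE)


def build_dyad_comparison(
    dyads_by_forum: Mapping[str, Sequence[Dyad]],
    outcome: str = "duration",
    *,
    duration_population: str = "all",
) -> pd.DataFrame:
    """Within-forum patient-dyad vs other-dyad comparison of one outcome.

    Per forum, a two-group rank test (Kruskal-Wallis with k=2) of the
    outcome across dyad groups, reporting the signed mean-rank difference
    (patient dyads minus other dyads) and its p-value.  Indicator outcomes
    are 0/1 encodings of level >= slightly intimate / level == highly
    intimate.  ``duration_population`` restricts the duration comparison
    to ``"intimate"`` dyads (level >= slightly intimate) or keeps
    ``"all"`` dyads.  A forum where either group is empty, or where the
    outcome is constant, yields an NA row (diff and p missing).
    """
    if outcome not in _DYAD_OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; use one of {_DYAD_OUTCOMES}")
    if duration_population not in ("all", "intimate"):
        raise ValueError("duration_population must be 'all' or 'intimate'")
    rows = []
    for forum, dyads in dyads_by_forum.items():
        pool = [d for d in dyads if d.group is not None and d.level is not None]
        if outcome == "duration" and duration_population == "intimate":
            pool = [d for d in pool if d.level >= IntimacyLevel.SLIGHTLY_INTIMATE]
        pat = [_dyad_outcome(d, outcome) for d in pool if d.group is DyadGroup.PATIENT_DYAD]
        oth = [_dyad_outcome(d, outcome) for d in pool if d.group is DyadGroup.OTHER_DYAD]
        row = {
            "forum": forum,
            "outcome": outcome,
            "n_patient_dyads": len(pat),
            "n_other_dyads": len(oth),
            "diff": np.nan,
            "z": np.nan,
            "p": np.nan,
        }
        if pat and oth:
            try:
                res = kruskal_wallis([pat, oth])
            except DegenerateDataError:
                pass  # constant outcome in this forum -> NA row
            else:
                diff = res.mean_ranks[0] - res.mean_ranks[1]
                row["diff"] = diff
                row["z"] = math.copysign(math.sqrt(res.H), diff) if res.H > 0 else 0.0
                row["p"] = res.p
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["forum", "outcome", "n_patient_dyads", "n_other_dyads", "diff", "z", "p"],
    )


def format_p(p: float, floor: float = 1e-4) -> str:
    """Human-readable p: values below the floor render as '<0.0001'."""
    if np.isnan(p):
        return "NA"
    if p < floor:
        return f"<{floor:.4f}".rstrip("0").rstrip(".") if floor != 1e-4 else "<0.0001"
    return f"{p:.4f}"
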