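"""Dyads: unordered member pairs, intimacy thresholds, duration, grouping.

The unit of analysis for relationship-level comparisons is the *dyad*: an
unordered pair of members joined by at least one attributed message.  A
dyad's tie strength is the symmetric message count (both arc directions
summed); its intimacy class is assigned by comparing that count to
mean + sigma and mean + 2*sigma of the dyad counts in scope:

    acquaintance        count <  mu + sigma
    slightly intimate   mu + sigma <= count < mu + 2*sigma
    highly intimate     count >= mu + 2*sigma

Counts exactly at a threshold are assigned upward so the three classes
are exhaustive.  Relationship duration is the whole-day difference
between the dyad's first and last attributed message.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import json
import math
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .forum_io import Member, MemberGroup, UserType, member_group
from .network_builder import CommNetwork

__all__ = [
    "IntimacyLevel",
    "DyadGroup",
    "Dyad",
    "IntimacyThresholds",
    "compute_dyads",
    "compute_thresholds",
    "classify_dyad",
    "classify_dyads",
    "assign_dyad_group",
    "dyads_to_frame",
    "write_dyad_table",
]


class IntimacyLevel(enum.IntEnum):
    """Ordinal tie-strength class; order is meaningful."""

    ACQUAINTANCE = 0
    SLIGHTLY_INTIMATE = 1
    HIGHLY_INTIMATE = 2

    @property
    def label(self) -> str:
        return self.name.lower()


class DyadGroup(str, enum.Enum):
    PATIENT_DYAD = "patient_dyad"   # both members patient or survivor
    OTHER_DYAD = "other_dyad"


@dataclasses.dataclass
class Dyad:
    forum: str
    member_a: str                       # lexicographically smaller id
    member_b: str
    count: int                          # messages in both directions
    first_date: dt.date
    last_date: dt.date
    level: IntimacyLevel | None = None
    group: DyadGroup | None = None

    @property
    def duration_days(self) -> int:
        return (self.last_date - self.first_date).days


@dataclasses.dataclass(frozen=True)
class IntimacyThresholds:
    """mu/sigma of in-scope dyad counts and the derived cut points."""

    mu: float
    sigma: float
    t1: float                           # mu + sigma
    t2: float                           # mu + 2*sigma
    scope: str = "per_forum"
    sd_convention: str = "population"
    n_dyads: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_dyads(network: CommNetwork, corpus=None) -> list[Dyad]:
    """Collapse a directed network to unordered dyads.

    Each pair with at least one arc in either direction yields one dyad;
    its count sums both directions, its first/last dates come from the
    attributed message timestamps.  If ``corpus`` is given, network nodes
    are checked against the corpus roster.
    """
    if corpus is not None:
        roster = set(corpus.member_index())
        stray = set(network.graph.nodes) - roster
        if stray:
            raise ValueError(
                f"network/corpus mismatch: nodes not in corpus roster: {sorted(stray)[:5]}"
            )
    agg: dict[tuple[str, str], list] = {}
    for u, v, d in network.graph.edges(data=True):
        key = (u, v) if u < v else (v, u)
        entry = agg.setdefault(key, [0, None, None])
        entry[0] += d["weight"]
        lo, hi = d["times"][0], d["times"][-1]
        entry[1] = lo if entry[1] is None else min(entry[1], lo)
        entry[2] = hi if entry[2] is None else max(entry[2], hi)
    dyads = [
        Dyad(
            forum=network.forum,
            member_a=a,
            member_b=b,
            count=cnt,
            first_date=first.date(),
            last_date=last.date(),
        )
        for (a, b), (cnt, first, last) in sorted(agg.items())
    ]
    return dyads


def compute_thresholds(
    dyads: Sequence[Dyad] | Sequence[int],
    scope: str = "per_forum",
    *,
    sd_convention: str = "population",
) -> IntimacyThresholds:
    """Mean/SD of dyad counts in scope and the two intimacy cut points.

    The SD is the population SD (divide by n) by default;
    ``sd_convention="sample"`` divides by n-1.  An empty scope leaves the
    thresholds undefined and raises ``ValueError``.
    """
    counts = np.asarray(
        [d.count if isinstance(d, Dyad) else int(d) for d in dyads], dtype=float
    )
    if counts.size == 0:
        raise ValueError("intimacy thresholds are undefined for an empty dyad set")
    if sd_convention == "population":
        ddof = 0
    elif sd_convention == "sample":
        ddof = 1
    else:
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    mu = float(counts.mean())
    sigma = float(counts.std(ddof=ddof)) if counts.size > ddof else 0.0
    return IntimacyThresholds(
        mu=mu, sigma=sigma, t1=mu + sigma, t2=mu + 2 * sigma,
        scope=scope, sd_convention=sd_convention, n_dyads=int(counts.size),
    )


def classify_dyad(count: int, thresholds: IntimacyThresholds) -> IntimacyLevel:
    """Three-way threshold rule; ties at a cut point are assigned upward."""
    if count >= thresholds.t2:
        return IntimacyLevel.HIGHLY_INTIMATE
    if count >= thresholds.t1:
        return IntimacyLevel.SLIGHTLY_INTIMATE
    return IntimacyLevel.ACQUAINTANCE


def assign_dyad_group(
    member_a: Member | UserType,
    member_b: Member | UserType,
    *,
    strict: bool = False,
) -> DyadGroup | None:
    """patient_dyad iff both members are patient/survivor.

    Default mode puts every other pair (mixed included) in ``other_dyad``;
    strict mode restricts ``other_dyad`` to both-non-patient pairs and
    returns ``None`` for mixed dyads (caller excludes them).
    """
    ga = member_group(member_a.user_type if isinstance(member_a, Member) else member_a)
    gb = member_group(member_b.user_type if isinstance(member_b, Member) else member_b)
    both_patient = ga is MemberGroup.PATIENT_SURVIVOR and gb is MemberGroup.PATIENT_SURVIVOR
    if both_patient:
        return DyadGroup.PATIENT_DYAD
    if strict and (ga is MemberGroup.PATIENT_SURVIVOR or gb is MemberGroup.PATIENT_SURVIVOR):
        return None
    return DyadGroup.OTHER_DYAD


def classify_dyads(
    dyads: Iterable[Dyad],
    network: CommNetwork,
    *,
    scope: str = "per_forum",
    sd_convention: str = "population",
    strict_groups: bool = False,
    thresholds: IntimacyThresholds | None = None,
) -> tuple[list[Dyad], IntimacyThresholds]:
    """Assign level and group to every dyad of one forum.

    With ``scope="per_forum"`` (default) thresholds come from this forum's
    own dyad counts; pass precomputed ``thresholds`` for global scope.
    Dyads whose group is excluded in strict mode keep ``group=None``.
    """
    dyads = list(dyads)
    if thresholds is None:
        thresholds = compute_thresholds(dyads, scope, sd_convention=sd_convention)
    for d in dyads:
        d.level = classify_dyad(d.count, thresholds)
        d.group = assign_dyad_group(
            network.user_type(d.member_a), network.user_type(d.member_b),
            strict=strict_groups,
        )
    return dyads, thresholds


def dyads_to_frame(dyads: Sequence[Dyad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "forum": d.forum,
                "member_a": d.member_a,
                "member_b": d.member_b,
                "count": d.count,
                "first_date": d.first_date.isoformat(),
                "last_date": d.last_date.isoformat(),
                "duration_days": d.duration_days,
                "level": d.level.label if d.level is not None else "",
                "group": d.group.value if d.group is not None else "",
            }
            for d in dyads
        ],
        columns=[
            "forum", "member_a", "member_b", "count", "first_date",
            "last_date", "duration_days", "level", "group",
        ],
    )


def write_dyad_table(
    dyads: Sequence[Dyad],
    thresholds: IntimacyThresholds,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Emit the dyad CSV plus a JSON sidecar recording thresholds/flags."""
    path = Path(path)
    dyads_to_frame(dyads).to_csv(path, index=False, lineterminator="\n")
    if metadata_path is None:
        metadata_path = path.with_suffix(".meta.json")
    Path(metadata_path).write_text(
        json.dumps(thresholds.to_dict(), indent=2, sort_keys=True) + "\n"
    )
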