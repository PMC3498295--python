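"""End-to-end orchestration: corpus -> networks -> dyads -> comparisons.

``run_study`` wires the stages together under one RunConfig and writes a
reproducible result bundle: rerunning with the same config and seed
produces byte-identical CSV/JSON outputs.  Every under-specified
analytical choice (attribution rule, SD convention, threshold scope, tie
rule, pairwise procedure, duration population) is recorded in the run
metadata so sensitivity claims are auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import __version__
from .dyad_metrics import classify_dyads, compute_dyads, write_dyad_table
from .forum_io import (
    ForumCorpus,
    MemberGroup,
    apply_study_window,
    read_corpus,
    summarize_corpus,
    write_corpus,
)
from .group_stats import build_dyad_comparison, build_forum_comparison
from .network_builder import build_network, export_pajek
from .synthetic_forum import DEFAULT_WINDOW, StyleConfig, generate_forums
from .viz_layout import intimate_subgraph, kamada_kawai_layout, render_network

__all__ = ["RunConfig", "run_study"]

log = logging.getLogger("forumnet")


@dataclasses.dataclass
class RunConfig:
    """Everything a study run depends on; every flag lands in metadata."""

    out_dir: str | Path
    corpus_dir: str | Path | None = None          # ingest ...
    style_configs: list[StyleConfig] | None = None  # ... or simulate
    seed: int = 0
    thread_cutoff: object = DEFAULT_WINDOW[1]
    post_cutoff: object = DEFAULT_WINDOW[2]
    attribution_mode: str = "to_creator"
    threshold_scope: str = "per_forum"
    sd_convention: str = "population"
    # Table-4-style comparisons use the source study's comparison group:
    # both members non-patient; mixed dyads are excluded.  Set False to
    # pool mixed dyads into other_dyad instead.
    strict_dyad_groups: bool = True
    pairwise_procedure: str = "dunn"
    duration_population: str = "all"
    count_opening_posts: bool = True
    comparison_population: MemberGroup = MemberGroup.PATIENT_SURVIVOR
    make_figures: bool = False

    def validate(self) -> None:
        if (self.corpus_dir is None) == (self.style_configs is None):
            raise ValueError("provide exactly one of corpus_dir or style_configs")


def _load_corpus(config: RunConfig) -> ForumCorpus:
    if config.corpus_dir is not None:
        log.info("reading corpus from %s", config.corpus_dir)
        return read_corpus(config.corpus_dir)
    log.info("simulating %d forum(s), seed %d", len(config.style_configs), config.seed)
    return generate_forums(config.style_configs, config.seed)


def run_study(config: RunConfig) -> dict:
    """Run the full analysis; returns a manifest of what was written."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    corpus = _load_corpus(config)
    if config.style_configs is not None:
        write_corpus(corpus, out / "corpus")
    corpus = apply_study_window(corpus, config.thread_cutoff, config.post_cutoff)

    summary = summarize_corpus(corpus)
    summary.to_csv(out / "summary.csv", lineterminator="\n")

    forums = corpus.forums()
    dyads_by_forum = {}
    thresholds_by_forum = {}
    networks = {}
    for forum in forums:
        network = build_network(corpus, forum, config.attribution_mode)
        networks[forum] = network
        export_pajek(network, out / f"{forum}.net")
        dyads = compute_dyads(network, corpus)
        if not dyads:
            log.warning("forum %s: no dyads; skipped", forum)
            continue
        dyads, thresholds = classify_dyads(
            dyads, network,
            scope=config.threshold_scope,
            sd_convention=config.sd_convention,
            strict_groups=config.strict_dyad_groups,
        )
        dyads_by_forum[forum] = dyads
        thresholds_by_forum[forum] = thresholds.to_dict()
        write_dyad_table(dyads, thresholds, out / f"{forum}_dyads.csv")

    comparisons = {}
    if len(forums) >= 2:
        for metric in ("breadth", "contribution"):
            try:
                table = build_forum_comparison(
                    corpus, forums, metric,
                    population=config.comparison_population,
                    attribution_mode=config.attribution_mode,
                    pairwise=config.pairwise_procedure,
                    count_opening_posts=config.count_opening_posts,
                )
            except ValueError as exc:
                log.warning("forum comparison (%s) skipped: %s", metric, exc)
                continue
            path = out / f"forum_comparison_{metric}.csv"
            table.frame().to_csv(path, index=False, lineterminator="\n")
            comparisons[f"forum_{metric}"] = str(path.name)

    for outcome in ("duration", "intimate_indicator", "highly_intimate_indicator"):
        if not dyads_by_forum:
            break
        frame = build_dyad_comparison(
            dyads_by_forum, outcome,
            duration_population=config.duration_population,
        )
        path = out / f"dyad_comparison_{outcome}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        comparisons[f"dyad_{outcome}"] = str(path.name)

    figures = []
    if config.make_figures:
        for forum, network in networks.items():
            dyads = dyads_by_forum.get(forum, [])
            sub = intimate_subgraph(network, dyads)
            fig_path = out / f"{forum}_intimate.png"
            if sub.nodes():
                layout = kamada_kawai_layout(sub, seed=config.seed)
                render_network(sub, layout, out_path=fig_path)
            else:
                from .viz_layout import LayoutResult
                render_network(sub, LayoutResult({}, 0.0, 0), out_path=fig_path)
            figures.append(fig_path.name)

    metadata = {
        "forumnet_version": __version__,
        "seed": config.seed,
        "source": "simulated" if config.style_configs is not None else str(config.corpus_dir),
        "style_configs": (
            [c.to_dict() for c in config.style_configs]
            if config.style_configs is not None else None
        ),
        "window": {
            "thread_cutoff": str(config.thread_cutoff),
            "post_cutoff": str(config.post_cutoff),
        },
        "attribution_mode": config.attribution_mode,
        "threshold_scope": config.threshold_scope,
        "sd_convention": config.sd_convention,
        "tie_rule": "at-threshold counts assigned upward",
        "strict_dyad_groups": config.strict_dyad_groups,
        "pairwise_procedure": config.pairwise_procedure,
        "duration_population": config.duration_population,
        "count_opening_posts": config.count_opening_posts,
        "comparison_population": config.comparison_population.value,
        "thresholds": thresholds_by_forum,
        "outputs": {
            "summary": "summary.csv",
            "comparisons": comparisons,
            "figures": figures,
        },
    }
    (out / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n"
    )
    return metadata
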