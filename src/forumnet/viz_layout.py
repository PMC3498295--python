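"""Intimate-subnetwork extraction, stress layout, and rendering.

Visualisation follows the study convention for these forums: only dyads
at intimacy level slightly-intimate or above are drawn; node glyph and
colour encode the user type (red squares patients, pink squares
survivors, blue circles caregivers, light-yellow triangles unknown,
light-green triangles doctors); arc line width grows with message count.

The layout is a Kamada-Kawai-style stress minimisation: with graph
distances d_ij (unweighted shortest paths) and weights k_ij = 1/d_ij^2,
positions minimise

    stress(X) = sum_{i<j} k_ij (||x_i - x_j|| - d_ij)^2

by majorization (SMACOF with these weights), which makes the stress
nonincreasing at every iteration.  Connected components are laid out
independently and packed on a grid by decreasing size.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx
import numpy as np

from .dyad_metrics import Dyad, IntimacyLevel
from .forum_io import UserType
from .network_builder import CommNetwork

__all__ = [
    "LayoutResult",
    "intimate_subgraph",
    "kamada_kawai_layout",
    "render_network",
    "DEFAULT_STYLE_MAP",
]

#: user type -> (matplotlib marker, colour); the study's figure legend.
DEFAULT_STYLE_MAP: dict[str, tuple[str, str]] = {
    UserType.PATIENT.value: ("s", "red"),
    UserType.SURVIVOR.value: ("s", "pink"),
    UserType.CAREGIVER.value: ("o", "royalblue"),
    UserType.UNKNOWN.value: ("^", "khaki"),
    UserType.DOCTOR.value: ("^", "lightgreen"),
    UserType.NURSE.value: ("D", "lightgray"),
    UserType.STUDENT.value: ("D", "silver"),
    UserType.RESEARCHER.value: ("D", "gray"),
}


@dataclasses.dataclass
class LayoutResult:
    positions: dict[str, tuple[float, float]]
    stress: float
    iterations: int
    initial_stress: float = 0.0


def intimate_subgraph(network: CommNetwork, dyads: Iterable[Dyad]) -> CommNetwork:
    """Restrict a network to members of at least slightly intimate dyads.

    Keeps every node incident to an intimate dyad and all arcs between the
    kept nodes; may be empty.
    """
    keep: set[str] = set()
    for d in dyads:
        if d.level is not None and d.level >= IntimacyLevel.SLIGHTLY_INTIMATE:
            keep.add(d.member_a)
            keep.add(d.member_b)
    sub = network.graph.subgraph(keep).copy()
    return CommNetwork(forum=network.forum, graph=sub,
                       attribution_mode=network.attribution_mode)


def kamada_kawai_layout(
    network: CommNetwork,
    max_iterations: int = 500,
    tolerance: float = 1e-6,
    seed: int = 0,
) -> LayoutResult:
    """Stress-majorization layout of a communication network.

    Raises ``ValueError`` on an empty network.  Components are laid out
    independently, then packed on a grid by decreasing node count with
    spacing 1.2x the larger component diameter.
    """
    nodes = network.nodes()
    if not nodes:
        raise ValueError("cannot lay out an empty network")
    rng = np.random.default_rng(seed)
    und = network.graph.to_undirected(as_view=False)
    components = sorted(
        (sorted(c) for c in nx.connected_components(und)),
        key=lambda c: (-len(c), c[0]),
    )

    placed: dict[str, np.ndarray] = {}
    total_stress = 0.0
    total_initial = 0.0
    total_iters = 0
    extents: list[tuple[list[str], np.ndarray]] = []
    for comp in components:
        pos, s, s0, iters = _smacof(und, comp, rng, max_iterations, tolerance)
        total_stress += s
        total_initial += s0
        total_iters = max(total_iters, iters)
        extents.append((comp, pos))

    # grid packing, biggest component first
    cell = 0.0
    for comp, pos in extents:
        span = pos.max(axis=0) - pos.min(axis=0) if len(comp) > 1 else np.zeros(2)
        cell = max(cell, float(span.max()))
    cell = 1.2 * max(cell, 1.0)
    cols = max(1, math.ceil(math.sqrt(len(extents))))
    for k, (comp, pos) in enumerate(extents):
        center = pos.mean(axis=0)
        offset = np.array([(k % cols) * cell, -(k // cols) * cell])
        for node, p in zip(comp, pos):
            placed[node] = p - center + offset

    return LayoutResult(
        positions={m: (float(p[0]), float(p[1])) for m, p in placed.items()},
        stress=total_stress,
        iterations=total_iters,
        initial_stress=total_initial,
    )


def _smacof(
    graph: nx.Graph,
    nodes: list[str],
    rng: np.random.Generator,
    max_iterations: int,
    tolerance: float,
) -> tuple[np.ndarray, float, float, int]:
    """Majorize the weighted stress of one connected component."""
    n = len(nodes)
    if n == 1:
        return np.zeros((1, 2)), 0.0, 0.0, 0
    lengths = dict(nx.all_pairs_shortest_path_length(graph.subgraph(nodes)))
    d = np.zeros((n, n))
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if i != j:
                d[i, j] = lengths[u][v]
    w = np.zeros_like(d)
    nz = d > 0
    w[nz] = 1.0 / d[nz] ** 2

    theta = 2 * np.pi * np.arange(n) / n + rng.uniform(0, 2 * np.pi)
    radius = max(float(d.max()) / 2.0, 1.0)
    x = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    x += rng.normal(scale=1e-3 * radius, size=x.shape)

    iu = np.triu_indices(n, 1)

    def stress(pos: np.ndarray) -> float:
        diff = pos[:, None, :] - pos[None, :, :]
        e = np.sqrt((diff ** 2).sum(axis=2))
        return float((w[iu] * (e[iu] - d[iu]) ** 2).sum())

    # V matrix of the majorization (pseudo-inverted once per component)
    v = -w.copy()
    np.fill_diagonal(v, w.sum(axis=1))
    v_pinv = np.linalg.pinv(v)

    s_init = stress(x)
    s_prev = s_init
    iters = 0
    for iters in range(1, max_iterations + 1):
        diff = x[:, None, :] - x[None, :, :]
        e = np.sqrt((diff ** 2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(e > 0, d / np.where(e > 0, e, 1.0), 0.0)
        b = -w * ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = v_pinv @ (b @ x)
        s = stress(x)
        if s_prev - s <= tolerance * max(s_prev, 1e-12):
            s_prev = min(s, s_prev)
            break
        s_prev = s
    return x, s_prev, s_init, iters


def render_network(
    network: CommNetwork,
    layout: LayoutResult,
    style_map: Mapping[str, tuple[str, str]] | None = None,
    out_path: str | Path = "network.png",
):
    """Draw the network with the study's glyph legend; returns the figure.

    Arc line width is strictly increasing in message count
    (0.5 + 0.6*sqrt(weight)).  An empty network still writes a blank
    canvas.  Raises ``KeyError`` if a node has no layout position.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    style = dict(DEFAULT_STYLE_MAP)
    if style_map:
        style.update({k: tuple(v) for k, v in style_map.items()})

    missing = [m for m in network.nodes() if m not in layout.positions]
    if missing:
        raise KeyError(f"nodes missing from layout: {missing[:5]}")

    fig, ax = plt.subplots(figsize=(8, 8))
    for u, v, weight in network.arcs():
        xu, yu = layout.positions[u]
        xv, yv = layout.positions[v]
        ax.annotate(
            "", xy=(xv, yv), xytext=(xu, yu),
            arrowprops=dict(
                arrowstyle="-|>", lw=arc_width(weight), color="0.45",
                shrinkA=6, shrinkB=6,
            ),
        )
    by_type: dict[str, list[str]] = {}
    for m in network.nodes():
        by_type.setdefault(network.user_type(m).value, []).append(m)
    for utype, ids in sorted(by_type.items()):
        marker, color = style[utype]
        xs = [layout.positions[m][0] for m in ids]
        ys = [layout.positions[m][1] for m in ids]
        ax.scatter(xs, ys, marker=marker, c=color, edgecolors="black",
                   s=80, zorder=3, label=utype)
    ax.set_title(f"{network.forum}: intimate communication sub-network")
    ax.set_axis_off()
    if by_type:
        ax.legend(loc="lower right", fontsize=8)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return fig


def arc_width(weight: int) -> float:
    """Line width for an arc of the given message count; strictly
    increasing in the count."""
    return 0.5 + 0.6 * math.sqrt(weight)
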