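"""Directed communication networks from thread-structured corpora.

Every forum becomes a directed weighted graph: nodes are members who wrote
at least one post (a member enters the network with their first post),
arcs carry the count of attributed messages from sender to recipient, and
arc timestamps are retained so dyad first/last-contact dates can be
derived downstream.

Who a reply "speaks to" is not observable in thread structure, so two
attribution rules are provided:

``to_creator`` (default)
    each reply is one message from its author to the thread creator —
    the conservative creator/responder reading;

``to_all_prior``
    each reply is one message from its author to every distinct earlier
    participant in the thread, the reading in which a reply addresses the
    whole conversation so far.

Both rules drop self-pairs (a member replying in their own thread creates
no arc) and neither credits opening posts with arcs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import networkx as nx

from .forum_io import ForumCorpus, UserType

__all__ = [
    "CommNetwork",
    "build_network",
    "member_breadth",
    "member_contribution",
    "export_pajek",
    "ATTRIBUTION_MODES",
]

ATTRIBUTION_MODES = ("to_creator", "to_all_prior")


@dataclasses.dataclass
class CommNetwork:
    """Per-forum directed weighted message-flow graph.

    ``graph`` is a :class:`networkx.DiGraph` whose nodes carry a
    ``user_type`` attribute and whose edges carry ``weight`` (message
    count) and ``times`` (sorted message timestamps).
    """

    forum: str
    graph: nx.DiGraph
    attribution_mode: str

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def user_type(self, member_id: str) -> UserType:
        return self.graph.nodes[member_id]["user_type"]

    def arcs(self) -> list[tuple[str, str, int]]:
        """(source, target, weight) triples, sorted."""
        return sorted(
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        )

    def total_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def _identify_opening(posts, thread):
    """Index of the opening post: first post by the creator at creation time."""
    for i, p in enumerate(posts):
        if p.author_id == thread.creator_id and p.posted_at == thread.created_at:
            return i
    return None


def build_network(
    corpus: ForumCorpus, forum: str, mode: str = "to_creator"
) -> CommNetwork:
    """Build the directed communication network of one forum.

    Raises ``ValueError`` for an unknown forum or attribution mode.
    """
    if mode not in ATTRIBUTION_MODES:
        raise ValueError(f"unknown attribution mode {mode!r}; use one of {ATTRIBUTION_MODES}")
    if forum not in corpus.forums():
        raise ValueError(f"forum {forum!r} not present in corpus")

    midx = corpus.member_index()
    graph = nx.DiGraph()

    def add_message(src: str, dst: str, ts: dt.datetime) -> None:
        if src == dst:
            return
        if graph.has_edge(src, dst):
            d = graph[src][dst]
            d["weight"] += 1
            d["times"].append(ts)
        else:
            graph.add_edge(src, dst, weight=1, times=[ts])

    posts_by_thread: dict[str, list] = {}
    for p in corpus.posts:
        posts_by_thread.setdefault(p.thread_id, []).append(p)

    for thread in corpus.threads_of(forum):
        posts = sorted(
            posts_by_thread.get(thread.thread_id, ()),
            key=lambda p: (p.posted_at, p.post_id),
        )
        for p in posts:  # node on first authored post
            graph.add_node(p.author_id, user_type=midx[p.author_id].user_type)
        opening = _identify_opening(posts, thread)
        if mode == "to_creator":
            for i, p in enumerate(posts):
                if i != opening:
                    add_message(p.author_id, thread.creator_id, p.posted_at)
        else:  # to_all_prior
            prior: list[str] = []
            for i, p in enumerate(posts):
                if i != opening:
                    for earlier in prior:
                        add_message(p.author_id, earlier, p.posted_at)
                if p.author_id not in prior:
                    prior.append(p.author_id)

    for _, _, d in graph.edges(data=True):
        d["times"].sort()
    return CommNetwork(forum=forum, graph=graph, attribution_mode=mode)


def member_breadth(network: CommNetwork, member_id: str) -> int:
    """Distinct correspondents of a member: unique neighbours over the
    union of in- and out-arcs."""
    if member_id not in network.graph:
        raise KeyError(f"member {member_id!r} is not a node of forum {network.forum!r}")
    g = network.graph
    return len((set(g.successors(member_id)) | set(g.predecessors(member_id))) - {member_id})


def member_contribution(
    corpus: ForumCorpus,
    forum: str,
    member_id: str,
    *,
    count_opening_posts: bool = True,
) -> int:
    """Messages composed by a member in one forum.

    With ``count_opening_posts`` (default) the thread-opening message
    counts toward its creator's contribution; disabling it counts replies
    only.
    """
    if member_id not in corpus.member_index():
        raise KeyError(f"unknown member {member_id!r}")
    tidx = {t.thread_id: t for t in corpus.threads_of(forum)}
    total = 0
    for p in corpus.posts:
        thread = tidx.get(p.thread_id)
        if thread is None or p.author_id != member_id:
            continue
        is_opening = p.author_id == thread.creator_id and p.posted_at == thread.created_at
        if is_opening and not count_opening_posts:
            continue
        total += 1
    return total


def export_pajek(network: CommNetwork, path: str | Path) -> None:
    """Write a Pajek ``.net`` file: ``*Vertices`` then ``*Arcs``.

    Vertices are numbered 1..N in member-id sort order; arcs are sorted by
    (source index, target index) and carry their message-count weight.
    ASCII, LF line endings, bit-exact across repeated exports.
    """
    nodes = network.nodes()
    index = {m: i + 1 for i, m in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    lines += [f'{i + 1} "{m}"' for i, m in enumerate(nodes)]
    lines.append("*Arcs")
    arcs = sorted((index[u], index[v], w) for u, v, w in network.arcs())
    lines += [f"{u} {v} {w}" for u, v, w in arcs]
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii", newline="\n")
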