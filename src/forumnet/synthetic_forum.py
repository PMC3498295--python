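"""Synthetic forum-corpus generator with planted communication structure.

Real threaded health-forum data is rarely redistributable, so every
downstream stage here is exercised on generated corpora whose social
structure is planted by three interpretable dials:

``sociality``
    Partner-choice style in [0, 1].  At 1 every reply author is a fresh
    draw from the member activity distribution (broad, shallow contact —
    many correspondents, light dyads).  At 0 reply authors are re-drawn
    from the set of members who already replied to the same thread
    creator, reinforcing repeated partners (narrow, deep contact — few
    correspondents, heavy dyads).

``homophily``
    Probability in [0, 1] that a patient/survivor's reply lands on a
    patient/survivor-created thread when at least one exists; otherwise the
    thread is chosen uniformly.  Plants the like-seeks-like concentration
    of patient-to-patient exchange.

``activity_concentration``
    Concentration of the symmetric Dirichlet from which per-member posting
    propensities are drawn.  Small values give a few hyper-active members
    and a long quiet tail (heavily skewed participation, as observed in
    real forums); large values flatten activity.

Generation is a single seeded stream per corpus: identical (config, seed)
pairs produce bit-identical corpora, and multi-forum studies derive one
independent substream per forum in config order, so adding a forum never
reshuffles another forum's draws.

Generative model (per forum):

1. members with exact per-type counts; activity weights ~ Dirichlet(a).
2. thread creators drawn from activity weights; creation times uniform on
   [start, thread_cutoff]; each thread opens with a post by its creator.
3. per-thread reply counts drawn from the configured distribution, fixing
   the total reply budget.
4. each reply slot: a provisional author is a fresh draw from activity
   weights; the slot's thread is chosen under the homophily rule given
   that author's group; then with probability ``sociality`` the
   provisional author is kept, else the author is re-drawn uniformly from
   members who already replied in any thread of this thread's creator
   (fallback: keep the fresh draw).  Reply times are uniform on
   (thread creation, post_cutoff) and strictly increasing within a thread.

Self-replies (creator replying in their own thread) are allowed here;
network construction drops self-arcs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import yaml

from .forum_io import (
    ForumCorpus,
    Member,
    MemberGroup,
    Post,
    Thread,
    USER_TYPE_ORDER,
    UserType,
    member_group,
)

__all__ = [
    "StyleConfig",
    "ConfigError",
    "generate_corpus",
    "generate_forums",
    "sample_member_population",
    "simulate_thread",
    "choose_thread",
    "female_style",
    "male_style",
    "PRESETS",
    "DEFAULT_WINDOW",
]


class ConfigError(ValueError):
    """A StyleConfig violates its invariants."""


#: Study window used by the presets: 2001-09-01 thread-creation start,
#: 2010-04-30 thread-creation cutoff, replies accepted through 2010-05-17.
DEFAULT_WINDOW = (
    dt.datetime(2001, 9, 1),
    dt.datetime(2010, 4, 30, 23, 59, 59),
    dt.datetime(2010, 5, 17, 23, 59, 59),
)

#: Preset per-type member mix for a 200-member forum, scaled from the
#: registration mix of a real female-specific cancer forum (roughly half
#: patient/survivor, a large unknown tail, few professionals).
DEFAULT_MEMBER_MIX: dict[UserType, int] = {
    UserType.PATIENT: 82,
    UserType.SURVIVOR: 19,
    UserType.CAREGIVER: 15,
    UserType.DOCTOR: 2,
    UserType.NURSE: 0,
    UserType.STUDENT: 0,
    UserType.RESEARCHER: 5,
    UserType.UNKNOWN: 77,
}


@dataclasses.dataclass
class StyleConfig:
    """Parameters of one synthetic forum.

    ``replies_per_thread`` is a distribution spec: ``{"dist": "poisson",
    "mean": m}`` or ``{"dist": "fixed", "n": k}``.
    """

    forum_name: str
    n_members_by_type: Mapping[UserType, int]
    window: tuple[dt.datetime, dt.datetime, dt.datetime] = DEFAULT_WINDOW
    n_threads: int = 300
    replies_per_thread: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"dist": "poisson", "mean": 4.0}
    )
    sociality: float = 0.5
    homophily: float = 0.8
    activity_concentration: float = 0.3

    def __post_init__(self) -> None:
        self.n_members_by_type = {
            UserType(k): int(v) for k, v in dict(self.n_members_by_type).items()
        }

    @property
    def n_members(self) -> int:
        return sum(self.n_members_by_type.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.n_members_by_type.values()):
            raise ConfigError("member counts must be nonnegative")
        if self.n_threads < 0:
            raise ConfigError("n_threads must be nonnegative")
        if self.n_threads > 0 and self.n_members == 0:
            raise ConfigError("cannot create threads in a forum with no members")
        if not (0.0 <= self.sociality <= 1.0):
            raise ConfigError("sociality must lie in [0, 1]")
        if not (0.0 <= self.homophily <= 1.0):
            raise ConfigError("homophily must lie in [0, 1]")
        if self.activity_concentration <= 0:
            raise ConfigError("activity_concentration must be positive")
        start, tcut, pcut = self.window
        if not (start <= tcut <= pcut):
            raise ConfigError("window must be ordered start <= thread_cutoff <= post_cutoff")
        dist = self.replies_per_thread.get("dist")
        if dist == "poisson":
            if self.replies_per_thread.get("mean", -1) < 0:
                raise ConfigError("poisson mean must be nonnegative")
        elif dist == "fixed":
            if self.replies_per_thread.get("n", -1) < 0:
                raise ConfigError("fixed reply count must be nonnegative")
        else:
            raise ConfigError(f"unknown replies_per_thread dist {dist!r}")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "forum_name": self.forum_name,
            "n_members_by_type": {k.value: v for k, v in self.n_members_by_type.items()},
            "window": [t.isoformat() for t in self.window],
            "n_threads": self.n_threads,
            "replies_per_thread": dict(self.replies_per_thread),
            "sociality": self.sociality,
            "homophily": self.homophily,
            "activity_concentration": self.activity_concentration,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "StyleConfig":
        data = dict(data)
        if "window" in data:
            data["window"] = tuple(
                dt.datetime.fromisoformat(t) if isinstance(t, str) else t
                for t in data["window"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "list[StyleConfig]":
        """Load one or more forum configs from a YAML file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, Mapping):
            data = [data]
        return [cls.from_dict(d) for d in data]


def female_style(forum_name: str = "female_style", **overrides) -> StyleConfig:
    """Preset: narrow/deep partner choice (sociality 0.15, homophily 0.8).

    The low sociality concentrates replies on repeated partners, planting
    few but heavy dyads — the narrow, intimate style.  Calibration values
    are conventions of this package, not estimates from data.
    """
    params = dict(
        forum_name=forum_name,
        n_members_by_type=dict(DEFAULT_MEMBER_MIX),
        sociality=0.15,
        homophily=0.8,
    )
    params.update(overrides)
    return StyleConfig(**params)


def male_style(forum_name: str = "male_style", **overrides) -> StyleConfig:
    """Preset: broad/shallow partner choice (sociality 0.85, homophily 0.8)."""
    params = dict(
        forum_name=forum_name,
        n_members_by_type=dict(DEFAULT_MEMBER_MIX),
        sociality=0.85,
        homophily=0.8,
    )
    params.update(overrides)
    return StyleConfig(**params)


PRESETS = {"female_style": female_style, "male_style": male_style}


# -- population ----------------------------------------------------------------


def sample_member_population(config: StyleConfig, seed: int | None = None) -> list[Member]:
    """Materialise the member roster: exact per-type counts, stable sortable ids.

    Counts are exact (not sampled), so no randomness is consumed; ``seed``
    is accepted for interface symmetry.
    """
    config.validate()
    members: list[Member] = []
    idx = 0
    for utype in USER_TYPE_ORDER:
        for _ in range(config.n_members_by_type.get(utype, 0)):
            members.append(Member(f"{config.forum_name}_m{idx:04d}", config.forum_name, utype))
            idx += 1
    return members


def _draw_reply_count(spec: Mapping[str, float], rng: np.random.Generator) -> int:
    if spec["dist"] == "fixed":
        return int(spec["n"])
    return int(rng.poisson(spec["mean"]))


def _uniform_time(rng: np.random.Generator, lo: dt.datetime, hi: dt.datetime) -> dt.datetime:
    span = max(int((hi - lo).total_seconds()), 1)
    return lo + dt.timedelta(seconds=int(rng.integers(0, span)))


def choose_thread(
    rng: np.random.Generator,
    replier_group: MemberGroup,
    n_threads: int,
    patient_thread_idx: Sequence[int],
    homophily: float,
) -> int:
    """Pick the thread a reply lands on.

    A patient/survivor replier is restricted to patient/survivor-created
    threads with probability ``homophily`` whenever any exist; all other
    draws are uniform over every thread.
    """
    if (
        replier_group is MemberGroup.PATIENT_SURVIVOR
        and len(patient_thread_idx) > 0
        and rng.random() < homophily
    ):
        return int(patient_thread_idx[rng.integers(0, len(patient_thread_idx))])
    return int(rng.integers(0, n_threads))


# -- single-thread building block ----------------------------------------------


def simulate_thread(
    config: StyleConfig,
    members: Sequence[Member],
    rng: np.random.Generator,
    *,
    thread_id: str = "t0000",
) -> tuple[Thread, list[Post]]:
    """Generate one standalone thread with its opening post and replies.

    The creator is drawn with probability proportional to freshly drawn
    activity weights; each reply author is a fresh activity draw with
    probability ``sociality``, otherwise re-drawn uniformly from this
    thread's previous repliers (fresh draw when there are none yet).
    Within a full corpus, :func:`generate_corpus` additionally routes each
    reply to a thread under the homophily rule; a single isolated thread
    has no thread choice to make.
    """
    if not members:
        raise ConfigError("simulate_thread requires a nonempty member population")
    start, tcut, pcut = config.window
    weights = rng.dirichlet(np.full(len(members), config.activity_concentration))
    creator = members[int(rng.choice(len(members), p=weights))]
    created_at = _uniform_time(rng, start, tcut)
    thread = Thread(thread_id, config.forum_name, creator.member_id, created_at)
    posts = [Post(f"{thread_id}_p000000", thread_id, creator.member_id, created_at)]

    n_replies = _draw_reply_count(config.replies_per_thread, rng)
    prior_repliers: list[str] = []
    events: list[tuple[dt.datetime, str]] = []
    for _ in range(n_replies):
        author_id = members[int(rng.choice(len(members), p=weights))].member_id
        if rng.random() >= config.sociality and prior_repliers:
            author_id = prior_repliers[int(rng.integers(0, len(prior_repliers)))]
        if author_id not in prior_repliers:
            prior_repliers.append(author_id)
        events.append((_uniform_time(rng, created_at + dt.timedelta(seconds=1), pcut), author_id))

    events.sort(key=lambda e: e[0])
    last = created_at
    for i, (ts, author_id) in enumerate(events, start=1):
        if ts <= last:  # enforce strictly increasing times within the thread
            ts = last + dt.timedelta(seconds=1)
        last = ts
        posts.append(Post(f"{thread_id}_p{i:06d}", thread_id, author_id, ts))
    return thread, posts


# -- full corpus ----------------------------------------------------------------


def generate_corpus(config: StyleConfig, seed: int) -> ForumCorpus:
    """Generate one forum's corpus; deterministic given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    members = sample_member_population(config)
    corpus = ForumCorpus(members=members, threads=[], posts=[], window=None)
    if config.n_threads == 0 or not members:
        corpus.validate()
        return corpus

    start, tcut, pcut = config.window
    n = len(members)
    member_ids = [m.member_id for m in members]
    groups = [member_group(m.user_type) for m in members]
    weights = rng.dirichlet(np.full(n, config.activity_concentration))

    # threads, in creation-time order
    creator_idx = rng.choice(n, size=config.n_threads, p=weights)
    times = sorted(
        _uniform_time(rng, start, tcut) for _ in range(config.n_threads)
    )
    threads = [
        Thread(f"{config.forum_name}_t{i:04d}", config.forum_name,
               member_ids[int(c)], ts)
        for i, (c, ts) in enumerate(zip(creator_idx, times))
    ]
    patient_thread_idx = np.array(
        [i for i, c in enumerate(creator_idx)
         if groups[int(c)] is MemberGroup.PATIENT_SURVIVOR],
        dtype=int,
    )

    # reply budget: per-thread draws fix the total number of replies
    budget = sum(
        _draw_reply_count(config.replies_per_thread, rng)
        for _ in range(config.n_threads)
    )

    # reply slots: fresh author -> homophily-guided thread -> sociality gate
    repliers_of_creator: dict[str, list[str]] = {}
    thread_events: dict[int, list[tuple[dt.datetime, str]]] = {
        i: [] for i in range(config.n_threads)
    }
    for _ in range(budget):
        prov_idx = int(rng.choice(n, p=weights))
        t_i = choose_thread(
            rng, groups[prov_idx], config.n_threads, patient_thread_idx,
            config.homophily,
        )
        creator_id = threads[t_i].creator_id
        pool = repliers_of_creator.setdefault(creator_id, [])
        if rng.random() < config.sociality or not pool:
            author_id = member_ids[prov_idx]
        else:
            author_id = pool[int(rng.integers(0, len(pool)))]
        if author_id not in pool:
            pool.append(author_id)
        ts = _uniform_time(
            rng, threads[t_i].created_at + dt.timedelta(seconds=1), pcut
        )
        thread_events[t_i].append((ts, author_id))

    posts: list[Post] = []
    p_i = 0
    for t_i, thread in enumerate(threads):
        posts.append(
            Post(f"{config.forum_name}_p{p_i:06d}", thread.thread_id,
                 thread.creator_id, thread.created_at)
        )
        p_i += 1
        last = thread.created_at
        for ts, author_id in sorted(thread_events[t_i], key=lambda e: e[0]):
            if ts <= last:
                ts = last + dt.timedelta(seconds=1)
            last = ts
            posts.append(
                Post(f"{config.forum_name}_p{p_i:06d}", thread.thread_id, author_id, ts)
            )
            p_i += 1

    corpus = ForumCorpus(members=members, threads=threads, posts=posts, window=None)
    corpus.validate()
    return corpus


def generate_forums(configs: Sequence[StyleConfig], seed: int) -> ForumCorpus:
    """Generate a multi-forum corpus, one independent substream per forum.

    Substreams are derived from (seed, position) in config order, so
    appending a forum leaves earlier forums' draws untouched.
    """
    names = [c.forum_name for c in configs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate forum names in config list: {names}")
    members: list[Member] = []
    threads: list[Thread] = []
    posts: list[Post] = []
    for i, config in enumerate(configs):
        sub = np.random.SeedSequence([int(seed), i]).generate_state(1)[0]
        corpus = generate_corpus(config, int(sub))
        members.extend(corpus.members)
        threads.extend(corpus.threads)
        posts.extend(corpus.posts)
    out = ForumCorpus(members=members, threads=threads, posts=posts)
    out.validate()
    return out
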