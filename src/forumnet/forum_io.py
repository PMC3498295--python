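"""Corpus data model and plain-text I/O for threaded forum data.

A forum corpus is the triple (members, threads, posts) for one or more
named forums.  Members carry a self-assigned user type describing their
relationship to the disease; threads are discussions opened by a creator
post; posts are timestamped messages inside a thread.  The corpus is the
sole input of every downstream stage (network construction, dyad
classification, group statistics).

On-disk representation: three UTF-8 CSV tables with header rows,

    members.csv:  member_id,forum,user_type
    threads.csv:  thread_id,forum,creator_id,created_at
    posts.csv:    post_id,thread_id,author_id,posted_at

Timestamps are ISO-8601, timezone-naive (a bare date parses as midnight).
``write_corpus`` emits rows sorted by id so repeated writes of the same
corpus are byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd

__all__ = [
    "UserType",
    "MemberGroup",
    "Member",
    "Thread",
    "Post",
    "ForumCorpus",
    "ValidationError",
    "member_group",
    "read_corpus",
    "write_corpus",
    "apply_study_window",
    "summarize_corpus",
    "parse_timestamp",
    "format_timestamp",
]


class ValidationError(ValueError):
    """A corpus table violates the data-model invariants."""


class UserType(str, enum.Enum):
    """Self-assigned role of a forum member.

    Exactly eight categories are representable; ``unknown`` is a real
    category (members who never state a role), never a missing value.
    """

    PATIENT = "patient"
    SURVIVOR = "survivor"
    CAREGIVER = "caregiver"
    DOCTOR = "doctor"
    NURSE = "nurse"
    STUDENT = "student"
    RESEARCHER = "researcher"
    UNKNOWN = "unknown"


#: Fixed reporting order for user-type columns.
USER_TYPE_ORDER: tuple[UserType, ...] = (
    UserType.PATIENT,
    UserType.SURVIVOR,
    UserType.CAREGIVER,
    UserType.DOCTOR,
    UserType.NURSE,
    UserType.STUDENT,
    UserType.RESEARCHER,
    UserType.UNKNOWN,
)


class MemberGroup(str, enum.Enum):
    """Two-way grouping used throughout the statistical analysis.

    Members registered as patient or survivor form the patient/survivor
    group; every other user type (caregiver, doctor, nurse, student,
    researcher, unknown) is non-patient.
    """

    PATIENT_SURVIVOR = "patient_survivor"
    NON_PATIENT = "non_patient"


def member_group(user_type: UserType) -> MemberGroup:
    """Map a user type onto the patient/survivor vs non-patient dichotomy."""
    if user_type in (UserType.PATIENT, UserType.SURVIVOR):
        return MemberGroup.PATIENT_SURVIVOR
    return MemberGroup.NON_PATIENT


@dataclasses.dataclass(frozen=True, slots=True)
class Member:
    member_id: str
    forum: str
    user_type: UserType


@dataclasses.dataclass(frozen=True, slots=True)
class Thread:
    thread_id: str
    forum: str
    creator_id: str
    created_at: dt.datetime


@dataclasses.dataclass(frozen=True, slots=True)
class Post:
    post_id: str
    thread_id: str
    author_id: str
    posted_at: dt.datetime


@dataclasses.dataclass
class ForumCorpus:
    """Members, threads and posts for one or more forums.

    ``window`` records the (thread_cutoff, post_cutoff) pair once
    :func:`apply_study_window` has been applied; ``None`` means the corpus
    is unwindowed.
    """

    members: list[Member]
    threads: list[Thread]
    posts: list[Post]
    window: tuple[dt.datetime, dt.datetime] | None = None

    # -- convenience lookups -------------------------------------------------

    def forums(self) -> list[str]:
        return sorted({m.forum for m in self.members} | {t.forum for t in self.threads})

    def members_of(self, forum: str) -> list[Member]:
        return [m for m in self.members if m.forum == forum]

    def threads_of(self, forum: str) -> list[Thread]:
        return [t for t in self.threads if t.forum == forum]

    def posts_of(self, forum: str) -> list[Post]:
        tids = {t.thread_id for t in self.threads if t.forum == forum}
        return [p for p in self.posts if p.thread_id in tids]

    def member_index(self) -> dict[str, Member]:
        return {m.member_id: m for m in self.members}

    def thread_index(self) -> dict[str, Thread]:
        return {t.thread_id: t for t in self.threads}

    def canonical(self) -> "ForumCorpus":
        """Copy with id-sorted record lists (for equality comparisons)."""
        return ForumCorpus(
            members=sorted(self.members, key=lambda m: m.member_id),
            threads=sorted(self.threads, key=lambda t: t.thread_id),
            posts=sorted(self.posts, key=lambda p: p.post_id),
            window=self.window,
        )

    def validate(self) -> None:
        """Check referential integrity and ordering invariants.

        Raises :class:`ValidationError` naming the first offending record.
        """
        seen_members: set[str] = set()
        for m in self.members:
            if m.member_id in seen_members:
                raise ValidationError(f"duplicate member_id {m.member_id!r}")
            seen_members.add(m.member_id)
        midx = self.member_index()
        seen_threads: set[str] = set()
        for t in self.threads:
            if t.thread_id in seen_threads:
                raise ValidationError(f"duplicate thread_id {t.thread_id!r}")
            seen_threads.add(t.thread_id)
            creator = midx.get(t.creator_id)
            if creator is None:
                raise ValidationError(
                    f"thread {t.thread_id!r} created by unknown member {t.creator_id!r}"
                )
            if creator.forum != t.forum:
                raise ValidationError(
                    f"thread {t.thread_id!r} creator {t.creator_id!r} belongs to forum "
                    f"{creator.forum!r}, not {t.forum!r}"
                )
        tidx = self.thread_index()
        seen_posts: set[str] = set()
        for p in self.posts:
            if p.post_id in seen_posts:
                raise ValidationError(f"duplicate post_id {p.post_id!r}")
            seen_posts.add(p.post_id)
            thread = tidx.get(p.thread_id)
            if thread is None:
                raise ValidationError(
                    f"post {p.post_id!r} references unknown thread {p.thread_id!r}"
                )
            if p.author_id not in midx:
                raise ValidationError(
                    f"post {p.post_id!r} authored by unknown member {p.author_id!r}"
                )
            if p.posted_at < thread.created_at:
                raise ValidationError(
                    f"post {p.post_id!r} at {p.posted_at} predates its thread "
                    f"({thread.created_at})"
                )


# -- timestamps ---------------------------------------------------------------


def parse_timestamp(text: str) -> dt.datetime:
    """Parse an ISO-8601 timestamp; a bare date becomes midnight.

    Any timezone offset is converted to UTC and dropped: the whole corpus
    is treated as timezone-naive UTC.
    """
    ts = dt.datetime.fromisoformat(text.strip())
    if ts.tzinfo is not None:
        ts = ts.astimezone(dt.timezone.utc).replace(tzinfo=None)
    return ts


def format_timestamp(ts: dt.datetime) -> str:
    return ts.isoformat(sep="T")


def _coerce_cutoff(cutoff: dt.date | dt.datetime | str) -> dt.datetime:
    """Normalize a cutoff to an inclusive datetime bound.

    A bare date is inclusive of the whole calendar day (23:59:59), because
    study windows are naturally stated as dates.
    """
    if isinstance(cutoff, str):
        cutoff = parse_timestamp(cutoff)
        if cutoff.time() == dt.time.min:
            cutoff = cutoff.date()
    if isinstance(cutoff, dt.datetime):
        return cutoff
    return dt.datetime.combine(cutoff, dt.time(23, 59, 59))


# -- reading ------------------------------------------------------------------

_FILES = ("members.csv", "threads.csv", "posts.csv")


def _read_table(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    if not path.is_file():
        raise FileNotFoundError(f"missing corpus table: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return df


def _parse_time_column(df: pd.DataFrame, column: str, filename: str) -> list[dt.datetime]:
    out: list[dt.datetime] = []
    for row, text in enumerate(df[column], start=2):  # header is row 1
        try:
            out.append(parse_timestamp(text))
        except ValueError as exc:
            raise ValidationError(
                f"{filename} row {row}: unparseable timestamp {text!r}"
            ) from exc
    return out


def read_corpus(path: str | Path) -> ForumCorpus:
    """Read and validate a three-table corpus directory."""
    path = Path(path)
    mdf = _read_table(path / "members.csv", ("member_id", "forum", "user_type"))
    tdf = _read_table(path / "threads.csv", ("thread_id", "forum", "creator_id", "created_at"))
    pdf = _read_table(path / "posts.csv", ("post_id", "thread_id", "author_id", "posted_at"))

    members = []
    for row, rec in enumerate(mdf.itertuples(index=False), start=2):
        try:
            utype = UserType(rec.user_type)
        except ValueError as exc:
            raise ValidationError(
                f"members.csv row {row}: unknown user_type {rec.user_type!r}"
            ) from exc
        members.append(Member(rec.member_id, rec.forum, utype))

    created = _parse_time_column(tdf, "created_at", "threads.csv")
    threads = [
        Thread(rec.thread_id, rec.forum, rec.creator_id, ts)
        for rec, ts in zip(tdf.itertuples(index=False), created)
    ]
    posted = _parse_time_column(pdf, "posted_at", "posts.csv")
    posts = [
        Post(rec.post_id, rec.thread_id, rec.author_id, ts)
        for rec, ts in zip(pdf.itertuples(index=False), posted)
    ]

    corpus = ForumCorpus(members=members, threads=threads, posts=posts)
    corpus.validate()
    return corpus


def write_corpus(corpus: ForumCorpus, path: str | Path) -> None:
    """Write a corpus as three CSV tables, rows sorted by id.

    Deterministic: writing the same corpus twice produces byte-identical
    files, so ``read_corpus(write_corpus(c))`` round-trips exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    mdf = pd.DataFrame(
        [(m.member_id, m.forum, m.user_type.value) for m in
         sorted(corpus.members, key=lambda m: m.member_id)],
        columns=["member_id", "forum", "user_type"],
    )
    tdf = pd.DataFrame(
        [(t.thread_id, t.forum, t.creator_id, format_timestamp(t.created_at)) for t in
         sorted(corpus.threads, key=lambda t: t.thread_id)],
        columns=["thread_id", "forum", "creator_id", "created_at"],
    )
    pdf = pd.DataFrame(
        [(p.post_id, p.thread_id, p.author_id, format_timestamp(p.posted_at)) for p in
         sorted(corpus.posts, key=lambda p: p.post_id)],
        columns=["post_id", "thread_id", "author_id", "posted_at"],
    )
    mdf.to_csv(path / "members.csv", index=False, lineterminator="\n")
    tdf.to_csv(path / "threads.csv", index=False, lineterminator="\n")
    pdf.to_csv(path / "posts.csv", index=False, lineterminator="\n")


# -- study window --------------------------------------------------------------


def apply_study_window(
    corpus: ForumCorpus,
    thread_cutoff: dt.date | dt.datetime | str,
    post_cutoff: dt.date | dt.datetime | str,
    *,
    keep_silent_members: bool = False,
) -> ForumCorpus:
    """Restrict a corpus to a study window.

    Threads created after ``thread_cutoff`` are discarded along with every
    post in them; posts after ``post_cutoff`` are discarded; replies posted
    after the thread cutoff to threads created before it are retained.
    By default members left with no surviving post are dropped (a member
    enters a communication network with their first post); pass
    ``keep_silent_members=True`` to retain them for registration counts.
    """
    tcut = _coerce_cutoff(thread_cutoff)
    pcut = _coerce_cutoff(post_cutoff)
    if tcut > pcut:
        raise ValueError(f"thread_cutoff {tcut} is after post_cutoff {pcut}")

    threads = [t for t in corpus.threads if t.created_at <= tcut]
    kept_tids = {t.thread_id for t in threads}
    posts = [p for p in corpus.posts if p.thread_id in kept_tids and p.posted_at <= pcut]
    if keep_silent_members:
        members = list(corpus.members)
    else:
        authors = {p.author_id for p in posts}
        members = [m for m in corpus.members if m.member_id in authors]
    return ForumCorpus(members=members, threads=threads, posts=posts, window=(tcut, pcut))


# -- summary table -------------------------------------------------------------


def summarize_corpus(corpus: ForumCorpus) -> pd.DataFrame:
    """Count members, threads and posts by forum and user type.

    Returns a frame indexed by (block, forum) where block is one of
    ``members`` / ``threads`` / ``posts`` (threads and posts attributed to
    the creator's / author's user type) and each block has an ``all``
    grand-total row; columns are the eight user types plus ``total``.
    """
    midx = corpus.member_index()
    tidx = corpus.thread_index()
    forums = corpus.forums()
    cols = [u.value for u in USER_TYPE_ORDER]

    def _block(rows: Iterable[tuple[str, UserType]]) -> pd.DataFrame:
        frame = pd.DataFrame(0, index=forums, columns=cols, dtype=int)
        for forum, utype in rows:
            frame.loc[forum, utype.value] += 1
        frame.loc["all"] = frame.sum(axis=0)
        frame["total"] = frame.sum(axis=1)
        return frame

    blocks = {
        "members": _block((m.forum, m.user_type) for m in corpus.members),
        "threads": _block(
            (t.forum, midx[t.creator_id].user_type) for t in corpus.threads
        ),
        "posts": _block(
            (tidx[p.thread_id].forum, midx[p.author_id].user_type) for p in corpus.posts
        ),
    }
    out = pd.concat(blocks, names=["block", "forum"])
    return out
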