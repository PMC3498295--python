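import datetime as dt

import pytest

from forumnet.forum_io import ForumCorpus, Member, Post, Thread, UserType


def ts(text: str) -> dt.datetime:
    return dt.datetime.fromisoformat(text)


@pytest.fixture
def tiny_corpus() -> ForumCorpus:
    """One forum, one thread by A, replies B, B, C (plus the opening post).

    The canonical hand-enumerable example: under to_creator attribution the
    arcs are B->A weight 2 and C->A weight 1.
    """
    forum = "demo"
    members = [
        Member("A", forum, UserType.PATIENT),
        Member("B", forum, UserType.SURVIVOR),
        Member("C", forum, UserType.CAREGIVER),
    ]
    threads = [Thread("t1", forum, "A", ts("2002-01-01T10:00:00"))]
    posts = [
        Post("p0", "t1", "A", ts("2002-01-01T10:00:00")),
        Post("p1", "t1", "B", ts("2002-01-02T10:00:00")),
        Post("p2", "t1", "B", ts("2002-01-05T10:00:00")),
        Post("p3", "t1", "C", ts("2002-01-11T10:00:00")),
    ]
    corpus = ForumCorpus(members=members, threads=threads, posts=posts)
    corpus.validate()
    return corpus


@pytest.fixture
def minimal_corpus() -> ForumCorpus:
    """One patient member, one thread, one opening post."""
    corpus = ForumCorpus(
        members=[Member("m1", "solo", UserType.PATIENT)],
        threads=[Thread("t1", "solo", "m1", ts("2003-06-01T00:00:00"))],
        posts=[Post("p1", "t1", "m1", ts("2003-06-01T00:00:00"))],
    )
    corpus.validate()
    return corpus


@pytest.fixture
def empty_corpus() -> ForumCorpus:
    return ForumCorpus(members=[], threads=[], posts=[])
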