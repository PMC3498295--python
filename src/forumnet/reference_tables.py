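"""Published registration / activity counts for six cancer forums.

The 2001--2010 cancercompass.com study corpus (six cancer-specific
discussion forums: melanoma, renal cell, prostate, testicular, ovarian,
breast) is not redistributable, but its published per-forum counts of
members, threads and posts by user type are, and serve two roles here:

* realistic scale and composition targets for the synthetic generator's
  presets, and
* fixed inputs for summary statistics (survivor percentages, corpus
  totals) that can be recomputed exactly.

Counts are per user type in the order patient, survivor, caregiver,
doctor, nurse, student, researcher, unknown.

The published member grand total (8,388) exceeds the sum of the per-forum
member rows (7,971); the source does not explain the discrepancy (possibly
cross-forum registrations counted once per site).  Both numbers are kept;
nothing here attempts to reconcile them.
"""

from __future__ import annotations

import pandas as pd

from .forum_io import USER_TYPE_ORDER

__all__ = [
    "FORUMS",
    "MEMBER_COUNTS",
    "THREAD_COUNTS",
    "POST_COUNTS",
    "REPORTED_MEMBER_TOTAL",
    "SEER_INCIDENCE_PER_100K",
    "reference_summary",
]

FORUMS = ("melanoma", "renal_cell", "prostate", "testicular", "ovarian", "breast")

# forum -> (patient, survivor, caregiver, doctor, nurse, student, researcher, unknown)
MEMBER_COUNTS: dict[str, tuple[int, ...]] = {
    "melanoma":   (351, 54, 155, 8, 1, 0, 29, 367),
    "renal_cell": (327, 21, 232, 6, 2, 0, 7, 308),
    "prostate":   (609, 81, 231, 31, 0, 0, 47, 378),
    "testicular": (21, 8, 15, 3, 0, 0, 11, 39),
    "ovarian":    (554, 129, 99, 15, 0, 1, 31, 518),
    "breast":     (1453, 587, 161, 36, 1, 1, 67, 976),
}

THREAD_COUNTS: dict[str, tuple[int, ...]] = {
    "melanoma":   (205, 22, 81, 3, 1, 0, 17, 273),
    "renal_cell": (216, 8, 195, 2, 1, 0, 3, 248),
    "prostate":   (565, 38, 194, 4, 0, 0, 39, 343),
    "testicular": (13, 2, 10, 0, 0, 0, 11, 31),
    "ovarian":    (350, 42, 62, 3, 0, 1, 27, 376),
    "breast":     (956, 309, 69, 8, 0, 0, 37, 620),
}

POST_COUNTS: dict[str, tuple[int, ...]] = {
    "melanoma":   (1003, 117, 452, 122, 5, 0, 39, 986),
    "renal_cell": (1323, 138, 1145, 20, 6, 0, 12, 923),
    "prostate":   (3346, 790, 657, 411, 0, 0, 121, 1146),
    "testicular": (37, 10, 21, 6, 0, 0, 13, 58),
    "ovarian":    (2919, 386, 333, 42, 0, 1, 70, 1173),
    "breast":     (4841, 2158, 301, 241, 2, 1, 113, 1962),
}

#: Member grand total as published (does not equal the per-forum column sum).
REPORTED_MEMBER_TOTAL = 8388

#: SEER age-adjusted incidence per 100,000 (diagnoses 1975-2007), by gender.
#: Static reference data; used only for context, never in computation.
SEER_INCIDENCE_PER_100K = pd.DataFrame(
    {
        "breast": [1.08, 124.68],
        "ovarian": [0.0, 14.75],
        "prostate": [154.25, 0.0],
        "testicular": [5.04, 0.0],
        "melanoma": [18.83, 13.12],
        "renal_cell": [15.21, 7.46],
    },
    index=["male", "female"],
)


def _block(counts: dict[str, tuple[int, ...]]) -> pd.DataFrame:
    cols = [u.value for u in USER_TYPE_ORDER]
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=cols)
    frame = frame.loc[list(FORUMS)]
    frame.loc["all"] = frame.sum(axis=0)
    frame["total"] = frame.sum(axis=1)
    return frame


def reference_summary() -> pd.DataFrame:
    """Published counts in the same (block, forum) shape as summarize_corpus."""
    blocks = {
        "members": _block(MEMBER_COUNTS),
        "threads": _block(THREAD_COUNTS),
        "posts": _block(POST_COUNTS),
    }
    return pd.concat(blocks, names=["block", "forum"])
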