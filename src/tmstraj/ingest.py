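"""Reading and preparing session-rating tables.

The pipeline consumes a long-format ratings table (``subject_id``,
``session`` 0..20, ``rating`` raw 1..5); a missing session simply has no
row.  This module applies the trial's inclusion rules, recodes the raw
5-level improvement rating to the 4-level modelling scale (raw 1 "much
worse" and 2 "a bit worse" are merged), fixes the session-zero "no change"
anchor, and can thin a series to weekly sampling for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InclusionReport",
    "apply_inclusion",
    "recode_ordinal",
    "subsample_weekly",
    "ratings_to_matrix",
    "read_ratings_csv",
    "N_PLANNED_SESSIONS",
    "MIN_SESSIONS_WITH_DATA",
    "MAX_SPAN_DAYS",
    "RECODE_MAP",
    "WEEKLY_SESSIONS",
]

N_PLANNED_SESSIONS = 20
#: retain a subject only with ratings for >= 18 of the 20 planned sessions
MIN_SESSIONS_WITH_DATA = 18
#: first-to-last delivered session span must not exceed 6 weeks
MAX_SPAN_DAYS = 42
#: raw 1..5 -> modelling 1..4 ("much worse" merged into "a bit worse")
RECODE_MAP = {1: 1, 2: 1, 3: 2, 4: 3, 5: 4}
#: session-zero anchor on the raw scale ("just the same")
SESSION0_RAW = 3
WEEKLY_SESSIONS = (0, 5, 10, 15, 20)


@dataclass
class InclusionReport:
    """Tally of the inclusion filter, one first-matching reason per subject."""

    n_input: int
    n_excluded_wrong_target: int
    n_excluded_span: int
    n_excluded_missing: int
    n_included: int
    reasons: dict = field(default_factory=dict)  # subject_id -> reason string

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_wrong_target": self.n_excluded_wrong_target,
            "n_excluded_span": self.n_excluded_span,
            "n_excluded_missing": self.n_excluded_missing,
            "n_included": self.n_included,
            "reasons": {str(k): v for k, v in sorted(self.reasons.items())},
        }


def read_ratings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "session", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
    return df


def apply_inclusion(
    ratings: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, InclusionReport]:
    """Filter subjects by the trial's three inclusion rules.

    A subject is retained iff their wrong-target flag is 0, the first-to-last
    treatment span is at most 42 days, and at least 18 of the 20 planned
    sessions (sessions 1..20) have a rating.  Exclusion reasons are tallied
    in fixed priority order: wrong target, then span, then missing data.
    """
    meta = metadata.set_index("subject_id")
    subjects = ratings["subject_id"].unique()
    absent = [s for s in subjects if s not in meta.index]
    if absent:
        raise KeyError(f"subjects missing from metadata: {absent[:5]}")

    n_obs = (
        ratings[(ratings["session"] >= 1) & (ratings["session"] <= N_PLANNED_SESSIONS)]
        .groupby("subject_id")["rating"]
        .apply(lambda s: int(s.notna().sum()))
    )
    reasons: dict = {}
    keep = []
    for s in subjects:
        row = meta.loc[s]
        if bool(row.get("wrong_target", 0)):
            reasons[s] = "wrong_target"
        elif float(row.get("span_days", 0)) > MAX_SPAN_DAYS:
            reasons[s] = "span"
        elif int(n_obs.get(s, 0)) < MIN_SESSIONS_WITH_DATA:
            reasons[s] = "missing"
        else:
            keep.append(s)
    counts = pd.Series(list(reasons.values()))
    report = InclusionReport(
        n_input=len(subjects),
        n_excluded_wrong_target=int((counts == "wrong_target").sum()),
        n_excluded_span=int((counts == "span").sum()),
        n_excluded_missing=int((counts == "missing").sum()),
        n_included=len(keep),
        reasons=reasons,
    )
    filtered = ratings[ratings["subject_id"].isin(set(keep))].reset_index(drop=True)
    return filtered, report


def recode_ordinal(ratings: pd.DataFrame, anchor_session0: bool = True) -> pd.DataFrame:
    """Map raw 1..5 ratings onto the 4-level modelling scale.

    Raw categories 1 and 2 are merged (1, 2 -> 1; 3 -> 2; 4 -> 3; 5 -> 4);
    the merge is applied even when category 1 never occurs, so the number of
    modelling categories is always 4.  With ``anchor_session0`` the session-0
    value is forced to the "no change" category (recoded 2) for every
    subject, inserting the row if absent.  Missing sessions (absent rows or
    NaN ratings) are preserved for t >= 1.
    """
    df = ratings.copy()
    present = df["rating"].notna()
    vals = df.loc[present, "rating"]
    bad = ~vals.isin(RECODE_MAP)
    if bad.any():
        raise ValueError(f"raw ratings outside 1..5: {sorted(vals[bad].unique())[:5]}")
    df.loc[present, "rating"] = vals.map(RECODE_MAP)
    if anchor_session0:
        df = df[df["session"] != 0]
        anchor = pd.DataFrame(
            {
                "subject_id": df["subject_id"].unique(),
                "session": 0,
                "rating": RECODE_MAP[SESSION0_RAW],
            }
        )
        df = pd.concat([anchor, df], ignore_index=True)
    df = df.sort_values(["subject_id", "session"]).reset_index(drop=True)
    df["rating"] = df["rating"].astype(float)
    return df


def subsample_weekly(ratings: pd.DataFrame) -> pd.DataFrame:
    """Keep the session-0 anchor plus sessions 5, 10, 15, 20 only.

    Mimics weekly rather than daily sampling of improvement; idempotent, and
    missing values at the kept sessions remain missing.
    """
    return ratings[ratings["session"].isin(WEEKLY_SESSIONS)].reset_index(drop=True)


def ratings_to_matrix(
    ratings: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pivot a long ratings table to an N x T category matrix.

    Returns ``(Y, sessions, subject_ids)`` where ``Y`` holds the (recoded)
    category per subject/session with NaN for missing, ``sessions`` is the
    sorted vector of session indices present anywhere in the table, and
    ``subject_ids`` gives the row order.
    """
    wide = ratings.pivot_table(
        index="subject_id", columns="session", values="rating", aggfunc="first"
    ).sort_index()
    sessions = np.asarray(sorted(wide.columns))
    wide = wide.reindex(columns=sessions)
    return wide.to_numpy(dtype=float), sessions.astype(float), wide.index.to_numpy()
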