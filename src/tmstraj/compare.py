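"""Between-class validation statistics for trajectory classes.

Follow-up outcome scores (HDRS-17, BDI-II, PHQ-9, GAD-7, WSAS at weeks
8/16/26) are reduced to baseline-minus-follow-up changes and responder
flags (>= 50% reduction from baseline).  Classes are then compared with the
standard exploratory toolkit: one-way ANOVA with partial eta squared for
continuous variables (optionally on cube-root transformed distances),
chi-square for binary variables, MANOVA (Pillai's trace) for coordinates,
pairwise t tests (pooled variance unless Levene's test is significant, then
Welch) with Cohen's d, and Pearson correlations between coil dispersion and
symptom reduction.  Tests are two-tailed at alpha = 0.05 with no
multiplicity correction by default (a Holm option is provided), matching an
explicitly exploratory analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "PairwiseResult",
    "reduction_and_response",
    "compare_classes",
    "cohens_d",
    "correlate_dispersion_outcome",
    "holm_adjust",
]

ALPHA = 0.05
FOLLOWUP_WEEKS = (8, 16, 26)


@dataclass
class PairwiseResult:
    class_a: int
    class_b: int
    test: str  # "t_test" or "welch_t"
    statistic: float
    df: float
    p_value: float
    cohens_d: float
    skipped: bool = False


@dataclass
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    df: tuple
    p_value: float
    effect_size_name: str
    effect_size: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    transform_applied: bool = False
    group_means: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def significant_pairs(self) -> list[tuple[int, int]]:
        return [
            (p.class_a, p.class_b)
            for p in self.pairwise
            if not p.skipped and p.p_value < ALPHA
        ]


def reduction_and_response(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-subject score reductions and responder flags per follow-up.

    Input is the long outcome table (``subject_id``, ``scale``,
    ``baseline``, ``week8``, ``week16``, ``week26``).  Reduction is
    baseline minus follow-up; a responder has a reduction of at least half
    the baseline (the boundary counts).  A missing follow-up leaves both
    the reduction and the flag missing; a zero baseline leaves the
    responder flag undefined (NaN) and is flagged in
    ``responder_undefined``.
    """
    df = outcomes.copy()
    if df["baseline"].isna().any():
        raise ValueError("baseline scores must be present")
    for week in FOLLOWUP_WEEKS:
        col = f"week{week}"
        red = df["baseline"] - df[col]
        df[f"reduction_w{week}"] = red
        with np.errstate(invalid="ignore"):
            resp = (red >= 0.5 * df["baseline"]).astype(float)
        resp[df[col].isna()] = np.nan
        resp[df["baseline"] == 0] = np.nan
        df[f"responder_w{week}"] = resp
    df["responder_undefined"] = df["baseline"] == 0
    return df


def cohens_d(a, b) -> float:
    """Pooled-SD Cohen's d, first group minus second."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if sp == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / sp)


def _pairwise_tests(groups: dict) -> list[PairwiseResult]:
    out = []
    keys = sorted(groups)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            a, b = groups[ka], groups[kb]
            if len(a) < 2 or len(b) < 2:
                out.append(
                    PairwiseResult(ka, kb, "t_test", np.nan, np.nan, np.nan, np.nan, skipped=True)
                )
                continue
            lev_p = stats.levene(a, b).pvalue if (np.std(a) > 0 or np.std(b) > 0) else 1.0
            equal_var = lev_p >= ALPHA
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            out.append(
                PairwiseResult(
                    class_a=ka,
                    class_b=kb,
                    test="t_test" if equal_var else "welch_t",
                    statistic=float(res.statistic),
                    df=float(res.df),
                    p_value=float(res.pvalue),
                    cohens_d=cohens_d(a, b),
                )
            )
    return out


def compare_classes(
    values,
    classes,
    kind: str = "continuous",
    variable: str = "",
    cube_root: bool = False,
    pairwise: bool = True,
) -> ComparisonResult:
    """Omnibus between-class test for one variable.

    ``kind="continuous"`` runs a one-way ANOVA (partial eta squared =
    SS_between / (SS_between + SS_within)) plus all pairwise t tests;
    ``kind="binary"`` a chi-square test on the class-by-outcome table with
    Cramer's V; ``kind="multivariate"`` a MANOVA reporting Pillai's trace
    (``values`` then holds one column per dependent variable).  With
    ``cube_root`` the analysis runs on cube-root transformed values, the
    convention for right-skewed distance variables.
    """
    cls = np.asarray(classes)
    if kind == "multivariate":
        V = np.asarray(values, dtype=float)
        ok = np.isfinite(V).all(axis=1) & (cls >= 0)
        return _manova_pillai(V[ok], cls[ok], variable)

    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    v, cls = v[ok], cls[ok]
    if cube_root:
        v = np.cbrt(v)
    labels = np.unique(cls)
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty classes")
    groups = {int(c): v[cls == c] for c in labels}

    if kind == "continuous":
        arrs = list(groups.values())
        if np.ptp(v) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*arrs)
        grand = v.mean()
        ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
        ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
        eta_p2 = ss_between / (ss_between + ss_within) if (ss_between + ss_within) > 0 else 0.0
        df = (len(labels) - 1, len(v) - len(labels))
        return ComparisonResult(
            variable=variable,
            test="anova",
            statistic=float(f_stat),
            df=df,
            p_value=float(p),
            effect_size_name="partial_eta2",
            effect_size=float(eta_p2),
            pairwise=_pairwise_tests(groups) if pairwise else [],
            transform_applied=cube_root,
            group_means={k: float(g.mean()) for k, g in groups.items()},
        )

    if kind == "binary":
        table = pd.crosstab(cls, v)
        if table.shape[1] < 2 or table.shape[0] < 2:
            chi2, p, dof = 0.0, 1.0, (table.shape[0] - 1) * max(table.shape[1] - 1, 1)
        else:
            chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        n = len(v)
        k = min(table.shape) - 1
        cramer = np.sqrt(chi2 / (n * k)) if n * k > 0 else 0.0
        return ComparisonResult(
            variable=variable,
            test="chi_square",
            statistic=float(chi2),
            df=(int(dof),),
            p_value=float(p),
            effect_size_name="cramers_v",
            effect_size=float(cramer),
            group_means={int(c): float(g.mean()) for c, g in groups.items()},
        )

    raise ValueError(f"unknown kind {kind!r}")


def _manova_pillai(V: np.ndarray, cls: np.ndarray, variable: str) -> ComparisonResult:
    from statsmodels.multivariate.manova import MANOVA

    frame = pd.DataFrame(V, columns=[f"v{j}" for j in range(V.shape[1])])
    frame["cls"] = pd.Categorical(cls)
    dep = " + ".join(frame.columns[:-1])
    mv = MANOVA.from_formula(f"{dep} ~ cls", data=frame)
    tab = mv.mv_test().results["cls"]["stat"]
    row = tab.loc["Pillai's trace"]
    return ComparisonResult(
        variable=variable,
        test="manova_pillai",
        statistic=float(row["Value"]),
        df=(float(row["Num DF"]), float(row["Den DF"])),
        p_value=float(row["Pr > F"]),
        effect_size_name="pillai_trace",
        effect_size=float(row["Value"]),
    )


def correlate_dispersion_outcome(
    dispersion: pd.Series,
    reductions: pd.DataFrame,
    exclude_class: int | None = None,
    assignments: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson r between coil dispersion and score reduction per follow-up.

    ``dispersion`` maps subject_id to the across-session SD; ``reductions``
    holds ``subject_id`` and ``reduction_w8/16/26`` columns (one scale).
    ``exclude_class`` drops one class (requires ``assignments``) — the
    sensitivity analysis that removes the strongest improvers.
    """
    df = reductions.merge(
        dispersion.rename("s").rename_axis("subject_id").reset_index(), on="subject_id"
    )
    if exclude_class is not None:
        if assignments is None:
            raise ValueError("exclude_class requires assignments")
        cls = assignments.rename("cls").rename_axis("subject_id").reset_index()
        df = df.merge(cls, on="subject_id")
        df = df[df["cls"] != exclude_class]
    rows = []
    for week in FOLLOWUP_WEEKS:
        sub = df[["s", f"reduction_w{week}"]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs at week {week}")
        x, y = sub["s"], sub[f"reduction_w{week}"]
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero variance in correlation input")
        r, p = stats.pearsonr(x, y)
        rows.append({"week": week, "r": float(r), "p_value": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
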