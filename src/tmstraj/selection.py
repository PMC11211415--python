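"""Class-number selection and classification-adequacy indices.

Selection follows the trial's rule: among candidate class numbers, keep the
fits that converged and whose smallest modal class holds at least 5% of the
sample, then take the lowest BIC.  Adequacy of the chosen classification is
summarised by APPA (average posterior probability of assignment per class),
OCC (odds of correct classification) and relative entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lcga import LCGAFit

__all__ = [
    "AdequacyIndices",
    "bic",
    "aic",
    "select_model",
    "ModelSelectionError",
    "adequacy",
    "classes_merged",
    "APPA_ACCEPTABLE",
    "OCC_ACCEPTABLE",
    "MIN_CLASS_FRACTION",
]

#: conventional advisory thresholds; flags only, never hard gates
APPA_ACCEPTABLE = 0.7
OCC_ACCEPTABLE = 5.0
MIN_CLASS_FRACTION = 0.05


def bic(fit: LCGAFit) -> float:
    """Bayesian Information Criterion, -2 loglik + k ln N (lower is better)."""
    return -2.0 * fit.loglik + fit.n_params * np.log(fit.n_subjects)


def aic(fit: LCGAFit) -> float:
    return -2.0 * fit.loglik + 2.0 * fit.n_params


class ModelSelectionError(RuntimeError):
    """No candidate model passed the selection rule; carries the rationale."""

    def __init__(self, table: pd.DataFrame):
        super().__init__("no fitted model passed the selection criteria")
        self.table = table


def select_model(
    fits: list[LCGAFit], min_frac: float = MIN_CLASS_FRACTION
) -> tuple[LCGAFit, pd.DataFrame]:
    """Apply the BIC + minimum-class-size + convergence rule.

    Returns the selected fit and a per-G rationale table (BIC, AIC, minimum
    modal class fraction, convergence, pass/fail).  A model whose smallest
    class falls below ``min_frac`` (e.g. 4.8% against a 5% floor) is
    excluded even if its BIC is lowest.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for f in fits:
        min_fraction = float(f.class_fractions.min())
        passed = bool(f.converged and min_fraction >= min_frac)
        rows.append(
            {
                "G": f.G,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "BIC": bic(f),
                "AIC": aic(f),
                "min_fraction": min_fraction,
                "converged": bool(f.converged),
                "passed": passed,
            }
        )
    table = pd.DataFrame(rows)
    eligible = table[table["passed"]]
    if eligible.empty:
        raise ModelSelectionError(table)
    best_g = int(eligible.loc[eligible["BIC"].idxmin(), "G"])
    selected = next(f for f in fits if f.G == best_g)
    return selected, table


@dataclass
class AdequacyIndices:
    """Classification adequacy of a fitted mixture."""

    appa: np.ndarray  # per class; NaN for empty modal classes
    occ: np.ndarray  # per class; +inf when APPA = 1, NaN when undefined
    relative_entropy: float
    class_fractions: np.ndarray  # modal fractions
    pi_hat: np.ndarray  # membership-proportion estimate used in OCC
    occ_variant: str

    @property
    def min_class_fraction(self) -> float:
        return float(np.min(self.class_fractions))

    @property
    def appa_acceptable(self) -> np.ndarray:
        return self.appa > APPA_ACCEPTABLE

    @property
    def occ_acceptable(self) -> np.ndarray:
        return self.occ > OCC_ACCEPTABLE

    def to_dict(self) -> dict:
        return {
            "appa": [None if np.isnan(v) else float(v) for v in self.appa],
            "occ": [
                None if np.isnan(v) else ("inf" if np.isinf(v) else float(v))
                for v in self.occ
            ],
            "relative_entropy": float(self.relative_entropy),
            "class_fractions": [float(v) for v in self.class_fractions],
            "pi_hat": [float(v) for v in self.pi_hat],
            "occ_variant": self.occ_variant,
        }


def adequacy(
    posteriors: np.ndarray | LCGAFit, occ_variant: str = "posterior_mean"
) -> AdequacyIndices:
    """APPA, OCC and relative entropy from a posterior classification matrix.

    APPA_g averages p_ig over subjects modally assigned to class g.  OCC_g
    is the odds ratio [APPA_g/(1-APPA_g)] / [pi_g/(1-pi_g)]; by default
    ``pi_g`` is the model-estimated membership proportion (mean posterior
    column), with ``occ_variant="modal"`` using modal class counts instead
    (the two differ slightly and printed literature values are not always
    recoverable from either).  Relative entropy is
    ``1 - sum_i sum_g (-p_ig ln p_ig) / (N ln G)``: 1 for a one-hot
    classification, 0 for a uniformly uncertain one.
    """
    post = posteriors.posteriors if isinstance(posteriors, LCGAFit) else np.asarray(posteriors, float)
    N, G = post.shape
    modal = post.argmax(axis=1)
    fractions = np.bincount(modal, minlength=G) / N

    appa = np.full(G, np.nan)
    for g in range(G):
        sel = modal == g
        if sel.any():
            appa[g] = post[sel, g].mean()

    if occ_variant == "posterior_mean":
        pi_hat = post.mean(axis=0)
    elif occ_variant == "modal":
        pi_hat = fractions.astype(float)
    else:
        raise ValueError(f"unknown occ_variant {occ_variant!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        appa_odds = appa / (1.0 - appa)  # inf when APPA == 1
        pi_odds = pi_hat / (1.0 - pi_hat)
        occ = appa_odds / pi_odds
    occ[np.isnan(appa)] = np.nan

    if G >= 2:
        p = np.clip(post, 1e-300, 1.0)
        entropy = float(np.sum(-p * np.log(p)))
        rel_entropy = 1.0 - entropy / (N * np.log(G))
    else:
        rel_entropy = 1.0
    return AdequacyIndices(
        appa=appa,
        occ=occ,
        relative_entropy=rel_entropy,
        class_fractions=fractions,
        pi_hat=pi_hat,
        occ_variant=occ_variant,
    )


def classes_merged(
    true_labels: np.ndarray, assignments: np.ndarray, class_a: int, class_b: int
) -> bool:
    """True when two ground-truth classes map to the same fitted class.

    A ground-truth class "maps to" the fitted class that the plurality of
    its members are modally assigned to.  Used to detect, e.g., the merging
    of delayed and plateau improvers under coarser temporal sampling.
    """
    true_labels = np.asarray(true_labels)
    assignments = np.asarray(assignments)
    targets = []
    for c in (class_a, class_b):
        sel = assignments[true_labels == c]
        if sel.size == 0:
            return False
        targets.append(np.bincount(sel).argmax())
    return targets[0] == targets[1]
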