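"""Seeded synthetic cohorts for the trajectory pipeline.

Generates the four tables the analysis consumes — session-by-session ordinal
improvement ratings, neuronavigation coil logs, follow-up outcome scores and a
node/label brain atlas — together with ground-truth class labels, so every
downstream stage can be exercised and validated without any trial data.

The rating model is the same one the analysis fits: each subject belongs to a
latent class ``g`` with a cubic latent trajectory ``lambda_g(u)`` on scaled
session time ``u = t/20``; the observed 1–5 rating at session ``t`` is the
cumulative-probit discretisation of ``lambda_g(u(t)) + eps`` with standard
normal ``eps`` and fixed thresholds.  All generator choices beyond that
(default class shapes, coil-noise model, outcome model) are synthetic
stand-ins with no empirical counterpart; they are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "OutcomeSpec",
    "generate_cohort",
    "generate_atlas",
    "DEFAULT_CLASS_NAMES",
    "POWER_NETWORK_LABELS",
]

#: Canonical class order: best end-of-course latent level first.
DEFAULT_CLASS_NAMES = (
    "strong",
    "delayed",
    "plateau",
    "non_improver",
    "worsening",
)

#: The 13 named resting-state networks of a Power-style 264-node atlas.
POWER_NETWORK_LABELS = (
    "sensory/somatomotor hand",
    "sensory/somatomotor mouth",
    "cingulo-opercular task control",
    "auditory",
    "default mode",
    "memory retrieval",
    "visual",
    "fronto-parietal task control",
    "salience",
    "subcortical",
    "ventral attention",
    "dorsal attention",
    "cerebellar",
)

# E[within-subject sample SD of |x_t - x_1|] / sigma for isotropic per-axis
# Gaussian jitter and 20 sessions (Monte-Carlo, 2e5 reps).  The naive iid
# value sqrt(2*(3 - 8/pi)) ~ 0.952 is biased upward because every distance
# shares the session-1 draw.
_SD_D1_PER_SIGMA = 0.8175

# Within-session metric is the RMS distance of K samples from their centroid;
# for per-axis scale w, E[RMS^2] = 3 w^2 (K-1)/K.
_DEFAULT_N_WITHIN = 5

_EXACT_TRIAL_PROPORTIONS = tuple(np.array([27, 54, 47, 88, 12]) / 228.0)

# Cubic latent-trajectory coefficients on u = t/20; rows follow
# DEFAULT_CLASS_NAMES.  Shapes: early saturating rise / flat-then-late-rise /
# early rise then flat / flat at "no change" / slow decline.
_DEFAULT_BETAS = (
    (0.84, 11.2, -11.2, 4.2),
    (0.84, 0.0, 1.0, 1.1),
    (0.84, 7.0, -8.4, 3.36),
    (0.84, 0.0, 0.0, 0.0),
    (0.42, -2.8, 0.0, 0.0),
)

#: Raw-scale thresholds (M = 5 categories).  tau_1 = -2.7 keeps category 1
#: ("much worse") below ~1% of data points; tau_2 = 0 anchors "no change".
_DEFAULT_THRESHOLDS = (-2.7, 0.0, 1.7, 3.4)

_SCALE_BOUNDS = {
    "HDRS17": (0, 52),
    "BDI2": (0, 63),
    "PHQ9": (0, 27),
    "GAD7": (0, 21),
    "WSAS": (0, 40),
}


@dataclass
class OutcomeSpec:
    """Generative settings for one follow-up scale."""

    baseline_mean: float
    baseline_sd: float
    reduction_by_class: tuple[float, ...]
    reduction_sd: float
    week_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _default_outcomes() -> dict[str, OutcomeSpec]:
    return {
        "HDRS17": OutcomeSpec(23.0, 4.0, (14.0, 10.0, 8.0, 5.0, 1.0), 5.0),
        "BDI2": OutcomeSpec(35.0, 8.0, (18.0, 13.0, 10.0, 6.0, 1.0), 6.0),
        "PHQ9": OutcomeSpec(18.0, 4.0, (9.0, 7.0, 5.0, 3.0, 0.5), 3.0),
        "GAD7": OutcomeSpec(13.0, 4.0, (7.0, 5.0, 4.0, 2.0, 0.5), 3.0),
        "WSAS": OutcomeSpec(30.0, 6.0, (12.0, 9.0, 7.0, 4.0, 1.0), 4.0),
    }


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults reproduce the qualitative study conditions: five classes with
    the trial's class fractions, 4 + 1 raw rating levels over 20 sessions
    with sparse missingness, class-dependent coil-location jitter matching
    the reported per-class dispersion (4.9/3.3/2.9/2.8/2.1 mm), and
    class-graded follow-up score reductions.
    """

    n_subjects: int = 228
    class_proportions: tuple[float, ...] = _EXACT_TRIAL_PROPORTIONS
    class_betas: tuple[tuple[float, float, float, float], ...] = _DEFAULT_BETAS
    thresholds: tuple[float, ...] = _DEFAULT_THRESHOLDS
    missing_rate: float = 0.02
    max_missing_per_subject: int = 2
    n_sessions: int = 20
    coil_sd_by_class: tuple[float, ...] = (4.9, 3.3, 2.9, 2.8, 2.1)
    within_session_sd_by_class: tuple[float, ...] = (2.3, 1.8, 1.9, 1.6, 1.1)
    n_within_samples: int = _DEFAULT_N_WITHIN
    target_center: tuple[float, float, float] = (-41.0, 23.0, 35.0)
    target_spread: float = 6.0
    outcome_effects: dict[str, OutcomeSpec] = field(default_factory=_default_outcomes)
    followup_missing_rate: float = 0.05
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"class_proportions must sum to 1 (got {p.sum()!r})")
        if np.any(p <= 0):
            raise ValueError("class_proportions must all be > 0")
        tau = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(tau) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        betas = np.asarray(self.class_betas, dtype=float)
        if betas.shape != (self.n_classes, 4):
            raise ValueError("class_betas must be G x 4")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for name, sds in (
            ("coil_sd_by_class", self.coil_sd_by_class),
            ("within_session_sd_by_class", self.within_session_sd_by_class),
        ):
            arr = np.asarray(sds, dtype=float)
            if arr.shape != (self.n_classes,):
                raise ValueError(f"{name} must have one entry per class")
            if np.any(arr < 0):
                raise ValueError(f"{name} entries must be >= 0")
        for scale, spec in self.outcome_effects.items():
            if len(spec.reduction_by_class) != self.n_classes:
                raise ValueError(f"outcome_effects[{scale}] needs one reduction per class")


@dataclass
class SyntheticCohort:
    """Generated tables plus ground truth, all keyed by ``subject_id``."""

    ratings: pd.DataFrame  # subject_id, session, rating (raw 1..5)
    metadata: pd.DataFrame  # subject_id, wrong_target, span_days, treatment_arm
    coil: pd.DataFrame  # subject_id, session, x/y/z_mni_mm, sample_index
    targets: pd.DataFrame  # subject_id, x, y, z, arm
    outcomes: pd.DataFrame  # subject_id, scale, baseline, week8, week16, week26
    true_class: pd.Series  # subject_id -> 0-based class index
    config: SimConfig

    def write_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.ratings.to_csv(out / "ratings.csv", index=False)
        self.metadata.to_csv(out / "metadata.csv", index=False)
        self.coil.to_csv(out / "coil.csv", index=False)
        self.targets.to_csv(out / "targets.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.true_class.rename("true_class").rename_axis("subject_id").to_csv(
            out / "true_class.csv"
        )


def _draw_ratings(config: SimConfig, classes: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n, t_max = config.n_subjects, config.n_sessions
    betas = np.asarray(config.class_betas, dtype=float)
    tau = np.asarray(config.thresholds, dtype=float)
    t = np.arange(1, t_max + 1)
    u = t / 20.0
    design = np.vander(u, 4, increasing=True)  # T x 4
    lam = betas @ design.T  # G x T
    latent = lam[classes] + rng.standard_normal((n, t_max))
    # category = 1 + number of thresholds below the latent value
    ratings = 1 + np.searchsorted(tau, latent.ravel(), side="left").reshape(n, t_max)

    missing = rng.random((n, t_max)) < config.missing_rate
    if config.max_missing_per_subject is not None:
        # keep only the first k missing slots per subject (cap mirrors the
        # >= 18-of-20 inclusion rule)
        excess = missing.cumsum(axis=1) > config.max_missing_per_subject
        missing &= ~excess

    subj = np.repeat(np.arange(n), t_max)
    frame = pd.DataFrame(
        {
            "subject_id": subj,
            "session": np.tile(t, n),
            "rating": ratings.ravel(),
        }
    )
    frame = frame[~missing.ravel()]
    anchor = pd.DataFrame(
        {"subject_id": np.arange(n), "session": 0, "rating": 3}
    )
    frame = (
        pd.concat([anchor, frame], ignore_index=True)
        .sort_values(["subject_id", "session"])
        .reset_index(drop=True)
    )
    return frame


def _draw_coil(config: SimConfig, classes: np.ndarray, rng: np.random.Generator):
    n, t_max, k = config.n_subjects, config.n_sessions, config.n_within_samples
    center = np.asarray(config.target_center, dtype=float)
    targets = center + rng.normal(0.0, config.target_spread, size=(n, 3))

    coil_sd = np.asarray(config.coil_sd_by_class, dtype=float)[classes]
    sigma = coil_sd / _SD_D1_PER_SIGMA  # per-axis scale giving E[SD of d1] ~ coil_sd
    session_means = targets[:, None, :] + rng.standard_normal((n, t_max, 3)) * sigma[:, None, None]

    within_sd = np.asarray(config.within_session_sd_by_class, dtype=float)[classes]
    w = within_sd / np.sqrt(3.0 * (k - 1) / k) if k > 1 else np.zeros(n)
    samples = session_means[:, :, None, :] + (
        rng.standard_normal((n, t_max, k, 3)) * w[:, None, None, None]
    )

    rows = []
    sess = np.arange(1, t_max + 1)
    mean_frame = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n), t_max),
            "session": np.tile(sess, n),
            "sample_index": 0,
            "x_mni_mm": session_means[:, :, 0].ravel(),
            "y_mni_mm": session_means[:, :, 1].ravel(),
            "z_mni_mm": session_means[:, :, 2].ravel(),
        }
    )
    rows.append(mean_frame)
    if k > 0:
        samp_frame = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(n), t_max * k),
                "session": np.tile(np.repeat(sess, k), n),
                "sample_index": np.tile(np.arange(1, k + 1), n * t_max),
                "x_mni_mm": samples[:, :, :, 0].ravel(),
                "y_mni_mm": samples[:, :, :, 1].ravel(),
                "z_mni_mm": samples[:, :, :, 2].ravel(),
            }
        )
        rows.append(samp_frame)
    coil = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["subject_id", "session", "sample_index"])
        .reset_index(drop=True)
    )
    arm = np.where(np.arange(n) % 2 == 0, "cgiTBS", "F3-rTMS")
    target_frame = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "x": targets[:, 0],
            "y": targets[:, 1],
            "z": targets[:, 2],
            "arm": arm,
        }
    )
    return coil, target_frame, arm


def _draw_outcomes(config: SimConfig, classes: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    frames = []
    for scale in sorted(config.outcome_effects):
        spec = config.outcome_effects[scale]
        lo, hi = _SCALE_BOUNDS.get(scale, (0.0, np.inf))
        baseline = np.clip(
            rng.normal(spec.baseline_mean, spec.baseline_sd, size=n), lo, hi
        ).round(0)
        cols = {"subject_id": np.arange(n), "scale": scale, "baseline": baseline}
        reduction_mean = np.asarray(spec.reduction_by_class, dtype=float)[classes]
        for week, factor in zip((8, 16, 26), spec.week_factors):
            red = rng.normal(reduction_mean * factor, spec.reduction_sd, size=n)
            score = np.clip(baseline - red, lo, hi).round(0)
            score[rng.random(n) < config.followup_missing_rate] = np.nan
            cols[f"week{week}"] = score
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame(
            columns=["subject_id", "scale", "baseline", "week8", "week16", "week26"]
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort, reproducible from ``config.seed``.

    Subjects are assigned a latent class from ``class_proportions``; ratings,
    coil logs and outcomes are then drawn conditionally on class as described
    in the module docstring.  Session-0 ratings are fixed at 3 ("no change")
    for every subject.
    """
    config = copy.deepcopy(config) if config is not None else SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    classes = rng.choice(
        config.n_classes, size=config.n_subjects, p=np.asarray(config.class_proportions)
    )
    ratings = _draw_ratings(config, classes, rng)
    coil, targets, arm = _draw_coil(config, classes, rng)
    outcomes = _draw_outcomes(config, classes, rng)
    span = rng.integers(26, 40, size=config.n_subjects)
    metadata = pd.DataFrame(
        {
            "subject_id": np.arange(config.n_subjects),
            "wrong_target": 0,
            "span_days": span,
            "treatment_arm": arm,
        }
    )
    true_class = pd.Series(classes, index=pd.RangeIndex(config.n_subjects, name="subject_id"))
    return SyntheticCohort(
        ratings=ratings,
        metadata=metadata,
        coil=coil,
        targets=targets,
        outcomes=outcomes,
        true_class=true_class,
        config=config,
    )


def rating_category_probs(config: SimConfig, g: int, session: int) -> np.ndarray:
    """Closed-form raw-category probabilities P(Y = m | class g, session t).

    Used to check generated frequencies against the generative model.
    """
    betas = np.asarray(config.class_betas, dtype=float)
    tau = np.asarray(config.thresholds, dtype=float)
    from scipy.stats import norm

    u = session / 20.0
    lam = betas[g] @ np.array([1.0, u, u**2, u**3])
    cdf = np.concatenate([[0.0], norm.cdf(tau - lam), [1.0]])
    return np.diff(cdf)


def generate_atlas(
    n_nodes: int,
    labels: tuple[str, ...] | list[str] = POWER_NETWORK_LABELS,
    seed: int = 0,
) -> pd.DataFrame:
    """Random node/label atlas on a cortical shell in MNI mm.

    Nodes are placed uniformly in direction with radius uniform in
    [55, 80] mm; every label appears at least once.  Columns match the atlas
    CSV schema: node_id, x_mni_mm, y_mni_mm, z_mni_mm, network_label.
    """
    labels = list(labels)
    if n_nodes < len(labels):
        raise ValueError(f"n_nodes={n_nodes} < number of labels ({len(labels)})")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal((n_nodes, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = rng.uniform(55.0, 80.0, size=n_nodes)
    xyz = direction * radius[:, None]
    assigned = np.array(
        labels + list(rng.choice(labels, size=n_nodes - len(labels))), dtype=object
    )
    rng.shuffle(assigned)
    return pd.DataFrame(
        {
            "node_id": np.arange(n_nodes),
            "x_mni_mm": xyz[:, 0],
            "y_mni_mm": xyz[:, 1],
            "z_mni_mm": xyz[:, 2],
            "network_label": assigned,
        }
    )


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(copy.deepcopy(config), **kwargs)
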