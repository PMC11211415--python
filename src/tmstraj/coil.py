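"""Stimulation-location dispersion metrics from neuronavigation coil logs.

A coil log holds, per subject, the session-mean coil coordinate for each
treatment session (MNI mm), optional within-session coordinate samples, and
the planned target.  Four per-subject metrics summarise placement
dispersion, mirroring the treatment-variable comparisons of the analysis:

* mean Euclidean distance from the planned target,
* mean distance from the session-1 location,
* the standard deviation of that distance across sessions (the
  between-session variability measure, ``s_i``), and
* the mean within-session SD (RMS distance of within-session samples from
  their session centroid).

Distance variables are right-skewed across patients, so group statistics
are computed on cube-root transformed values and back-transformed by
cubing (see :func:`cube_root_summary`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DispersionMetrics",
    "dispersion_metrics",
    "dispersion_table",
    "cube_root_summary",
]


@dataclass
class DispersionMetrics:
    """Per-subject dispersion summary (all in mm; NaN where undefined)."""

    mean_dist_target: float
    mean_dist_session1: float
    sd_dist_session1: float
    within_session_sd: float
    n_sessions_used: int


def _session_arrays(log: pd.DataFrame):
    means = log[log["sample_index"] == 0].sort_values("session")
    xyz = means[["x_mni_mm", "y_mni_mm", "z_mni_mm"]].to_numpy(dtype=float)
    valid = np.isfinite(xyz).all(axis=1)
    return means["session"].to_numpy()[valid], xyz[valid]


def dispersion_metrics(log: pd.DataFrame, target) -> DispersionMetrics:
    """Dispersion metrics for one subject's coil log.

    ``log`` is the subject's slice of the coil table (columns ``session``,
    ``sample_index``, ``x/y/z_mni_mm``; ``sample_index`` 0 marks the session
    mean, larger values within-session samples).  Sessions with missing
    coordinates are skipped.  The SD of distance-from-session-1 requires at
    least 3 usable sessions (2 distances); session-1-referenced metrics are
    NaN when session 1 itself is absent.
    """
    target = np.asarray(target, dtype=float)
    sessions, xyz = _session_arrays(log)
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions with mean coordinates")

    d_target = np.linalg.norm(xyz - target, axis=1)
    mean_dist_target = float(d_target.mean())

    mean_d1 = sd_d1 = np.nan
    if 1 in sessions:
        ref = xyz[sessions == 1][0]
        later = xyz[sessions != 1]
        if len(later):
            d1 = np.linalg.norm(later - ref, axis=1)
            mean_d1 = float(d1.mean())
            if len(d1) >= 2:
                sd_d1 = float(d1.std(ddof=1))

    within = log[log["sample_index"] > 0]
    within_sds = []
    for _, grp in within.groupby("session"):
        pts = grp[["x_mni_mm", "y_mni_mm", "z_mni_mm"]].to_numpy(dtype=float)
        pts = pts[np.isfinite(pts).all(axis=1)]
        if len(pts) >= 2:
            centroid = pts.mean(axis=0)
            within_sds.append(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    within_sd = float(np.mean(within_sds)) if within_sds else np.nan

    return DispersionMetrics(
        mean_dist_target=mean_dist_target,
        mean_dist_session1=mean_d1,
        sd_dist_session1=sd_d1,
        within_session_sd=within_sd,
        n_sessions_used=int(len(sessions)),
    )


def dispersion_table(coil: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Dispersion metrics for every subject in a coil table.

    ``targets`` must hold one row per subject with columns ``subject_id``,
    ``x``, ``y``, ``z``.
    """
    tgt = targets.set_index("subject_id")
    rows = []
    for sid, log in coil.groupby("subject_id"):
        m = dispersion_metrics(log, tgt.loc[sid, ["x", "y", "z"]].to_numpy())
        rows.append(
            {
                "subject_id": sid,
                "mean_dist_target_mm": m.mean_dist_target,
                "mean_dist_session1_mm": m.mean_dist_session1,
                "sd_dist_session1_mm": m.sd_dist_session1,
                "within_session_sd_mm": m.within_session_sd,
                "n_sessions_used": m.n_sessions_used,
            }
        )
    return pd.DataFrame(rows)


def cube_root_summary(values, confidence: float = 0.95) -> dict:
    """Mean and t-based CI on the cube-root scale, back-transformed by cubing.

    Zeros are legal (no offset is added).  Returns a dict with the
    transformed-scale mean/CI and the back-transformed (cubed) versions,
    which is how right-skewed distance variables are reported.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values supplied")
    if np.any(v < 0):
        raise ValueError("cube-root summary expects non-negative values")
    r = np.cbrt(v)
    mean = float(r.mean())
    if v.size > 1 and r.std(ddof=1) > 0:
        half = stats.t.ppf(0.5 + confidence / 2, df=v.size - 1) * r.std(ddof=1) / np.sqrt(v.size)
    else:
        half = 0.0
    lo, hi = mean - half, mean + half
    return {
        "mean_transformed": mean,
        "ci_transformed": (float(lo), float(hi)),
        "mean_backtransformed": float(mean**3),
        "ci_backtransformed": (float(lo**3), float(hi**3)),
        "n": int(v.size),
    }
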