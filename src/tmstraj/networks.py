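"""Estimate how many resting-state networks a treatment course stimulated.

For each patient the planned target is surrounded by 400 probe points lying
on 20 concentric spheres whose radii run from one tenth to twice the
patient's across-session dispersion ``s`` (20 points per sphere).  Each
probe (plus the target itself, 401 points in all) is mapped to the nearest
node of a coordinate/label brain atlas, and the number of distinct network
labels hit is the per-patient "networks stimulated" count.  Flags record
whether the probes reached the Executive Control Network (fronto-parietal
task control + dorsal attention labels), the Default Mode Network, or the
Ventral Attention Network (salience, cingulo-opercular task control or
ventral attention labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "NetworkScore",
    "DEFAULT_NETWORK_GROUPS",
    "probe_points",
    "fibonacci_sphere",
    "nearest_labels",
    "count_networks",
    "score_cohort",
    "class_network_summary",
]

N_SPHERES = 20
POINTS_PER_SPHERE = 20
MAX_RADIUS_FACTOR = 2.0  # outermost sphere radius = 2 * s

#: Label groups over a Power-style atlas; editable by passing your own dict.
DEFAULT_NETWORK_GROUPS: dict[str, tuple[str, ...]] = {
    "ecn": ("fronto-parietal task control", "dorsal attention"),
    "dmn": ("default mode",),
    "van": ("salience", "cingulo-opercular task control", "ventral attention"),
}


@dataclass
class NetworkScore:
    subject_id: object
    n_networks: int
    labels_hit: set = field(default_factory=set)
    group_flags: dict = field(default_factory=dict)
    radius_used: float = np.nan  # outermost sphere radius (mm)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (spherical Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform 3x3 rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def probe_points(target, s: float, seed: int = 0) -> np.ndarray:
    """Target plus 400 probes on 20 spheres of radii (k/10)·s, k = 1..20.

    The 20 points per sphere form a spherical Fibonacci lattice under a
    seeded random rotation, so placement is quasi-uniform and reproducible.
    With ``s = 0`` every probe collapses onto the target.  Returns a
    (401, 3) array whose first row is the target.
    """
    if s < 0:
        raise ValueError("dispersion s must be >= 0")
    target = np.asarray(target, dtype=float)
    rng = np.random.default_rng(seed)
    lattice = fibonacci_sphere(POINTS_PER_SPHERE) @ _random_rotation(rng).T
    radii = (np.arange(1, N_SPHERES + 1) / 10.0) * s
    shells = radii[:, None, None] * lattice[None, :, :]  # (20, 20, 3)
    return np.vstack([target[None, :], target + shells.reshape(-1, 3)])


def nearest_labels(points, atlas: pd.DataFrame) -> list:
    """Network label of the nearest atlas node for each point.

    Exact distance ties resolve to the lowest ``node_id``.  The atlas table
    needs columns ``node_id``, ``x/y/z_mni_mm`` and ``network_label``.
    """
    if len(atlas) == 0:
        raise ValueError("atlas is empty")
    nodes = atlas.sort_values("node_id").reset_index(drop=True)
    xyz = nodes[["x_mni_mm", "y_mni_mm", "z_mni_mm"]].to_numpy(dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    # cKDTree breaks exact ties by insertion index = ascending node_id
    _, idx = cKDTree(xyz).query(pts)
    return nodes["network_label"].iloc[idx].tolist()


def count_networks(
    target,
    s: float,
    atlas: pd.DataFrame,
    seed: int = 0,
    subject_id=None,
    groups: dict | None = None,
    ignore_labels: tuple[str, ...] = (),
) -> NetworkScore:
    """Number of distinct networks hit by the probe cloud around a target.

    ``groups`` maps flag names to label tuples (defaults to the ECN / DMN /
    VAN grouping); labels are compared case-insensitively after trimming.
    ``ignore_labels`` drops labels (e.g. ``("uncertain",)``) from the count.
    """
    groups = DEFAULT_NETWORK_GROUPS if groups is None else groups
    pts = probe_points(target, s, seed=seed)
    labels = {str(lab).strip().lower() for lab in nearest_labels(pts, atlas)}
    labels -= {str(lab).strip().lower() for lab in ignore_labels}
    flags = {
        name: any(str(m).strip().lower() in labels for m in members)
        for name, members in groups.items()
    }
    return NetworkScore(
        subject_id=subject_id,
        n_networks=len(labels),
        labels_hit=labels,
        group_flags=flags,
        radius_used=MAX_RADIUS_FACTOR * s,
    )


def rotation_sensitivity(
    target,
    s: float,
    atlas: pd.DataFrame,
    n_rotations: int = 50,
    seed: int = 0,
    groups: dict | None = None,
) -> dict:
    """Monte-Carlo spread of the network count over probe-lattice rotations.

    The 20-point placement on each sphere is arbitrary up to rotation; this
    reports how much the per-patient count depends on that choice.
    """
    rng = np.random.default_rng(seed)
    counts = np.array(
        [
            count_networks(
                target, s, atlas, seed=int(rng.integers(0, 2**31)), groups=groups
            ).n_networks
            for _ in range(n_rotations)
        ]
    )
    return {
        "mean": float(counts.mean()),
        "sd": float(counts.std(ddof=1)) if n_rotations > 1 else 0.0,
        "min": int(counts.min()),
        "max": int(counts.max()),
        "n_rotations": int(n_rotations),
    }


def score_cohort(
    targets: pd.DataFrame,
    dispersion: pd.DataFrame,
    atlas: pd.DataFrame,
    seed: int = 0,
    groups: dict | None = None,
) -> pd.DataFrame:
    """Network scores for every subject with a usable dispersion estimate.

    ``dispersion`` is the table from :func:`tmstraj.coil.dispersion_table`;
    the across-session SD (``sd_dist_session1_mm``) sets the probe radii.
    Subjects whose SD is missing are skipped.  Per-subject probe rotations
    are derived from ``seed`` via a seed sequence, so the whole scoring is
    reproducible.
    """
    disp = dispersion.set_index("subject_id")["sd_dist_session1_mm"]
    rows = []
    subjects = [s for s in targets["subject_id"] if np.isfinite(disp.get(s, np.nan))]
    child_seeds = np.random.SeedSequence(seed).spawn(len(subjects))
    tgt = targets.set_index("subject_id")
    for sid, ss in zip(subjects, child_seeds):
        score = count_networks(
            tgt.loc[sid, ["x", "y", "z"]].to_numpy(dtype=float),
            float(disp.loc[sid]),
            atlas,
            seed=ss.generate_state(1)[0] % (2**31),
            subject_id=sid,
            groups=groups,
        )
        rows.append(
            {
                "subject_id": sid,
                "n_networks": score.n_networks,
                "labels_hit": ";".join(sorted(score.labels_hit)),
                **{k: bool(v) for k, v in score.group_flags.items()},
                "radius_used_mm": score.radius_used,
            }
        )
    return pd.DataFrame(rows)


def class_network_summary(
    scores: pd.DataFrame, assignments: pd.Series, confidence: float = 0.95
) -> pd.DataFrame:
    """Per-class summary: mean network count with CI, % multi-network, % flags.

    ``assignments`` maps subject_id to (0-based) class index and must cover
    every scored subject.  Empty classes yield a row flagged ``empty``.
    """
    merged = scores.merge(
        assignments.rename("class").rename_axis("subject_id").reset_index(),
        on="subject_id",
        how="left",
    )
    if merged["class"].isna().any():
        raise ValueError("some scored subjects have no class assignment")
    flag_cols = [c for c in scores.columns if c in ("ecn", "dmn", "van")]
    rows = []
    for cls in range(int(assignments.max()) + 1):
        grp = merged[merged["class"] == cls]
        n = len(grp)
        if n == 0:
            rows.append({"class": cls, "n": 0, "empty": True})
            continue
        x = grp["n_networks"].to_numpy(dtype=float)
        mean = float(x.mean())
        if n > 1 and x.std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + confidence / 2, df=n - 1) * x.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        row = {
            "class": cls,
            "n": n,
            "empty": False,
            "mean_n_networks": mean,
            "ci_lo": mean - half,
            "ci_hi": mean + half,
            "pct_multi_network": 100.0 * float((x > 1).mean()),
        }
        for c in flag_cols:
            row[f"pct_{c}"] = 100.0 * float(grp[c].mean())
        rows.append(row)
    return pd.DataFrame(rows)
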