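"""End-to-end pipeline: simulate/load → ingest → fit → select → report.

A single :class:`PipelineConfig` (constructible from a YAML or JSON file)
wires every stage: cohort input (CSV paths or a simulation block), class
enumeration and multi-start/convergence settings, the minimum-class-size
floor, the weekly-subsampling switch, and the network-grouping table.  Each
stage writes its artifact into the run directory, and a machine-readable
``summary.json`` collects the headline numbers.  Identical config and seed
give a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coil as coil_mod
from . import compare as compare_mod
from . import ingest, lcga, networks, selection
from .simulate import SimConfig, generate_atlas, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    # input: either a directory of CSVs ...
    data_dir: str | None = None
    atlas_csv: str | None = None
    # ... or simulation settings
    simulate: SimConfig | None = None
    atlas_nodes: int = 264

    g_max: int = 6
    n_starts: int = 100
    max_iter: int = 1000
    conv_b: float = 1e-4
    conv_l: float = 1e-4
    conv_g: float = 1e-4
    min_class_fraction: float = 0.05
    weekly_subsample: bool = False
    include_session0: bool = True
    network_groups: dict = field(
        default_factory=lambda: {k: list(v) for k, v in networks.DEFAULT_NETWORK_GROUPS.items()}
    )
    n_band_draws: int = 200
    seed: int = 0
    out_dir: str = "tmstraj_run"

    def validate(self) -> None:
        if not 1 <= self.g_max <= 10:
            raise ValueError("g_max must be in 1..10")
        for name in ("conv_b", "conv_l", "conv_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.min_class_fraction < 0.5:
            raise ValueError("min_class_fraction must be in [0, 0.5)")
        if self.data_dir is None and self.simulate is None:
            raise ValueError("either data_dir or a simulate block is required")


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML or JSON file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.simulate = SimConfig(**sim)
    return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _load_tables(config: PipelineConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate)
        cohort = generate_cohort(sim)
        atlas = (
            pd.read_csv(config.atlas_csv)
            if config.atlas_csv
            else generate_atlas(config.atlas_nodes, seed=sim.seed)
        )
        return cohort.ratings, cohort.metadata, cohort.coil, cohort.targets, cohort.outcomes, atlas
    d = Path(config.data_dir)
    ratings = ingest.read_ratings_csv(d / "ratings.csv")
    metadata = pd.read_csv(d / "metadata.csv")
    coil = pd.read_csv(d / "coil.csv")
    targets = pd.read_csv(d / "targets.csv")
    outcomes = pd.read_csv(d / "outcomes.csv")
    atlas = pd.read_csv(config.atlas_csv if config.atlas_csv else d / "atlas.csv")
    return ratings, metadata, coil, targets, outcomes, atlas


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the summary dict.

    Artifacts written to ``config.out_dir``: inclusion report, per-G fit
    JSONs and posterior CSVs, the selection rationale table, adequacy
    indices, predicted trajectories, dispersion metrics, network scores,
    comparison tables and ``summary.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        ratings, metadata, coil, targets, outcomes, atlas = _load_tables(config)

        stage = "ingest"
        filtered, report = ingest.apply_inclusion(ratings, metadata)
        _write_json(report.to_dict(), out / "inclusion_report.json")
        recoded = ingest.recode_ordinal(filtered, anchor_session0=config.include_session0)
        if config.weekly_subsample:
            recoded = ingest.subsample_weekly(recoded)

        stage = "fit"
        settings = lcga.FitSettings(
            n_starts=config.n_starts,
            max_iter=config.max_iter,
            conv_b=config.conv_b,
            conv_l=config.conv_l,
            conv_g=config.conv_g,
            seed=config.seed,
        )
        fits = []
        fit_dir = out / "fits"
        fit_dir.mkdir(exist_ok=True)
        for g in range(1, config.g_max + 1):
            fit = lcga.fit_lcga(
                recoded, g, settings=settings, warm_start=fits[-1] if fits else None
            )
            fit.to_json(fit_dir / f"fit_G{g}.json")
            fit.posteriors_frame().to_csv(fit_dir / f"posteriors_G{g}.csv", index=False)
            fits.append(fit)

        stage = "select"
        selected, rationale = selection.select_model(fits, config.min_class_fraction)
        rationale.to_csv(out / "selection.csv", index=False)

        stage = "adequacy"
        adq = selection.adequacy(selected)
        _write_json(adq.to_dict(), out / "adequacy.json")

        stage = "trajectories"
        try:
            H = lcga.observed_information(selected, recoded)
            vcov = np.linalg.pinv(H)
            traj = lcga.predict_trajectory(
                selected, vcov=vcov, n_draws=config.n_band_draws, seed=config.seed
            )
        except np.linalg.LinAlgError:
            traj = lcga.predict_trajectory(selected, vcov=None)
        traj.to_csv(out / "trajectories.csv", index=False)

        assignments = pd.Series(
            selected.assignments, index=pd.Index(selected.subject_ids, name="subject_id")
        )

        stage = "coil"
        disp = coil_mod.dispersion_table(coil, targets)
        disp.to_csv(out / "dispersion.csv", index=False)

        stage = "networks"
        groups = {k: tuple(v) for k, v in config.network_groups.items()}
        scores = networks.score_cohort(targets, disp, atlas, seed=config.seed, groups=groups)
        scores.to_csv(out / "network_scores.csv", index=False)
        scored = scores[scores["subject_id"].isin(assignments.index)]
        net_summary = networks.class_network_summary(scored, assignments)
        net_summary.to_csv(out / "network_summary.csv", index=False)

        stage = "compare"
        comparisons, corr = _comparisons(
            selected, assignments, disp, scores, outcomes, out
        )

        stage = "summary"
        summary = {
            "seed": config.seed,
            "n_included": report.n_included,
            "selected_G": selected.G,
            "selected_loglik": selected.loglik,
            "selected_bic": selection.bic(selected),
            "converged": bool(selected.converged),
            "class_fractions": [float(v) for v in selected.class_fractions],
            "adequacy": adq.to_dict(),
            "selection_table": rationale.to_dict(orient="records"),
            "dispersion_anova_p": comparisons["sd_dist_session1_mm"]["p_value"],
            "networks_anova_p": comparisons["n_networks"]["p_value"],
            "dispersion_by_class_mm": comparisons["sd_dist_session1_mm"]["group_means_backtransformed"],
            "networks_by_class": comparisons["n_networks"]["group_means"],
            "hdrs_correlation": corr,
        }
        _write_json(summary, out / "summary.json")
        return summary
    except Exception as err:  # noqa: BLE001 - annotate with failing stage
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err


def _comparisons(selected, assignments, disp, scores, outcomes, out: Path):
    """Class comparisons for dispersion, networks and outcome reductions."""
    rows = []
    results = {}

    dd = disp.set_index("subject_id").reindex(assignments.index)
    cls = assignments.to_numpy()

    for var, cube in [
        ("mean_dist_target_mm", True),
        ("mean_dist_session1_mm", True),
        ("sd_dist_session1_mm", True),
        ("within_session_sd_mm", True),
    ]:
        res = compare_mod.compare_classes(
            dd[var].to_numpy(), cls, kind="continuous", variable=var, cube_root=cube
        )
        back = {
            int(k): float(coil_mod.cube_root_summary(
                dd[var].to_numpy()[(cls == k) & np.isfinite(dd[var].to_numpy())]
            )["mean_backtransformed"])
            for k in sorted(set(cls))
        }
        results[var] = {
            "p_value": res.p_value,
            "statistic": res.statistic,
            "effect_size": res.effect_size,
            "group_means_backtransformed": back,
            "significant_pairs": res.significant_pairs(),
        }
        rows.append(_row(res))

    sc = scores.set_index("subject_id").reindex(assignments.index)
    res = compare_mod.compare_classes(
        sc["n_networks"].to_numpy(dtype=float), cls, kind="continuous", variable="n_networks"
    )
    results["n_networks"] = {
        "p_value": res.p_value,
        "statistic": res.statistic,
        "effect_size": res.effect_size,
        "group_means": {k: float(v) for k, v in res.group_means.items()},
        "significant_pairs": res.significant_pairs(),
    }
    rows.append(_row(res))

    red = compare_mod.reduction_and_response(outcomes)
    for scale in sorted(red["scale"].unique()):
        sub = red[red["scale"] == scale].set_index("subject_id").reindex(assignments.index)
        for week in compare_mod.FOLLOWUP_WEEKS:
            res = compare_mod.compare_classes(
                sub[f"reduction_w{week}"].to_numpy(),
                cls,
                kind="continuous",
                variable=f"{scale}_reduction_w{week}",
            )
            rows.append(_row(res))

    pd.DataFrame(rows).to_csv(out / "comparisons.csv", index=False)

    hdrs = red[red["scale"] == "HDRS17"][
        ["subject_id"] + [f"reduction_w{w}" for w in compare_mod.FOLLOWUP_WEEKS]
    ]
    s = disp.set_index("subject_id")["sd_dist_session1_mm"]
    corr_all = compare_mod.correlate_dispersion_outcome(s, hdrs)
    corr_excl = compare_mod.correlate_dispersion_outcome(
        s, hdrs, exclude_class=0, assignments=assignments
    )
    corr = {
        "whole_sample": corr_all.to_dict(orient="records"),
        "excluding_strong": corr_excl.to_dict(orient="records"),
    }
    return results, corr


def _row(res) -> dict:
    return {
        "variable": res.variable,
        "test": res.test,
        "statistic": res.statistic,
        "df": str(res.df),
        "p_value": res.p_value,
        "effect_size_name": res.effect_size_name,
        "effect_size": res.effect_size,
        "transform_applied": res.transform_applied,
        "significant_pairs": ";".join(f"{a}-{b}" for a, b in res.significant_pairs()),
        "group_means": json.dumps(res.group_means, sort_keys=True),
    }
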