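"""End-to-end orchestration: clean -> metrics -> home range -> covariates ->
network -> inference, from one configuration, with a run manifest.

The pipeline consumes either files on disk (fix table, colony geometry,
chick metadata) or a named synthetic scenario, executes every stage in
order, writes each stage's table to the output directory and records a
manifest (seed, parameter values, config hash, per-filter removal counts,
package version) so that any run can be reproduced exactly.

A single global seed fans out to per-stage seeds by fixed offsets, so each
stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cleaning import CleanConfig, clean, resample
from .colony_geometry import density_covariates, fence_threshold
from .home_range import home_range_table
from .movement_metrics import (
    daily_movement_table,
    movement_activity,
    repeatability,
    step_distances,
)
from .social_network import detect_associations, edge_list, node_metrics, round_times
from .tracking_io import read_chicks, read_colony, read_fixes, write_table

logger = logging.getLogger("colonytrack")

SEED_OFFSETS = {"simulate": 1, "bootstrap": 2, "permutation": 3}


@dataclass
class PipelineConfig:
    """Everything one run needs; all thresholds at their study defaults."""

    outdir: str = "colonytrack_out"
    # inputs: either the three paths, or a scenario name
    fixes_path: str | None = None
    colony_path: str | None = None
    chicks_path: str | None = None
    scenario: str | None = None
    # stage parameters
    clean: CleanConfig = field(default_factory=CleanConfig)
    association_threshold_m: float = 0.6
    kud_level: float = 0.95
    kud_resolution: int = 200
    n_boot: int = 1000
    n_perm: int = 10000
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest/report dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": dataclasses.asdict(config),
    }

    # ---- inputs -----------------------------------------------------------
    if config.scenario:
        from .synthetic_data import make_scenario

        bundle = make_scenario(config.scenario, seed=config.seed + SEED_OFFSETS["simulate"])
        fixes, colony, chicks = bundle.observed, bundle.colony, bundle.chicks
        from .tracking_io import validate_fixes, write_colony

        fixes = validate_fixes(fixes)
        write_table(fixes, outdir / "fixes_raw.csv")
        write_colony(colony, outdir / "colony.json")
        write_table(chicks, outdir / "chicks.csv")
    else:
        for name in ("fixes_path", "colony_path", "chicks_path"):
            p = getattr(config, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"pipeline input {name} missing: {p!r}")
        fixes = read_fixes(config.fixes_path)
        colony = read_colony(config.colony_path)
        chicks = read_chicks(config.chicks_path)

    # ---- cleaning ---------------------------------------------------------
    n_raw = len(fixes)
    cleaned = clean(fixes, colony, config.clean)
    write_table(cleaned, outdir / "fixes_clean.csv")
    resampled = resample(cleaned, config.clean.resample_interval_s)
    write_table(resampled, outdir / "fixes_resampled.csv")
    report["cleaning"] = {"n_raw": n_raw, "n_clean": len(cleaned), "n_resampled": len(resampled)}

    # ---- movement metrics -------------------------------------------------
    interval = config.clean.resample_interval_s
    activity = (
        resampled.groupby("tag_id", group_keys=False)[["t", "x", "y"]]
        .apply(lambda g: movement_activity(g, interval))
        .rename("movement_activity")
        .rename_axis("chick_id")
        .reset_index()
    )
    daily = daily_movement_table(resampled, interval)
    write_table(daily, outdir / "daily_movement.csv")
    try:
        rep = repeatability(daily, n_boot=config.n_boot,
                            seed=config.seed + SEED_OFFSETS["bootstrap"])
        report["repeatability"] = {
            "R": rep.R, "ci_low": rep.ci_low, "ci_high": rep.ci_high, "n_boot": rep.n_boot,
        }
    except ValueError as exc:  # e.g. a single tracking day
        logger.warning("repeatability skipped: %s", exc)
        report["repeatability"] = {"skipped": str(exc)}

    # ---- home range -------------------------------------------------------
    hr = home_range_table(resampled, level=config.kud_level, resolution=config.kud_resolution)
    write_table(hr, outdir / "home_range.csv")

    # ---- covariates -------------------------------------------------------
    steps = np.concatenate(
        [step_distances(g, interval) for _, g in resampled.groupby("tag_id")]
    )
    thr = fence_threshold(float(steps.mean()), float(steps.std(ddof=1)))
    report["fence_threshold_m"] = thr
    cov = density_covariates(chicks, colony, fence_threshold_m=thr)
    write_table(cov, outdir / "covariates.csv")

    # ---- social network ---------------------------------------------------
    rounded = round_times(fixes)
    events = detect_associations(rounded, config.association_threshold_m)
    write_table(events, outdir / "association_events.csv")
    write_table(edge_list(events), outdir / "edges.csv")
    net = node_metrics(events, chicks)
    write_table(net, outdir / "node_metrics.csv")

    # ---- inference --------------------------------------------------------
    from . import inference as inf

    metrics = activity.merge(hr, on="chick_id").merge(net, on="chick_id")
    write_table(metrics, outdir / "metrics.csv")
    data = inf.prepare_model_data(metrics, chicks, cov)
    fits: dict[str, dict] = {}
    for name, spec in inf.STANDARD_MODELS.items():
        if "nn3_pre_x_post" in spec.fixed_terms:
            used_spec, fit = inf.drop_nonsig_interaction(spec, data)
        else:
            used_spec, fit = spec, inf.fit_model(spec, data)
        entry = {
            "terms": fit.terms.reset_index().to_dict(orient="records"),
            "variance_components": fit.variance_components,
            "n": fit.n,
            "converged": fit.converged,
            "interaction_kept": "nn3_pre_x_post" in used_spec.fixed_terms,
        }
        if name in ("degree", "strength") and config.n_perm > 0:
            perm = inf.node_permutation_test(
                used_spec, data, n_perm=config.n_perm,
                seed=config.seed + SEED_OFFSETS["permutation"],
            )
            entry["permutation"] = {
                t: {
                    "observed_coef": r.observed_coef,
                    "p_two": r.p_two,
                    "outside_central_95": r.outside_central_95,
                    "n_perm": r.n_perm,
                }
                for t, r in perm.items()
            }
        fits[name] = entry
    report["models"] = fits

    # sibling correlations of movement activity and home range
    act = activity.set_index("chick_id")["movement_activity"]
    try:
        sc = inf.sibling_correlation(act, chicks)
        sc_hr = inf.sibling_correlation(hr.set_index("chick_id")["area_m2"], chicks)
        report["sibling_correlation"] = {
            "movement_r": sc.r, "movement_p": sc.p,
            "homerange_r": sc_hr.r, "homerange_p": sc_hr.p, "n_pairs": sc.n_pairs,
        }
    except ValueError as exc:
        report["sibling_correlation"] = {"skipped": str(exc)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
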