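"""End-to-end orchestration: simulate -> analyze -> report.

Each stage is a pure function of the configuration (and the seed it
derives); :func:`run_pipeline` chains them and writes CSV report tables
shaped like the study's summary tables — LQ fit parameters, RBE at the
chosen survival level, per-species dose-averaged LET, neutron class
summaries — plus a comparisons table, a machine-readable JSON summary and
a plain-text log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, reference
from .beam import depth_dose_curve, let_vs_depth
from .config import PipelineConfig
from .design import EndpointKind
from .endpoints import apoptosis_excess, compare_groups, summarize_endpoint
from .io import (
    write_colony_counts,
    write_endpoint_data,
    write_let_spectra,
    write_neutron_spectrum,
)
from .letd import classify_neutrons, combine_species, dose_average_let
from .survival import compute_rbe, fit_lq, surviving_fractions
from .synthetic import (
    generate_colony_counts,
    generate_endpoint_data,
    generate_let_spectrum,
    generate_neutron_spectrum,
    generate_reference_colony_counts,
    solve_dose_shares,
)

log = logging.getLogger("protonrbe")

PROTON_LABELS = ("PBS1", "PBS2", "DS1", "DS2")


def _stage_seeds(seed: int, n: int = 12) -> list[int]:
    """Deterministic per-stage child seeds derived from the master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def simulate_stage(config: PipelineConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    """Generate colony counts (proton + reference) and endpoint data."""
    seeds = _stage_seeds(config.seed)
    design = config.experiment_design(seed=seeds[0])
    truth = config.truth_lq()
    colony = generate_colony_counts(design, truth, seed=seeds[0])
    ref_label = config.analysis.reference_label
    if ref_label in truth:
        ref = generate_reference_colony_counts(
            truth[ref_label],
            doses=config.co60_doses_gy,
            runs=design.runs,
            wells_per_condition=design.wells_per_condition,
            seeded_cells=design.seeded_cells,
            plating_efficiency=design.plating_efficiency,
            seed=seeds[1],
            label=ref_label,
        )
        colony = pd.concat([colony, ref], ignore_index=True)
    endpoints = pd.concat(
        [
            generate_endpoint_data(design, kind, seed=seeds[2 + i])
            for i, kind in enumerate(EndpointKind)
        ],
        ignore_index=True,
    )
    write_colony_counts(colony, outdir / "colony_counts.csv")
    write_endpoint_data(endpoints, outdir / "endpoints.csv")
    log.info("simulate: %d colony rows, %d endpoint rows", len(colony), len(endpoints))
    return {"colony": colony, "endpoints": endpoints}


def beam_stage(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Depth-dose and LET-vs-depth curves for the configured beam."""
    e0 = config.beam.energy_mev
    pdd = depth_dose_curve(
        e0,
        grid_step=config.beam.grid_step_cm,
        straggling_sigma=config.beam.straggling_sigma_cm,
        positions=tuple(reference.POSITION_DEPTH_CM.values()),
    )
    let = let_vs_depth(e0, pdd.depth)
    df = pd.DataFrame(
        {"depth_cm": pdd.depth, "dose_pct": pdd.dose, "let_kev_um": let}
    )
    df.to_csv(outdir / "depth_dose.csv", index=False)
    log.info("beam: E0=%.1f MeV, peak at %.2f cm", e0, pdd.peak_depth)
    return df


def letd_stage(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Construct LET spectra per mode/position and tabulate LET_d."""
    seeds = _stage_seeds(config.seed)
    rows = []
    for i, ((mode, position), targets) in enumerate(sorted(reference.LETD_TARGETS.items())):
        shares = solve_dose_shares(targets, reference.LETD_ALL_PARTICLES[(mode, position)])
        spectra = generate_let_spectrum(
            targets, shares, seed=seeds[6] + i, position=position, mode=mode
        )
        write_let_spectra(spectra, outdir / f"let_spectra_{mode}{position}.csv")
        for species, spec in spectra.items():
            rows.append(
                (mode, position, species, dose_average_let(spec).letd)
            )
        rows.append(
            (mode, position, "all particles", combine_species(spectra.values()).letd)
        )
    df = pd.DataFrame(rows, columns=["mode", "position", "species", "letd_kev_um"])
    table = df.pivot_table(
        index="species", columns=["position", "mode"], values="letd_kev_um", sort=False
    )
    table.to_csv(outdir / "letd_table.csv")
    df.to_csv(outdir / "letd_long.csv", index=False)
    log.info("letd: %d species x condition entries", len(df))
    return df


def neutron_stage(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Sample neutron spectra per mode/position and classify them."""
    seeds = _stage_seeds(config.seed)
    rows = []
    for i, (mode, position) in enumerate(sorted(reference.NEUTRON_CLASS_PCT)):
        fr = reference.neutron_class_fractions(mode, position)
        spec = generate_neutron_spectrum(
            fr, config.neutron_samples, seed=seeds[7] + i, position=position, mode=mode
        )
        write_neutron_spectrum(spec, outdir / f"neutrons_{mode}{position}.csv")
        cls = classify_neutrons(spec)
        for label in cls.counts:
            rows.append(
                (
                    mode,
                    position,
                    label,
                    cls.counts[label],
                    cls.percentages[label],
                    cls.mean_wr,
                )
            )
    df = pd.DataFrame(
        rows, columns=["mode", "position", "class", "count", "pct", "mean_wr"]
    )
    df.to_csv(outdir / "neutron_classes.csv", index=False)
    log.info("neutrons: mean w_R by condition: %s",
             df.groupby(["mode", "position"])["mean_wr"].first().to_dict())
    return df


def survival_stage(
    config: PipelineConfig, colony: pd.DataFrame, outdir: Path
) -> tuple[pd.DataFrame, dict]:
    """Surviving fractions, LQ fits per condition, and the RBE table."""
    obs = surviving_fractions(colony, pooling=config.analysis.pooling)
    obs.to_csv(outdir / "survival_observations.csv", index=False)
    fits = {}
    for label, grp in obs.groupby("label"):
        fits[label] = fit_lq(grp, scale=config.analysis.fit_scale, label=str(label))
    fit_df = pd.DataFrame(
        [
            {
                "label": f.label,
                "alpha": f.alpha,
                "se_alpha": f.se_alpha,
                "beta": f.beta,
                "se_beta": f.se_beta,
                "r_squared": f.r_squared,
            }
            for f in fits.values()
        ]
    )
    fit_df.to_csv(outdir / "lq_fits.csv", index=False)

    ref_label = config.analysis.reference_label
    rbe_rows = []
    if ref_label in fits:
        for label in PROTON_LABELS:
            if label not in fits:
                continue
            est = compute_rbe(fits[ref_label], fits[label], config.analysis.survival_level)
            rbe_rows.append(
                {
                    "test": label,
                    "reference": ref_label,
                    "survival_level": est.survival_level,
                    "rbe": est.rbe,
                    "se": est.se,
                    "iso_dose_ref_gy": est.iso_dose_ref,
                    "iso_dose_test_gy": est.iso_dose_test,
                }
            )
    rbe_df = pd.DataFrame(rbe_rows)
    rbe_df.to_csv(outdir / "rbe.csv", index=False)
    log.info("survival: fitted %d conditions; %d RBE estimates", len(fits), len(rbe_df))
    return obs, {"fits": fits, "rbe": rbe_df}


def stats_stage(
    config: PipelineConfig,
    colony: pd.DataFrame,
    endpoints: pd.DataFrame,
    outdir: Path,
) -> pd.DataFrame:
    """Mode-vs-mode comparisons (F-then-t) and endpoint summaries."""
    alpha = config.analysis.alpha_level
    rows = []

    # survival: PBS vs DS per position and dose, run-level mean SF
    obs_wells = colony[colony["position"].isin([1, 2])].copy()
    for run_key, rgrp in obs_wells.groupby(["mode", "position", "run"]):
        ctrl = rgrp[rgrp["dose_gy"] == 0]
        pe = ctrl["colonies"].sum() / ctrl["seeded"].sum()
        obs_wells.loc[rgrp.index, "sf"] = (
            rgrp["colonies"] / rgrp["seeded"] / pe
        )
    for (position, dose), grp in obs_wells[obs_wells["dose_gy"] > 0].groupby(
        ["position", "dose_gy"]
    ):
        x = grp[grp["mode"] == "PBS"].groupby("run")["sf"].mean().to_numpy()
        y = grp[grp["mode"] == "DS"].groupby("run")["sf"].mean().to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        res = compare_groups(
            x, y, alpha_level=alpha, label_x=f"PBS{position}", label_y=f"DS{position}"
        )
        rows.append(
            {
                "endpoint": "surviving_fraction",
                "group1": res.label_x,
                "group2": res.label_y,
                "dose_gy": dose,
                "time_h": 0.0,
                "f": res.f_statistic,
                "p_f": res.p_f,
                "branch": "pooled" if res.equal_variance_assumed else "welch",
                "t": res.t_statistic,
                "p_t": res.p_t,
                "significant": res.significant,
            }
        )

    # endpoints: PBS vs DS per kind/position/dose/time over run x replicate
    for (kind, position, dose, t), grp in endpoints[endpoints["dose_gy"] > 0].groupby(
        ["endpoint", "position", "dose_gy", "time_h"]
    ):
        x = grp[grp["mode"] == "PBS"]["value"].to_numpy()
        y = grp[grp["mode"] == "DS"]["value"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        try:
            res = compare_groups(
                x, y, alpha_level=alpha,
                label_x=f"PBS{position}", label_y=f"DS{position}",
            )
        except ValueError:
            continue  # degenerate group (zero variance in both)
        rows.append(
            {
                "endpoint": kind,
                "group1": res.label_x,
                "group2": res.label_y,
                "dose_gy": dose,
                "time_h": t,
                "f": res.f_statistic,
                "p_f": res.p_f,
                "branch": "pooled" if res.equal_variance_assumed else "welch",
                "t": res.t_statistic,
                "p_t": res.p_t,
                "significant": res.significant,
            }
        )
    comp = pd.DataFrame(rows)
    comp.to_csv(outdir / "comparisons.csv", index=False)

    summary = summarize_endpoint(endpoints)
    summary.to_csv(outdir / "endpoint_summary.csv", index=False)

    apo = endpoints[endpoints["endpoint"] == EndpointKind.APOPTOSIS_TOTAL_PCT.value]
    if not apo.empty:
        apoptosis_excess(apo).to_csv(outdir / "apoptosis_excess.csv", index=False)
    log.info("stats: %d comparisons (%d significant)",
             len(comp), int(comp["significant"].sum()) if len(comp) else 0)
    return comp


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the full report bundle to `outdir`.

    Returns a summary dict (also written as ``summary.json``). Identical
    config + seed give byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        cfg_json = config.model_dump_json()
        cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
        log.info(
            "protonrbe %s (python %s, numpy %s) seed=%d config_hash=%s",
            __version__, platform.python_version(), np.__version__,
            config.seed, cfg_hash,
        )
        data = simulate_stage(config, outdir)
        beam_stage(config, outdir)
        letd_df = letd_stage(config, outdir)
        neutron_df = neutron_stage(config, outdir)
        obs, surv = survival_stage(config, data["colony"], outdir)
        comp = stats_stage(config, data["colony"], data["endpoints"], outdir)

        summary = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": cfg_hash,
            "rbe": surv["rbe"].to_dict(orient="records"),
            "lq_fits": {
                label: {"alpha": f.alpha, "beta": f.beta,
                        "se_alpha": f.se_alpha, "se_beta": f.se_beta,
                        "r_squared": f.r_squared}
                for label, f in surv["fits"].items()
            },
            "letd_all_particles": {
                f"{m}{p}": v
                for (m, p, sp, v) in letd_df.itertuples(index=False)
                if sp == "all particles"
            },
            "neutron_mean_wr": {
                f"{m}{p}": wr
                for (m, p, c, cnt, pct, wr) in neutron_df.itertuples(index=False)
                if c == "<=1 MeV"
            },
            "n_significant_comparisons": int(comp["significant"].sum())
            if len(comp)
            else 0,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
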