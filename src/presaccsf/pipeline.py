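"""End-to-end pipeline: simulate → saccade QC → BIP → HBM → attributes → stats.

Each stage is a standalone function reading its inputs from, and writing its
outputs to, a run directory, so any stage can be re-run from persisted
artifacts; :func:`run_pipeline` chains them and writes a manifest recording
the configuration snapshot, master and per-stage seeds, convergence flags and
output paths.  All tables are CSV; the manifest and the BIP population
summary are JSON.  A fixed master seed makes the whole run reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bip import BIPFit, BIPSummary, bip_population_summaries, fit_bip
from .eye import summarize_saccades
from .hbm import MCMCConfig, build_priors, final_estimates, hbm_data_from_trials, run_mcmc
from .qcsf import DEFAULT_GRID_SHAPE, ParamGrid
from .stats import benefit_curve, fdr_bh, lrt_flat_null, perm_paired_t, perm_rm_anova
from .synth import (
    EffectConfig,
    ExperimentConfig,
    config_to_dict,
    make_population,
    simulate_experiment,
)

__all__ = [
    "PipelineOptions",
    "run_pipeline",
    "stage_simulate",
    "stage_saccades",
    "stage_bip",
    "stage_hbm",
    "stage_stats",
]

ATTRIBUTES = ("peak_cs", "peak_sf", "bandwidth_fwhm", "cutoff_sf", "aulcsf")


@dataclass(frozen=True)
class PipelineOptions:
    """Scales and schedules for one pipeline run."""

    experiment: ExperimentConfig = ExperimentConfig()
    effects: EffectConfig = EffectConfig()
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    mcmc: MCMCConfig = MCMCConfig().reduced()
    n_perm: int = 1000
    qc: str = "detect"


def _stage_seed(master_seed: int, stage: str) -> int:
    offsets = {"simulate": 0, "hbm": 101, "stats": 202}
    return int((master_seed * 1000 + offsets[stage]) % (2**31 - 1))


def stage_simulate(outdir: Path, seed: int, opts: PipelineOptions) -> Path:
    """Ground-truth population + full adaptive experiment; writes trials.csv
    and truth.csv."""
    outdir.mkdir(parents=True, exist_ok=True)
    population = make_population(opts.experiment, opts.effects, seed=seed)
    trials, _ = simulate_experiment(
        population,
        opts.experiment,
        seed=seed,
        grid=ParamGrid.regular(opts.grid_shape),
        qc=opts.qc,
    )
    trials.to_csv(outdir / "trials.csv", index=False)
    rows = []
    for obs in population:
        for (loc, instr), params in obs.truth.items():
            rows.append(
                {
                    "participant": obs.participant,
                    "location": loc,
                    "instruction": instr,
                    "log_peak_cs": params.log_peak_cs,
                    "log_peak_sf": params.log_peak_sf,
                    "log_bandwidth": params.log_bandwidth,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "truth.csv", index=False)
    return outdir / "trials.csv"


def stage_saccades(outdir: Path) -> Path:
    """Per-direction saccade parameter summary from the QC'd trial table."""
    trials = pd.read_csv(outdir / "trials.csv")
    summarize_saccades(trials).to_csv(outdir / "saccade_summary.csv", index=False)
    return outdir / "saccade_summary.csv"


def stage_bip(outdir: Path, opts: PipelineOptions) -> Path:
    """Independent grid-Bayes fit per individual; writes bip_fits.csv and the
    population summary JSON that seeds the HBM priors."""
    trials = pd.read_csv(outdir / "trials.csv")
    data = hbm_data_from_trials(trials)
    grid = ParamGrid.regular(opts.grid_shape)
    included = trials[trials["qc_status"] == "included"]
    fits = []
    rows = []
    for _, lab in data.labels.iterrows():
        sub = included[
            (included["participant"] == lab["participant"])
            & (included["location"] == lab["location"])
            & (included["instruction"] == lab["instruction"])
        ]
        fit = fit_bip(sub, grid)
        fits.append(fit)
        row = {
            "participant": lab["participant"],
            "location": lab["location"],
            "instruction": lab["instruction"],
            "n_trials": fit.n_trials,
        }
        for k, name in enumerate(("log_peak_cs", "log_peak_sf", "log_bandwidth")):
            row[f"mean_{name}"] = fit.mean[k]
            row[f"sd_{name}"] = fit.sd[k]
        for a in range(3):
            for b in range(a, 3):
                row[f"cov_{a}{b}"] = fit.cov[a, b]
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "bip_fits.csv", index=False)
    summary = bip_population_summaries(fits)
    summary.to_json(outdir / "bip_summary.json")
    return outdir / "bip_summary.json"


def _load_bip_fits(outdir: Path, labels: pd.DataFrame) -> list[BIPFit]:
    df = pd.read_csv(outdir / "bip_fits.csv")
    fits = []
    for _, lab in labels.iterrows():
        row = df[
            (df["participant"] == lab["participant"])
            & (df["location"] == lab["location"])
            & (df["instruction"] == lab["instruction"])
        ].iloc[0]
        mean = np.array([row[f"mean_{n}"] for n in ("log_peak_cs", "log_peak_sf", "log_bandwidth")])
        sd = np.array([row[f"sd_{n}"] for n in ("log_peak_cs", "log_peak_sf", "log_bandwidth")])
        cov = np.zeros((3, 3))
        for a in range(3):
            for b in range(a, 3):
                cov[a, b] = cov[b, a] = row[f"cov_{a}{b}"]
        fits.append(BIPFit(mean=mean, sd=sd, cov=cov, n_trials=int(row["n_trials"])))
    return fits


def stage_hbm(outdir: Path, seed: int, opts: PipelineOptions, save_samples: bool = False) -> dict:
    """Fit the hierarchical model; writes estimates.csv (+ optional samples.csv)
    and returns convergence information."""
    trials = pd.read_csv(outdir / "trials.csv")
    data = hbm_data_from_trials(trials)
    summary = BIPSummary.from_json(outdir / "bip_summary.json")
    priors = build_priors(summary)
    init_fits = _load_bip_fits(outdir, data.labels)
    samples = run_mcmc(data, priors, opts.mcmc, seed=seed, init_fits=init_fits)
    estimates = final_estimates(samples)
    estimates.to_csv(outdir / "estimates.csv", index=False)
    if save_samples:
        samples.to_dataframe().to_csv(outdir / "samples.csv", index=False)
    info = {
        "converged": bool(samples.converged),
        "max_rhat": float(samples.rhat.max()),
        "total_retained_draws": int(samples.total_retained),
        "mean_accept_rate": float(samples.accept_rate.mean()),
    }
    with open(outdir / "hbm_info.json", "w") as fh:
        json.dump(info, fh, indent=2)
    return info


def stage_stats(outdir: Path, seed: int, opts: PipelineOptions) -> Path:
    """Permutation ANOVAs and post hoc tests on the attribute table, the
    presaccadic benefit curves, and the flat-CSF goodness-of-fit test."""
    estimates = pd.read_csv(outdir / "estimates.csv")
    trials = pd.read_csv(outdir / "trials.csv")

    rows = []
    for attr in ATTRIBUTES:
        res = perm_rm_anova(
            estimates, attr, ["location", "instruction"], n_perm=opts.n_perm, seed=seed
        )
        for r in res.values():
            rows.append(
                {
                    "attribute": attr,
                    "effect": r.effect,
                    "test": "rm_anova",
                    "statistic": r.statistic,
                    "df1": r.df[0],
                    "df2": r.df[1],
                    "p": r.p,
                    "effect_size": r.effect_size,
                    "n_perm": r.n_perm,
                    "seed": r.seed,
                }
            )
        # post hoc: presaccadic effect per location, and location pairs
        posthoc = []
        wide = estimates.pivot_table(
            index="participant", columns=["location", "instruction"], values=attr
        )
        for loc in sorted(estimates["location"].unique()):
            t = perm_paired_t(
                wide[(loc, "saccade")].to_numpy(),
                wide[(loc, "fixation")].to_numpy(),
                n_perm=opts.n_perm,
                seed=seed + 7,
                effect=f"saccade-fixation @ {loc}",
            )
            posthoc.append(t)
        by_loc = estimates.groupby(["participant", "location"])[attr].mean().unstack()
        locs = sorted(by_loc.columns)
        for i in range(len(locs)):
            for j in range(i + 1, len(locs)):
                t = perm_paired_t(
                    by_loc[locs[i]].to_numpy(),
                    by_loc[locs[j]].to_numpy(),
                    n_perm=opts.n_perm,
                    seed=seed + 11,
                    effect=f"{locs[i]}-{locs[j]}",
                )
                posthoc.append(t)
        adj = fdr_bh([t.p for t in posthoc])
        for t, pa in zip(posthoc, adj):
            rows.append(
                {
                    "attribute": attr,
                    "effect": t.effect,
                    "test": "paired_t",
                    "statistic": t.statistic,
                    "df1": t.df[0],
                    "df2": np.nan,
                    "p": t.p,
                    "p_fdr": pa,
                    "effect_size": t.effect_size,
                    "n_perm": t.n_perm,
                    "seed": t.seed,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "stats.csv", index=False)

    benefit = benefit_curve(estimates, n_perm=opts.n_perm, seed=seed + 13)
    benefit["summary"].to_csv(outdir / "benefit_summary.csv", index=False)
    benefit["location_tests"].to_csv(outdir / "benefit_tests.csv", index=False)

    lrt = lrt_flat_null(trials, estimates)
    with open(outdir / "lrt.json", "w") as fh:
        json.dump(lrt, fh, indent=2)
    return outdir / "stats.csv"


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    opts: PipelineOptions | None = None,
    save_samples: bool = False,
) -> dict:
    """Run every stage in order and write the run manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    opts = opts if opts is not None else PipelineOptions()
    outdir = Path(outdir)
    seeds = {s: _stage_seed(seed, s) for s in ("simulate", "hbm", "stats")}
    stage_simulate(outdir, seeds["simulate"], opts)
    stage_saccades(outdir)
    stage_bip(outdir, opts)
    hbm_info = stage_hbm(outdir, seeds["hbm"], opts, save_samples=save_samples)
    stage_stats(outdir, seeds["stats"], opts)
    manifest = {
        "version": __version__,
        "master_seed": seed,
        "stage_seeds": seeds,
        "config": config_to_dict(opts.experiment, opts.effects),
        "grid_shape": list(opts.grid_shape),
        "mcmc": asdict(opts.mcmc),
        "n_perm": opts.n_perm,
        "qc": opts.qc,
        "hbm": hbm_info,
        "outputs": {
            name: str(outdir / f"{name}.csv")
            for name in (
                "trials",
                "saccade_summary",
                "bip_fits",
                "estimates",
                "stats",
                "benefit_summary",
                "benefit_tests",
            )
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
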