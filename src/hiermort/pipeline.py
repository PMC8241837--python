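"""End-to-end orchestration: simulate/load, screen, rates, fit Models I-V.

The run bundle written to the output directory mirrors the reporting layout
of a multilevel mortality analysis: descriptive rate tables, a collinearity
report, per-model fixed-effect (IRR) panels, a random-effects summary per
outcome (variance, VPC, MIRR, explained variation, DIC, sample sizes),
chain-diagnostic arrays, and a machine-readable manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effects
from .episodes import SplitGrid, split_episodes
from .lifetable import mortality_rate, stratified_rates
from .model import MCMCSettings, ModelSpec, fit_mcmc
from .screen import collinearity_screen
from .simulate import Covariate, SimConfig, read_records, simulate_dataset, write_records

__all__ = ["RunConfig", "StageError", "run", "make_fixture", "load_run_config",
           "infer_covariates", "OUTCOME_HORIZONS", "FIXTURE_PRESETS"]

OUTCOME_HORIZONS = {"inm": 12.0, "u5m": 60.0}


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Exactly one of ``sim`` / ``input_csv`` supplies the child records."""

    sim: SimConfig | None = None
    input_csv: str | None = None
    covariates: tuple[Covariate, ...] | None = None
    outcomes: tuple[str, ...] = ("inm", "u5m")
    models: tuple[int, ...] = (1, 2, 3, 4, 5)
    grid: str = "monthly"
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    outdir: str = "hiermort_results"
    seed: int = 0
    screen_cutoff: float = 0.6
    verbose: bool = False

    def __post_init__(self):
        if (self.sim is None) == (self.input_csv is None):
            raise ValueError("exactly one of sim / input_csv must be given")
        bad = set(self.outcomes) - set(OUTCOME_HORIZONS)
        if bad:
            raise ValueError(f"unknown outcomes {sorted(bad)}")
        if self.grid not in ("monthly", "event-times"):
            raise ValueError("grid must be 'monthly' or 'event-times'")


def infer_covariates(records: pd.DataFrame) -> tuple[Covariate, ...]:
    """Recover covariate metadata from a record CSV.

    The tier is inferred from constancy within units (constant within every
    state -> state tier, within every neighbourhood -> neighbourhood tier,
    else child tier); the most frequent level becomes the reference, and
    observed frequencies the prevalences.
    """
    skip = {"state_id", "neigh_id", "child_id", "t_obs_months", "event"}
    covs = []
    for col in records.columns:
        if col in skip or pd.api.types.is_numeric_dtype(records[col]):
            continue
        per_state = records.groupby("state_id")[col].nunique()
        per_neigh = records.groupby("neigh_id")[col].nunique()
        if (per_state <= 1).all():
            tier = "state"
            freqs = records.drop_duplicates("state_id")[col].value_counts()
        elif (per_neigh <= 1).all():
            tier = "neighbourhood"
            freqs = records.drop_duplicates("neigh_id")[col].value_counts()
        else:
            tier = "child"
            freqs = records[col].value_counts()
        levels = tuple(freqs.index)
        probs = tuple((freqs / freqs.sum()).to_numpy())
        covs.append(Covariate(col, tier, levels, probs))
    return tuple(covs)


def _windowed(records: pd.DataFrame, horizon: float) -> pd.DataFrame:
    out = records.copy()
    t = out["t_obs_months"].to_numpy(dtype=float)
    e = out["event"].to_numpy(dtype=bool)
    e_w = e & (t <= horizon)
    out["t_obs_months"] = np.minimum(t, horizon)
    out["event"] = e_w.astype(np.int8)
    return out


def _fit_seed(base: int, outcome: str, model: int) -> int:
    return (base * 1000 + 100 * (0 if outcome == "inm" else 1) + model) % (2 ** 31)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "fits": {},
                      "pcv_reference": "model1",
                      "versions": {"numpy": np.__version__,
                                   "pandas": pd.__version__}}
    t0 = time.time()

    def stage(name):
        manifest["stages"].append(name)

    # ---- data ----------------------------------------------------------
    try:
        stage("data")
        if config.sim is not None:
            records = simulate_dataset(config.sim)
            write_records(records, outdir / "records.csv")
            covariates = config.covariates or config.sim.covariates
        else:
            records = read_records(config.input_csv)
            covariates = config.covariates or infer_covariates(records)
    except Exception as exc:
        raise StageError("data", exc) from exc
    cov_names = [c.name for c in covariates]

    # ---- collinearity screen ------------------------------------------
    try:
        stage("screen")
        if len(cov_names) >= 2:
            report = collinearity_screen(
                records, cutoff=config.screen_cutoff, columns=cov_names,
                ordinal_orders={c.name: c.levels for c in covariates})
            report.correlations.to_csv(outdir / "screen_correlations.csv")
            with open(outdir / "screen_flags.json", "w") as fh:
                json.dump({"cutoff": report.cutoff,
                           "flagged": [list(f) for f in report.flagged],
                           "degenerate": report.degenerate}, fh, indent=2)
    except Exception as exc:
        raise StageError("screen", exc) from exc

    # ---- life tables ---------------------------------------------------
    try:
        stage("rates")
        overall = {"n": len(records), "percent": 100.0}
        for name, win in (("inmr", 12), ("u5mr", 60)):
            overall[name] = mortality_rate(records, win).rate_per_1000
        pd.DataFrame([overall]).to_csv(outdir / "rates_overall.csv", index=False)
        for cov in covariates:
            tab = stratified_rates(records, cov.name, windows=(12, 60))
            tab = tab.rename(columns={"rate_12": "inmr", "rate_60": "u5mr"})
            tab.to_csv(outdir / f"rates_by_{cov.name}.csv", index=False)
    except Exception as exc:
        raise StageError("rates", exc) from exc

    # ---- model fits ----------------------------------------------------
    for outcome in config.outcomes:
        horizon = OUTCOME_HORIZONS[outcome]
        try:
            stage(f"fit:{outcome}")
            recs = _windowed(records, horizon)
            grid = (SplitGrid.monthly(horizon) if config.grid == "monthly"
                    else SplitGrid.from_event_times(recs))
            eps = split_episodes(recs, grid)
            null_medians = None
            summary_rows = []
            for m in config.models:
                spec = ModelSpec.model(m, mcmc=config.mcmc)
                seed = _fit_seed(config.seed, outcome, m)
                t_fit = time.time()
                draws = fit_mcmc(spec, eps, covariates, seed=seed,
                                 verbose=config.verbose)
                irr = effects.irr_table(draws, include_intercept=True)
                irr.to_csv(outdir / f"fixed_effects_{outcome}_model{m}.csv",
                           index=False)
                s2v_med = float(np.median(draws.sigma2_v))
                s2u_med = float(np.median(draws.sigma2_u))
                vpc_state, vpc_neigh = effects.vpc(s2v_med, s2u_med)
                mirr_v = effects.mirr_interval(draws.sigma2_v)
                mirr_u = effects.mirr_interval(draws.sigma2_u)
                dic_res = effects.dic(draws, eps)
                row = {
                    "model": m,
                    "sigma2_state": s2v_med,
                    "sigma2_state_lo": float(np.percentile(draws.sigma2_v, 2.5)),
                    "sigma2_state_hi": float(np.percentile(draws.sigma2_v, 97.5)),
                    "sigma2_neigh": s2u_med,
                    "sigma2_neigh_lo": float(np.percentile(draws.sigma2_u, 2.5)),
                    "sigma2_neigh_hi": float(np.percentile(draws.sigma2_u, 97.5)),
                    "vpc_state": vpc_state, "vpc_neigh": vpc_neigh,
                    "mirr_state": mirr_v[0], "mirr_state_lo": mirr_v[1],
                    "mirr_state_hi": mirr_v[2],
                    "mirr_neigh": mirr_u[0], "mirr_neigh_lo": mirr_u[1],
                    "mirr_neigh_hi": mirr_u[2],
                    "dic": dic_res.dic, "p_d": dic_res.p_d, "dbar": dic_res.dbar,
                    "n_states": len(draws.state_ids),
                    "n_neighbourhoods": len(draws.neigh_ids),
                    "n_children": int(recs["child_id"].nunique()),
                }
                if m == 1:
                    null_medians = (s2v_med, s2u_med)
                    row["pcv_state"] = row["pcv_neigh"] = np.nan
                elif null_medians is not None:
                    row["pcv_state"] = effects.pcv(null_medians[0], s2v_med)
                    row["pcv_neigh"] = effects.pcv(null_medians[1], s2u_med)
                else:
                    row["pcv_state"] = row["pcv_neigh"] = np.nan
                summary_rows.append(row)
                diag = effects.diagnostics(draws.sigma2_v)
                diag_u = effects.diagnostics(draws.sigma2_u)
                if not diag["degenerate"] and not diag_u["degenerate"]:
                    nl = min(len(diag["acf"]), len(diag_u["acf"]))
                    pd.DataFrame({
                        "lag": np.arange(nl),
                        "acf_sigma2_state": diag["acf"][:nl],
                        "acf_sigma2_neigh": diag_u["acf"][:nl],
                    }).to_csv(outdir / f"diagnostics_{outcome}_model{m}.csv",
                              index=False)
                manifest["fits"][f"{outcome}_model{m}"] = {
                    "seed": seed,
                    "seconds": round(time.time() - t_fit, 3),
                    "acceptance_rates": draws.meta["acceptance_rates"],
                    "reference_for_pcv": m == 1,
                }
            pd.DataFrame(summary_rows).to_csv(
                outdir / f"model_summary_{outcome}.csv", index=False)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"fit:{outcome}", exc) from exc

    manifest["seconds_total"] = round(time.time() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# fixtures

def _paper_shape_config() -> SimConfig:
    # exact published totals: 1,389 clusters over 37 states, 33,924 children
    n_states = 37
    base, rem = divmod(1389, n_states)
    neigh_counts = tuple([base + 1] * rem + [base] * (n_states - rem))
    total_neigh = sum(neigh_counts)
    cbase, crem = divmod(33_924, total_neigh)
    child_counts = tuple([cbase + 1] * crem + [cbase] * (total_neigh - crem))
    return SimConfig(n_states=n_states,
                     neighbourhoods_per_state=neigh_counts,
                     children_per_neighbourhood=child_counts,
                     seed=2018)


FIXTURE_PRESETS = {
    "small": lambda: SimConfig(n_states=37, neighbourhoods_per_state=4,
                               children_per_neighbourhood=10, seed=2018),
    "paper-shape": _paper_shape_config,
}


def make_fixture(preset: str, outdir=None) -> tuple[pd.DataFrame, dict]:
    """Deterministic packaged fixture plus its generating truth."""
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(FIXTURE_PRESETS)}")
    config = FIXTURE_PRESETS[preset]()
    records = simulate_dataset(config)
    truth = {
        "preset": preset,
        "sim_config": json.loads(config.to_json()),
        "n_records": len(records),
        "n_events": int(records["event"].sum()),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_records(records, outdir / f"{preset}.csv")
        with open(outdir / f"{preset}_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return records, truth


# ---------------------------------------------------------------------------
# YAML run configuration

def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = {}
    if "sim" in raw:
        kwargs["sim"] = SimConfig.from_json(json.dumps(raw["sim"]))
    if "input_csv" in raw:
        kwargs["input_csv"] = raw["input_csv"]
    if "mcmc" in raw:
        kwargs["mcmc"] = MCMCSettings(**raw["mcmc"])
    for key in ("outcomes", "models"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("grid", "outdir", "seed", "screen_cutoff", "verbose"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)
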