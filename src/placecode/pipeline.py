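"""Simulate → analyze → compare orchestration with reproducible reports.

Each stage is a thin composition of the library modules: sessions are
simulated (or loaded), pushed through transient detection, tuning, von
Mises fitting and the information metrics, and per-neuron tables are pooled
by condition/animal for nested-bootstrap group comparisons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidConfigError, SubsampleThresholdError
from .information import (
    build_trial_tensor,
    decode_position,
    discrimination_threshold,
    population_fisher_info,
    shuffle_noise_correlations,
    single_cell_fisher_info,
    subsample_neurons,
)
from .session import Session, read_session, write_session
from .stats import NestedSample, bonferroni, nested_bootstrap_test
from .synthetic import SyntheticConfig, simulate_session
from .transients import compute_activity, detect_transients, lowpass_filter
from .tuning import deconvolution_noise_gain, deconvolve, tuning_vector
from .vonmises import fit_cell

__all__ = ["PipelineConfig", "run_simulate", "run_analyze", "run_compare"]


@dataclass
class PipelineConfig:
    """Effective parameters of a pipeline run; fully serialisable to YAML."""

    seed: int = 0
    conditions: list[dict] = field(default_factory=lambda: [
        {"name": "control", "gain": 1.0, "n_animals": 5},
        {"name": "enriched", "gain": 2.0, "n_animals": 5},
    ])
    simulate: dict = field(default_factory=dict)  # SyntheticConfig overrides
    # transient detection
    lowpass_cutoff: float = 2.0
    transient_start_k: float = 2.0
    transient_end_k: float = 0.5
    transient_iters: int = 3
    baseline_window_s: float = 30.0
    min_transient_s: float = 0.2
    # tuning
    n_bins_tuning: int = 100
    tuning_thresh_k: float = 2.0
    decay_tau: float = 1.0
    # curve fitting
    n_bins_curve: int = 20
    cv_splits: int = 10
    train_frac: float = 0.75
    # decoding / information
    n_bins_decode: int = 20
    decoder_C: float = 1.0
    subsample_n: int = 42
    subsample_draws: int = 10
    criterion: float = 0.70
    # group statistics
    n_boot: int = 100_000
    metrics: tuple = ("activity", "tuning_index", "fisher_info", "r2_cv")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(d["metrics"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _animal_seed(root_seed: int, condition_idx: int, animal_idx: int) -> int:
    # deterministic, collision-free for realistic sizes, below 2**31
    return (root_seed * 100_003 + condition_idx * 1_009 + animal_idx) % (2**31 - 1)


def run_simulate(config: PipelineConfig, out_dir) -> pd.DataFrame:
    """Simulate the designed experiment and write one session per animal.

    Returns (and writes) a manifest with one row per session: condition,
    animal id, gain, seed and file path. Ground truth goes to a CSV sidecar
    keyed by neuron id.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, cond in enumerate(config.conditions):
        for aj in range(int(cond.get("n_animals", 1))):
            seed = _animal_seed(config.seed, ci, aj)
            scfg = SyntheticConfig(**{**config.simulate,
                                      "gain": float(cond.get("gain", 1.0)),
                                      "rng_seed": seed})
            session, truth = simulate_session(scfg)
            name = f"{cond['name']}_m{aj}"
            session.metadata.update({"subject": name,
                                     "condition": cond["name"]})
            path = out / f"{name}.h5"
            session.metadata = {k: v for k, v in session.metadata.items()
                                if k != "config"}
            write_session(session, path)
            pd.DataFrame({
                "neuron": np.arange(scfg.n_neurons),
                "tuned": truth.tuned,
                "baseline": truth.baseline,
                "amplitude": truth.amplitude,
                "concentration": truth.concentration,
                "preferred_phase": truth.preferred_phase,
            }).to_csv(out / f"{name}_truth.csv", index=False)
            rows.append({"condition": cond["name"], "animal": name,
                         "gain": cond.get("gain", 1.0), "seed": seed,
                         "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def analyze_session(session: Session,
                    config: Optional[PipelineConfig] = None,
                    decode: bool = True) -> tuple[pd.DataFrame, dict]:
    """Run the full per-session analysis.

    Returns a per-neuron table (activity, tuning index, von Mises
    parameters, single-cell Fisher information) and a session summary dict
    (decoder accuracy, population Fisher information with and without noise
    correlations, discrimination threshold, cohort medians/means).
    """
    cfg = config or PipelineConfig()
    fr = session.frame_rate

    filtered = lowpass_filter(session.dff, fr, cutoff=cfg.lowpass_cutoff)
    tset = detect_transients(
        filtered, fr, start_k=cfg.transient_start_k,
        end_k=cfg.transient_end_k, n_iter=cfg.transient_iters,
        baseline_window_s=cfg.baseline_window_s,
        min_duration_s=cfg.min_transient_s)
    activity = compute_activity(tset, session)

    rates = deconvolve(session.dff, fr, decay_tau=cfg.decay_tau)
    sigma_rate = tset.final_sigma() * deconvolution_noise_gain(fr, cfg.decay_tau)
    tun = tuning_vector(rates, session, n_bins=cfg.n_bins_tuning,
                        thresh_k=cfg.tuning_thresh_k, sigma=sigma_rate)

    fits = [fit_cell(session.dff[n], session, n_bins=cfg.n_bins_curve,
                     n_splits=cfg.cv_splits, train_frac=cfg.train_frac,
                     seed=cfg.seed + n)
            for n in range(session.n_neurons)]

    tensor = build_trial_tensor(session, n_bins=cfg.n_bins_decode)
    fi = single_cell_fisher_info(tensor)
    fi_per_cm2 = fi / tensor.bin_width**2

    per_neuron = pd.DataFrame({
        "neuron": np.arange(session.n_neurons),
        "activity": activity,
        "tuning_index": tun.index,
        "B": [f.B for f in fits],
        "A": [f.A for f in fits],
        "kappa": [f.kappa for f in fits],
        "phi": [f.phi for f in fits],
        "r2_cv": [f.r2_cv for f in fits],
        "peak_width": [f.peak_width for f in fits],
        "well_fitted": [f.well_fitted for f in fits],
        "fisher_info": fi,
    })

    summary = {
        "subject": session.metadata.get("subject"),
        "condition": session.metadata.get("condition"),
        "n_neurons": session.n_neurons,
        "n_laps": int(session.lap_index.max()),
        "median_activity": float(np.median(activity)),
        "mean_tuning_index": float(tun.index.mean()),
        "mean_r2_cv": float(per_neuron["r2_cv"].mean()),
        "well_fitted_fraction": float(per_neuron["well_fitted"].mean()),
        "mean_fisher_info": float(np.mean(fi)),
        "threshold_cm": discrimination_threshold(
            float(np.mean(fi_per_cm2)), criterion=cfg.criterion),
    }
    wf = per_neuron[per_neuron["well_fitted"]]
    summary["mean_amplitude_well_fitted"] = (
        float(wf["A"].mean()) if len(wf) else np.nan)

    if decode:
        try:
            draws = subsample_neurons(tensor, n=cfg.subsample_n,
                                      n_draws=cfg.subsample_draws,
                                      seed=cfg.seed)
            sub_flag = False
        except SubsampleThresholdError:
            draws = []
            sub_flag = True
        result = decode_position(session, n_bins=cfg.n_bins_decode,
                                 n_splits=cfg.cv_splits,
                                 train_frac=cfg.train_frac,
                                 seed=cfg.seed, C=cfg.decoder_C)
        pop = population_fisher_info(tensor, result.weights)
        pop_shuf = population_fisher_info(
            shuffle_noise_correlations(tensor, seed=cfg.seed),
            result.weights)
        summary.update({
            "decoder_accuracy": result.accuracy,
            "subsample_below_threshold": sub_flag,
            "n_subsample_draws": len(draws),
            "population_fi": pop.mean,
            "population_fi_shuffled": pop_shuf.mean,
        })
    return per_neuron, summary


def run_analyze(session_path, config: Optional[PipelineConfig] = None,
                out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Analyze one session file; optionally write the per-neuron table and
    summary (with config hash, seed and version embedded) to ``out_dir``."""
    cfg = config or PipelineConfig()
    session = read_session(session_path)
    per_neuron, summary = analyze_session(session, cfg)
    summary.update({"config_hash": cfg.config_hash, "seed": cfg.seed,
                    "version": __version__})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = Path(session_path).stem
        per_neuron.to_csv(out / f"{stem}_neurons.csv", index=False)
        with open(out / f"{stem}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return per_neuron, summary


def run_compare(manifest: pd.DataFrame,
                config: Optional[PipelineConfig] = None,
                out_dir=None) -> dict:
    """Pool per-neuron metrics by condition/animal and test group contrasts.

    Every pair of conditions is compared on each configured metric with the
    nested bootstrap; Bonferroni correction is applied across all
    comparisons in the report. The amplitude contrast is restricted to
    well-fitted cells, mirroring how tuning-curve parameters are only
    meaningful where the model fits.
    """
    cfg = config or PipelineConfig()
    required = {"condition", "animal", "path"}
    if not required.issubset(manifest.columns):
        raise InvalidConfigError(f"manifest needs columns {sorted(required)}")

    tables: dict[str, dict[str, pd.DataFrame]] = {}
    for row in manifest.itertuples():
        path = Path(row.path)
        if not path.exists():
            raise InvalidConfigError(f"missing session for animal {row.animal}")
        per_neuron, _ = analyze_session(read_session(path), cfg, decode=False)
        tables.setdefault(row.condition, {})[row.animal] = per_neuron

    conditions = list(tables)
    comparisons = []
    for i, ca in enumerate(conditions):
        for cb in conditions[i + 1:]:
            for metric in cfg.metrics:
                def sample(cond):
                    vals = []
                    for animal, tbl in tables[cond].items():
                        col = tbl[metric]
                        if metric == "A":
                            col = tbl.loc[tbl["well_fitted"], "A"]
                        v = col.to_numpy()
                        v = v[np.isfinite(v)]
                        if v.size:
                            vals.append(v)
                    return NestedSample(cond, vals)
                res = nested_bootstrap_test(sample(ca), sample(cb),
                                            n_boot=cfg.n_boot, seed=cfg.seed)
                comparisons.append({
                    "metric": metric, "a": ca, "b": cb,
                    "observed_diff": res.observed_diff,
                    "p": res.p_value,
                })
    p_adj = bonferroni([c["p"] for c in comparisons])
    for c, pa in zip(comparisons, p_adj):
        c["p_adj"] = float(pa)

    report = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "version": __version__,
        "n_boot": cfg.n_boot,
        "conditions": {
            cond: {"n_animals": len(tbls),
                   "n_neurons": int(sum(len(t) for t in tbls.values()))}
            for cond, tbls in tables.items()
        },
        "comparisons": comparisons,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "compare_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
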