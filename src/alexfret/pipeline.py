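"""End-to-end orchestration: simulate -> bursts -> BVA -> HMM -> distances.

One :func:`run` call executes the whole analysis reproducibly: every
stage draws its randomness from a substream derived from the single run
seed and the stage name, all stage artifacts are written to the output
directory (Photon-HDF5-style stream, TSV tables, JSON models), and a
consolidated JSON report records counts, state tables, rates, distances
and provenance (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import bursts as bursts_mod
from . import bva as bva_mod
from . import distances as dist_mod
from . import hmm as hmm_mod
from . import io as io_mod
from . import simkit

log = logging.getLogger("alexfret")


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    scenario: str = "apo"  # preset name, or path to a scenario YAML
    scenario_overrides: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "alexfret_run"
    # burst stage
    m: int = 10
    F: float = 6.0
    min_size: int = 30
    bg_window_s: float = 10.0
    s_range: tuple = (0.25, 0.75)
    corrections: dict = field(default_factory=dict)
    hist_bins: int = 40
    # BVA stage
    bva_n_sub: int = 5
    bva_confidence: float = 99.9
    # HMM stage
    k_range: tuple | None = None  # None: fixed K
    K: int | None = None  # used when k_range is None; None -> skip selection, use 4
    n_starts: int = 2
    max_iter: int = 300
    tol: float = 1e-8
    # distances
    R0: float = 54.5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["s_range"] = list(self.s_range)
        if self.k_range is not None:
            d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("s_range", "k_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific substream seed (stable, < 2**31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_scenario(config: RunConfig) -> simkit.SimScenario:
    if Path(config.scenario).suffix in (".yml", ".yaml") and Path(config.scenario).exists():
        sc = simkit.SimScenario.from_yaml(Path(config.scenario).read_text())
    else:
        sc = simkit.get_preset(config.scenario)
    over = dict(config.scenario_overrides)
    over["seed"] = stage_seed(config.seed, "simulate")
    return sc.replace(**over)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config_hash(config),
            "seed": config.seed,
            "alexfret_version": __version__,
        },
        "stages": {},
    }

    # -- simulate ----------------------------------------------------------
    scenario = _resolve_scenario(config)
    stream = simkit.simulate_experiment(scenario)
    io_mod.write_photon_hdf5(stream, outdir / "stream.h5")
    (outdir / "scenario.yaml").write_text(scenario.to_yaml())
    report["stages"]["simulate"] = {
        "n_photons": stream.n_photons,
        "duration_s": stream.duration_s,
        "artifact": "stream.h5",
    }
    log.info("simulate: %d photons over %.1f s", stream.n_photons, stream.duration_s)

    # -- bursts ------------------------------------------------------------
    bg = bursts_mod.estimate_background(stream, window_s=config.bg_window_s)
    table = bursts_mod.search_bursts(
        stream, m=config.m, F=config.F, min_size=config.min_size, background=bg
    )
    corr = bursts_mod.CorrectionSet(**config.corrections)
    metrics = bursts_mod.compute_metrics(table, corr)
    selected, sel_report = bursts_mod.select_bursts(
        metrics, s_range=config.s_range, size_range=(config.min_size, np.inf)
    )
    io_mod.write_table(metrics, outdir / "bursts.tsv")
    io_mod.write_table(selected, outdir / "bursts_selected.tsv")
    hist = bursts_mod.histogram_E(selected, bins=config.hist_bins)
    io_mod.write_table(hist, outdir / "fret_histogram.tsv")
    report["stages"]["bursts"] = {
        **sel_report,
        "artifact": "bursts.tsv",
        "histogram_artifact": "fret_histogram.tsv",
    }
    log.info("bursts: %(n_total)d found, %(n_selected)d dual-labeled", sel_report)

    # -- BVA ---------------------------------------------------------------
    if len(selected):
        cfg = bva_mod.BVAConfig(
            n_sub=config.bva_n_sub, confidence=config.bva_confidence
        )
        rng = np.random.default_rng(stage_seed(config.seed, "bva"))
        per_burst, per_bin = bva_mod.burst_variance(selected, stream, cfg, rng)
        io_mod.write_table(per_burst, outdir / "bva_bursts.tsv")
        io_mod.write_table(per_bin, outdir / "bva_bins.tsv")
        dyn_bins = per_bin.loc[per_bin["dynamic"], "E_center"].tolist()
        report["stages"]["bva"] = {
            "n_bursts": int(len(per_burst)),
            "dynamic_bins_E": dyn_bins,
            "artifact": "bva_bins.tsv",
        }
    else:
        report["stages"]["bva"] = {"status": "skipped: no selected bursts"}

    # -- HMM ---------------------------------------------------------------
    if len(selected) == 0:
        report["stages"]["hmm"] = {"status": "skipped: no selected bursts"}
        report["stages"]["distances"] = {"status": "skipped"}
    else:
        seqs = bursts_mod.burst_photons(stream, selected)
        hseed = stage_seed(config.seed, "hmm")
        if config.k_range is not None:
            best_K, fits = hmm_mod.icl_select(
                seqs,
                config.k_range,
                stream.clock_period_s,
                n_starts=config.n_starts,
                seed=hseed,
                max_iter=config.max_iter,
                tol=config.tol,
            )
            fit = fits[best_K]
            icl_table = {int(K): float(f.icl) for K, f in fits.items()}
        else:
            K = config.K if config.K is not None else 4
            fit = hmm_mod.em_fit_multistart(
                seqs,
                K,
                stream.clock_period_s,
                n_starts=config.n_starts,
                max_iter=config.max_iter,
                tol=config.tol,
                seed=hseed,
            )
            best_K, icl_table = K, None
        io_mod.write_json(fit.model.to_dict(), outdir / "hmm_model.json")
        io_mod.write_table(fit.states, outdir / "hmm_states.tsv")

        fret_idx = fit.states.loc[fit.states["label"] == "FRET", "state"].to_numpy()
        rates = None
        if fret_idx.size >= 2:
            rates = hmm_mod.transition_rates(fit.model, fret_idx, fit.occupancy)
        report["stages"]["hmm"] = {
            "selected_K": int(best_K),
            "icl": icl_table,
            "loglik": fit.loglik,
            "converged": bool(fit.converged),
            "states": fit.states.to_dict("records"),
            "rates_per_s": rates.rates.tolist() if rates is not None else None,
            "rate_method": rates.method if rates is not None else None,
            "artifact": "hmm_model.json",
        }

        # -- distances -----------------------------------------------------
        fp = dist_mod.ForsterParams(R0=config.R0)
        fret_tab = fit.states[fit.states["label"] == "FRET"]
        e_vals = fret_tab["E_state"].to_numpy()
        e_vals = np.clip(e_vals, 1e-6, 1 - 1e-6)
        conf = dist_mod.call_conformation(e_vals, fp)
        conf.insert(0, "state", fret_tab["state"].to_numpy())
        io_mod.write_table(conf, outdir / "distances.tsv")
        report["stages"]["distances"] = {
            "table": conf.to_dict("records"),
            "R0": config.R0,
            "artifact": "distances.tsv",
        }

    io_mod.write_json(report, outdir / "report.json")
    return report


def compare_scenarios(histograms: dict) -> pd.DataFrame:
    """Overlay FRET histograms from several runs into one table.

    ``histograms`` maps a scenario name to its histogram DataFrame
    (``bin_left/bin_right/frequency``); all binnings must be identical.
    """
    if len(histograms) < 2:
        raise ValueError("need at least two histograms to compare")
    names = list(histograms)
    ref = histograms[names[0]]
    out = ref[["bin_left", "bin_right"]].copy()
    for name in names:
        h = histograms[name]
        if len(h) != len(ref) or not np.allclose(
            h[["bin_left", "bin_right"]], ref[["bin_left", "bin_right"]]
        ):
            raise ValueError(f"histogram binning of {name!r} does not match")
        out[name] = h["frequency"].to_numpy()
    return out
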