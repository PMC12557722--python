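import numpy as np
import pytest

from alexfret import bursts as bursts_mod
from alexfret import simkit


@pytest.fixture(scope="session")
def apo_small():
    """A small apo-state experiment shared across burst/BVA tests:
    two-state dynamics (E 0.19/0.73, rates 50/202 1/s) with donor-only and
    acceptor-only contaminants, searched and selected with defaults."""
    sc = simkit.get_preset("apo").replace(n_bursts=500, seed=7)
    stream = simkit.simulate_experiment(sc)
    bg = bursts_mod.estimate_background(stream)
    table = bursts_mod.search_bursts(stream, background=bg)
    metrics = bursts_mod.compute_metrics(table)
    selected, report = bursts_mod.select_bursts(metrics)
    return {
        "scenario": sc,
        "stream": stream,
        "background": bg,
        "metrics": metrics,
        "selected": selected,
        "report": report,
    }


@pytest.fixture(scope="session")
def static_small():
    """A static single-state control (raptor-bound preset, E = 0.40)."""
    sc = simkit.get_preset("raptor-bound").replace(n_bursts=400, seed=3)
    stream = simkit.simulate_experiment(sc)
    bg = bursts_mod.estimate_background(stream)
    table = bursts_mod.search_bursts(stream, background=bg)
    metrics = bursts_mod.compute_metrics(table)
    selected, _ = bursts_mod.select_bursts(metrics)
    return {"scenario": sc, "stream": stream, "selected": selected}


def poisson_stream(rate, duration, seed, clock=12.5e-9, channel_probs=(0.4, 0.3, 0.3)):
    """Uniform Poisson photon stream helper (no bursts, no alternation)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0, duration, n))
    ticks = np.unique(np.round(t / clock).astype(np.int64))
    ch = rng.choice(3, size=ticks.size, p=channel_probs).astype(np.int8)
    return simkit.PhotonStream(
        timestamps=ticks, channels=ch, clock_period_s=clock, duration_s=duration
    )
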