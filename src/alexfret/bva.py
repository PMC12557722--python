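"""Burst-variance analysis (BVA).

Detects sub-millisecond conformational dynamics inside single-molecule
bursts.  Each burst's donor-excitation photon sequence is chopped into
consecutive windows of ``n_sub`` photons; the acceptor fraction of each
window is a subburst FRET value E_sub.  For a static molecule the photon
partitioning is binomial, so the standard deviation of E_sub around the
burst mean cannot exceed the shot-noise ("static") limit

    sigma_static(E) = sqrt(E * (1 - E) / n_sub)

(the dashed semicircle of a BVA plot).  Bursts from interconverting
molecules carry extra variance and rise above it.  Significance is
assessed per FRET bin with a Monte-Carlo binomial resampling band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simkit import Channel, PhotonStream


@dataclass
class BVAConfig:
    n_sub: int = 5  # donor-excitation photons per subburst
    bin_edges: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 21))
    confidence: float = 99.9  # percentile of the Monte-Carlo static band
    n_mc: int = 1000

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.n_sub < 2:
            raise ValueError("n_sub must be >= 2")
        if self.bin_edges[0] > 0 or self.bin_edges[-1] < 1:
            raise ValueError("bins must cover [0, 1]")


def static_limit(E, n_sub: int):
    """Shot-noise standard deviation of subburst FRET for a static state."""
    E = np.asarray(E, dtype=float)
    if np.any((E < 0) | (E > 1)):
        raise ValueError("E must lie in [0, 1]")
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    return np.sqrt(E * (1.0 - E) / n_sub)


def burst_variance(
    bursts: pd.DataFrame,
    stream: PhotonStream,
    config: BVAConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Per-burst subburst FRET standard deviation versus the static limit.

    Bursts contributing fewer than ``2 * n_sub`` donor-excitation photons
    (i.e. fewer than two complete subbursts) are excluded.  Returns
    ``(per_burst, per_bin)`` DataFrames: per burst the mean subburst FRET
    ``E_mean`` and its standard deviation ``sigma``; per FRET bin the mean
    sigma, the analytic static limit at the bin centre and the Monte-Carlo
    upper confidence bound under the static (binomial) null, plus a
    ``dynamic`` flag where the observed mean exceeds the bound.
    """
    cfg = config or BVAConfig()
    rng = rng or np.random.default_rng(0)
    n_sub = cfg.n_sub

    rows = []
    sub_counts = []  # acceptor counts per subburst, per burst (for the MC)
    for i0, i1 in zip(bursts["istart"], bursts["istop"]):
        ch = stream.channels[i0:i1]
        dex = ch[(ch == Channel.DexDem) | (ch == Channel.DexAem)]
        n_win = dex.size // n_sub
        if n_win < 2:
            continue
        acc = (dex[: n_win * n_sub] == Channel.DexAem).reshape(n_win, n_sub)
        e_sub = acc.sum(axis=1) / n_sub
        rows.append(
            {
                "istart": i0,
                "istop": i1,
                "n_windows": n_win,
                "E_mean": e_sub.mean(),
                "sigma": e_sub.std(ddof=0),
            }
        )
        sub_counts.append(n_win)
    per_burst = pd.DataFrame(
        rows, columns=["istart", "istop", "n_windows", "E_mean", "sigma"]
    )
    if per_burst.empty:
        per_bin = pd.DataFrame(
            columns=[
                "bin_left", "bin_right", "E_center", "n_bursts",
                "mean_sigma", "static_sigma", "mc_upper", "dynamic",
            ]
        )
        return per_burst, per_bin

    edges = cfg.bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(
        np.searchsorted(edges, per_burst["E_mean"].to_numpy(), side="right") - 1,
        0,
        centers.size - 1,
    )
    per_burst["bin"] = which

    bin_rows = []
    for b in range(centers.size):
        sel = per_burst[per_burst["bin"] == b]
        n_b = len(sel)
        row = {
            "bin_left": edges[b],
            "bin_right": edges[b + 1],
            "E_center": centers[b],
            "n_bursts": n_b,
            "static_sigma": static_limit(centers[b], n_sub),
        }
        if n_b == 0:
            row.update(mean_sigma=np.nan, mc_upper=np.nan, dynamic=False)
        else:
            row["mean_sigma"] = sel["sigma"].mean()
            row["mc_upper"] = _mc_static_band(
                sel["E_mean"].to_numpy(),
                sel["n_windows"].to_numpy(),
                n_sub,
                cfg.n_mc,
                cfg.confidence,
                rng,
            )
            row["dynamic"] = bool(row["mean_sigma"] > row["mc_upper"])
        bin_rows.append(row)
    per_bin = pd.DataFrame(bin_rows)
    return per_burst, per_bin


def _mc_static_band(e_means, n_windows, n_sub, n_mc, confidence, rng):
    """Upper percentile of the bin-mean sigma under the static binomial null,
    matching each burst's subburst count and mean FRET."""
    n_windows = n_windows.astype(int)
    total = int(n_windows.sum())
    p = np.repeat(e_means, n_windows)
    # draws: (n_mc, total subbursts across bursts in the bin)
    counts = rng.binomial(n_sub, p[None, :], size=(n_mc, total))
    e_sub = counts / n_sub
    # per-burst sigma for every replicate
    starts = np.concatenate([[0], np.cumsum(n_windows)])
    sigmas = np.empty((n_mc, n_windows.size))
    for i, (a, b) in enumerate(zip(starts[:-1], starts[1:])):
        sigmas[:, i] = e_sub[:, a:b].std(axis=1, ddof=0)
    return float(np.percentile(sigmas.mean(axis=1), confidence))
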