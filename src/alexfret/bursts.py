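"""Burst detection and per-burst FRET / stoichiometry metrics.

A burst is the photon cluster emitted while one molecule diffuses through
the confocal volume.  Detection uses the standard sliding-window rate
criterion: a photon is "in burst" when some window of ``m`` consecutive
photons containing it is denser than ``F`` times the local background
rate.  Each burst then yields the raw proximity ratio PR, the corrected
FRET efficiency E and the donor-acceptor stoichiometry S, from which
dual-labeled molecules (S around 0.5) are separated from donor-only
(S near 1) and acceptor-only (S near 0) contaminants.

Burst tables are plain :class:`pandas.DataFrame` objects with columns
``istart, istop, start_tick, stop_tick, n_photons, F_DD, F_DA, F_AA,
duration_ms`` (+ metric columns added by :func:`compute_metrics`).
Photon index spans are half-open ``[istart, istop)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simkit import Channel, N_CHANNELS, PhotonStream


@dataclass(frozen=True)
class CorrectionSet:
    """ALEX correction factors.

    leakage ``l``: donor signal bleeding into the acceptor channel;
    direct_excitation ``d``: acceptor excitation by the donor laser;
    gamma: detection-efficiency / quantum-yield ratio; beta: excitation
    intensity normalization for S.
    """

    leakage: float = 0.0
    direct_excitation: float = 0.0
    gamma: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.leakage < 0 or self.direct_excitation < 0:
            raise ValueError("leakage and direct excitation must be >= 0")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be > 0")


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------


def estimate_background(
    stream: PhotonStream,
    window_s: float = 10.0,
    tail_factor: float = 3.0,
    n_iter: int = 4,
) -> pd.DataFrame:
    """Estimate per-channel background rates from inter-photon delays.

    For each time window the out-of-burst tail of the exponential delay
    distribution is fitted: delays above a threshold ``th`` follow
    Exp(rate) shifted by ``th`` (memorylessness), so
    ``rate = 1 / (mean(delay | delay > th) - th)``.  The threshold is
    iterated to ``tail_factor / rate`` so in-burst spacings are excluded.

    Returns a DataFrame with one row per window and columns
    ``t_start, t_stop, bg_all, bg_DexDem, bg_DexAem, bg_AexAem`` (counts/s).
    """
    if stream.n_photons == 0:
        raise ValueError("cannot estimate background from an empty stream")
    t = stream.times_s
    t_end = max(stream.duration_s, float(t[-1]) + 1e-12)
    edges = np.arange(0.0, t_end, window_s)
    if edges.size == 0 or t_end - edges[-1] > 0:
        edges = np.append(edges, t_end)
    if edges.size < 2:
        edges = np.array([0.0, t_end])

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (t >= lo) & (t < hi)
        row = {"t_start": lo, "t_stop": hi}
        row["bg_all"] = _tail_rate(t[sel], hi - lo, tail_factor, n_iter)
        for ch in Channel:
            row[f"bg_{ch.name}"] = _tail_rate(
                t[sel & (stream.channels == ch)], hi - lo, tail_factor, n_iter
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _tail_rate(t: np.ndarray, span: float, tail_factor: float, n_iter: int) -> float:
    if t.size < 10:
        return t.size / span if span > 0 else np.nan
    d = np.diff(t)
    d = d[d > 0]
    if d.size < 10:
        return t.size / span
    th = d.mean()
    rate = 1.0 / th
    for _ in range(n_iter):
        tail = d[d > th]
        if tail.size < 5:
            break
        rate = 1.0 / (tail.mean() - th)
        th = tail_factor / rate
    return rate


# ---------------------------------------------------------------------------
# burst search
# ---------------------------------------------------------------------------


def search_bursts(
    stream: PhotonStream,
    m: int = 10,
    F: float = 6.0,
    min_size: int = 30,
    background: pd.DataFrame | None = None,
    window_s: float = 10.0,
    trim_gap_factor: float | None = 1.0,
) -> pd.DataFrame:
    """Sliding-window burst search.

    A window of ``m`` consecutive photons starting at photon ``i`` is "hot"
    when its span satisfies ``t[i+m-1] - t[i] <= m / (F * bg)`` with ``bg``
    the all-photon background rate of the window's time segment.  Every
    photon covered by a hot window is in-burst; maximal contiguous runs of
    in-burst photons form bursts, and bursts with fewer than ``min_size``
    photons are discarded.

    Burst edges are then trimmed: leading/trailing photons whose gap
    toward the burst interior exceeds ``trim_gap_factor / (F * bg)`` are
    stripped.  Hot windows straddling a burst edge always sweep in a few
    isolated background photons whose multi-millisecond spacings would
    otherwise dilate the burst span (and bias downstream photon-by-photon
    kinetics); in-burst spacings are orders of magnitude shorter, so the
    trim threshold separates the two cleanly.  ``trim_gap_factor=None``
    disables trimming.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if F <= 1:
        raise ValueError("F must be > 1")
    n = stream.n_photons
    cols = [
        "istart", "istop", "start_tick", "stop_tick", "n_photons",
        "F_DD", "F_DA", "F_AA", "duration_ms",
    ]
    if n < m:
        return pd.DataFrame(columns=cols)
    if background is None:
        background = estimate_background(stream, window_s=window_s)

    t = stream.times_s
    # per-photon background rate from its window
    win = np.searchsorted(background["t_stop"].to_numpy(), t, side="right")
    win = np.clip(win, 0, len(background) - 1)
    bg = background["bg_all"].to_numpy()[win]

    span = t[m - 1 :] - t[: n - m + 1]
    max_span = m / (F * bg[: n - m + 1])
    hot = span <= max_span

    # mark photons covered by any hot window via run-length accumulation
    cover = np.zeros(n + 1, dtype=np.int64)
    idx = np.nonzero(hot)[0]
    np.add.at(cover, idx, 1)
    np.add.at(cover, idx + m, -1)
    in_burst = np.cumsum(cover[:-1]) > 0

    max_gap = None
    if trim_gap_factor is not None:
        max_gap = trim_gap_factor / (F * bg)  # per-photon threshold (s)
    return _bursts_from_mask(stream, in_burst, min_size, max_gap)


def _trim_edges(
    t: np.ndarray,
    i0: int,
    i1: int,
    max_gap,
    median_factor: float = 10.0,
    lookahead: int = 10,
) -> tuple[int, int]:
    """Strip edge photons separated from the burst core by sparse gaps.

    The gap threshold is ``median_factor`` times the burst's own median
    inter-photon spacing (in-burst spacings are roughly exponential, so
    real gaps essentially never exceed ten medians), capped by the
    background-derived ``max_gap``.  Hot windows sweep in at most
    window-size edge photons, so it suffices to look ``lookahead``
    photons deep on each side: everything outside the innermost
    over-threshold gap there is cut.
    """
    if max_gap is None:
        return i0, i1
    gaps = np.diff(t[i0:i1])
    med = np.median(gaps) if gaps.size else 0.0
    changed = True
    while changed and i1 - i0 >= 2:
        changed = False
        depth = min(lookahead, i1 - i0 - 1)
        for j in range(i0 + depth - 1, i0 - 1, -1):  # innermost sparse gap first
            if (t[j + 1] - t[j]) > min(max_gap[j], median_factor * med):
                i0 = j + 1
                changed = True
                break
        depth = min(lookahead, i1 - i0 - 1)
        for j in range(i1 - depth - 1, i1 - 1):
            if (t[j + 1] - t[j]) > min(max_gap[j], median_factor * med):
                i1 = j + 1
                changed = True
                break
    return i0, i1


def _bursts_from_mask(
    stream: PhotonStream,
    in_burst: np.ndarray,
    min_size: int,
    max_gap: np.ndarray | None = None,
) -> pd.DataFrame:
    edges = np.diff(in_burst.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if in_burst[0]:
        starts = np.insert(starts, 0, 0)
    if in_burst[-1]:
        stops = np.append(stops, in_burst.size)

    rows = []
    period_ms = stream.clock_period_s * 1e3
    t = stream.times_s
    for i0, i1 in zip(starts, stops):
        i0, i1 = _trim_edges(t, int(i0), int(i1), max_gap)
        if i1 - i0 < min_size:
            continue
        ch = stream.channels[i0:i1]
        counts = np.bincount(ch, minlength=N_CHANNELS)
        rows.append(
            {
                "istart": i0,
                "istop": i1,
                "start_tick": stream.timestamps[i0],
                "stop_tick": stream.timestamps[i1 - 1] + 1,
                "n_photons": i1 - i0,
                "F_DD": counts[Channel.DexDem],
                "F_DA": counts[Channel.DexAem],
                "F_AA": counts[Channel.AexAem],
                "duration_ms": (stream.timestamps[i1 - 1] - stream.timestamps[i0])
                * period_ms,
            }
        )
    df = pd.DataFrame(rows, columns=[
        "istart", "istop", "start_tick", "stop_tick", "n_photons",
        "F_DD", "F_DA", "F_AA", "duration_ms",
    ])
    return df


def search_bursts_bruteforce(
    stream: PhotonStream,
    m: int,
    F: float,
    min_size: int,
    background: pd.DataFrame,
    trim_gap_factor: float | None = 1.0,
) -> pd.DataFrame:
    """Naive O(n*m) evaluation of the identical burst criterion.

    Independent oracle for :func:`search_bursts`; intended for small
    streams only.
    """
    n = stream.n_photons
    t = stream.times_s
    bg_edges = background["t_stop"].to_numpy()
    bg_rates = background["bg_all"].to_numpy()

    def bg_at(i):
        w = int(np.clip(np.searchsorted(bg_edges, t[i], side="right"), 0, len(bg_rates) - 1))
        return bg_rates[w]

    in_burst = np.zeros(n, dtype=bool)
    for i in range(n - m + 1):
        if (t[i + m - 1] - t[i]) <= m / (F * bg_at(i)):
            for j in range(i, i + m):
                in_burst[j] = True
    max_gap = None
    if trim_gap_factor is not None:
        max_gap = np.array([trim_gap_factor / (F * bg_at(i)) for i in range(n)])
    return _bursts_from_mask(stream, in_burst, min_size, max_gap)


# ---------------------------------------------------------------------------
# burst metrics and selection
# ---------------------------------------------------------------------------


def compute_metrics(
    bursts: pd.DataFrame, corrections: CorrectionSet | None = None
) -> pd.DataFrame:
    """Add PR, corrected E, raw and corrected S columns to a burst table.

    PR = F_DA / (F_DD + F_DA);
    F_DA' = F_DA - l*F_DD - d*F_AA;
    E = F_DA' / (gamma*F_DD + F_DA');
    S = (gamma*F_DD + F_DA') / (gamma*F_DD + F_DA' + F_AA/beta).

    With all corrections at their neutral values E equals PR exactly.
    Corrected E may leave [0, 1] when corrections are nonzero; bursts with
    an undefined metric (zero denominator) get NaN and ``flag_undefined``.
    """
    c = corrections or CorrectionSet()
    out = bursts.copy()
    dd = out["F_DD"].to_numpy(dtype=float)
    da = out["F_DA"].to_numpy(dtype=float)
    aa = out["F_AA"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        pr = np.where(dd + da > 0, da / (dd + da), np.nan)
        da_c = da - c.leakage * dd - c.direct_excitation * aa
        den_e = c.gamma * dd + da_c
        e = np.where(den_e != 0, da_c / den_e, np.nan)
        den_s = den_e + aa / c.beta
        s = np.where(den_s != 0, den_e / den_s, np.nan)
        s_raw = np.where(dd + da + aa > 0, (dd + da) / (dd + da + aa), np.nan)

    out["PR"] = pr
    out["E"] = e
    out["S"] = s
    out["S_raw"] = s_raw
    out["flag_undefined"] = ~(np.isfinite(pr) & np.isfinite(e) & np.isfinite(s))
    return out


def select_bursts(
    metrics: pd.DataFrame,
    s_range: tuple = (0.25, 0.75),
    size_range: tuple = (30, np.inf),
) -> tuple[pd.DataFrame, dict]:
    """Keep dual-labeled bursts by S and size; report what was excluded.

    Returns ``(selected, report)`` where the report counts donor-only
    (S above the range) and acceptor-only (S below) rejections.
    """
    s_lo, s_hi = s_range
    n_lo, n_hi = size_range
    if not (s_lo <= s_hi) or not (n_lo <= n_hi):
        raise ValueError("invalid selection ranges")
    s = metrics["S"].to_numpy(dtype=float)
    size = metrics["n_photons"].to_numpy()
    ok_size = (size >= n_lo) & (size <= n_hi)
    in_s = (s >= s_lo) & (s <= s_hi)
    keep = ok_size & in_s & np.isfinite(s)
    report = {
        "n_total": int(len(metrics)),
        "n_selected": int(keep.sum()),
        "n_donor_only": int((ok_size & (s > s_hi)).sum()),
        "n_acceptor_only": int((ok_size & (s < s_lo)).sum()),
        "n_undersized": int((~ok_size).sum()),
    }
    if report["n_selected"] == 0 and report["n_total"] > 0:
        warnings.warn("burst selection returned no bursts", stacklevel=2)
    return metrics.loc[keep].reset_index(drop=True), report


def histogram_E(
    selected: pd.DataFrame, bins: int | np.ndarray = 40
) -> pd.DataFrame:
    """Normalized FRET-efficiency histogram over [0, 1].

    Returns a DataFrame with ``bin_left, bin_right, count, frequency``.
    """
    if np.isscalar(bins):
        if bins < 2:
            raise ValueError("need at least 2 bins")
        edges = np.linspace(0.0, 1.0, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if edges.size < 3:
            raise ValueError("need at least 2 bins")
    e = selected["E"].to_numpy(dtype=float) if len(selected) else np.empty(0)
    e = e[np.isfinite(e)]
    counts, _ = np.histogram(np.clip(e, edges[0], edges[-1]), bins=edges)
    total = counts.sum()
    freq = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": freq,
        }
    )


def burst_photons(stream: PhotonStream, bursts: pd.DataFrame):
    """Extract per-burst photon sequences for the photon-by-photon HMM.

    Returns a list of ``(timestamps_ticks, channels)`` pairs.  Duplicate
    timestamps (distinct detectors firing within one clock tick) are bumped
    forward by one tick so inter-photon gaps are always >= 1.
    """
    seqs = []
    for i0, i1 in zip(bursts["istart"], bursts["istop"]):
        ts = stream.timestamps[i0:i1].copy()
        for k in range(1, ts.size):
            if ts[k] <= ts[k - 1]:
                ts[k] = ts[k - 1] + 1
        seqs.append((ts, stream.channels[i0:i1].astype(np.int64)))
    return seqs
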