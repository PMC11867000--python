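"""Criticality metrics of oscillation amplitude envelopes.

Two estimators locate a signal on the subcritical-critical-supercritical
axis:

* **DFA** — detrended fluctuation analysis of the envelope's cumulative
  profile.  The scaling exponent is the slope of log F(s) vs log s; 0.5 means
  temporally uncorrelated amplitude dynamics, exponents above 0.5 indicate
  power-law long-range temporal correlations (LRTCs).
* **fE/I** — functional excitation/inhibition ratio, defined as
  1 - r(w_amp, w_nF): one minus the Pearson correlation between windowed mean
  amplitudes and windowed amplitude-normalized detrended fluctuations.
  Values below 1 indicate inhibition dominance, ~1 criticality, above 1
  excitation dominance.  fE/I is only interpretable near criticality, so
  cells whose DFA exponent does not exceed 0.6 are masked invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .signal import FrequencyGrid, NarrowbandEnvelope, ParcelTimeSeries, morlet_filter

log = logging.getLogger(__name__)

DFA_FIT_RANGE = (2.0, 25.0)  # seconds
DFA_VALIDITY_THRESHOLD = 0.6
FEI_WINDOW_CYCLES = 40


# ---------------------------------------------------------------------------
# DFA


@dataclass
class DFAResult:
    exponent: float
    window_sizes: np.ndarray  # seconds
    fluctuation: np.ndarray  # F(s), same length
    fit_weights: np.ndarray  # robust-fit weights per window size
    r2: float


def _window_starts(n: int, size: int, overlap: float) -> np.ndarray:
    step = max(1, int(round(size * (1.0 - overlap))))
    return np.arange(0, n - size + 1, step)


def _detrended_rms_sq(profile: np.ndarray, size: int, overlap: float) -> float:
    """Mean squared residual around a per-window linear trend, pooled over windows."""
    starts = _window_starts(profile.size, size, overlap)
    t = np.arange(size, dtype=float)
    t -= t.mean()
    denom = float(np.sum(t * t))
    acc = 0.0
    for s in starts:
        seg = profile[s : s + size]
        slope = float(np.dot(t, seg)) / denom
        resid = seg - seg.mean() - slope * t
        acc += float(np.dot(resid, resid))
    return acc / (starts.size * size)


def _tukey_bisquare_fit(
    x: np.ndarray, y: np.ndarray, c: float = 4.685, max_iter: int = 50, tol: float = 1e-8
) -> tuple[float, float, np.ndarray]:
    """IRLS line fit with Tukey bisquare weights; returns (slope, intercept, weights)."""
    w = np.ones_like(x)
    slope, intercept = 0.0, 0.0
    for _ in range(max_iter):
        W = np.sum(w)
        xm = np.sum(w * x) / W
        ym = np.sum(w * y) / W
        denom = np.sum(w * (x - xm) ** 2)
        new_slope = np.sum(w * (x - xm) * (y - ym)) / denom
        new_intercept = ym - new_slope * xm
        resid = y - (new_slope * x + new_intercept)
        # MAD scale; guard against exact fits
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale < 1e-12:
            slope, intercept = new_slope, new_intercept
            w = np.ones_like(x)
            break
        u = resid / (c * scale)
        w_new = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if np.sum(w_new) < 2:  # pathological: keep previous weights
            slope, intercept = new_slope, new_intercept
            break
        converged = abs(new_slope - slope) < tol and abs(new_intercept - intercept) < tol
        slope, intercept, w = new_slope, new_intercept, w_new
        if converged:
            break
    return slope, intercept, w


def dfa(
    envelope: np.ndarray | NarrowbandEnvelope,
    fs: float | None = None,
    fit_range: tuple[float, float] = DFA_FIT_RANGE,
    overlap: float = 0.5,
    n_sizes: int = 10,
    parcel: int = 0,
) -> DFAResult:
    """Detrended fluctuation analysis of an amplitude envelope.

    The cumulative profile of the demeaned envelope is split into windows of
    ``n_sizes`` log-spaced durations within ``fit_range`` (50% overlap by
    default); each window is linearly detrended and F(s) is the RMS residual
    pooled over windows.  The exponent is the slope of log10 F vs log10 s
    under an iteratively reweighted least-squares fit with Tukey bisquare
    weights (c = 4.685), which de-emphasizes outlying window sizes.
    """
    if isinstance(envelope, NarrowbandEnvelope):
        x = envelope.valid(parcel)
        fs = envelope.fs
    else:
        x = np.asarray(envelope, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a raw array")
    if not np.all(np.isfinite(x)):
        raise ValueError("envelope contains non-finite values")
    max_win = int(round(fit_range[1] * fs))
    if x.size < 2 * max_win:
        raise ValueError(
            f"signal too short for DFA: need >= {2 * max_win} samples "
            f"(2 x {fit_range[1]} s at {fs} Hz), got {x.size}"
        )
    sizes = np.unique(
        np.round(np.geomspace(fit_range[0] * fs, fit_range[1] * fs, n_sizes)).astype(int)
    )
    profile = np.cumsum(x - x.mean())
    fluct = np.array([np.sqrt(_detrended_rms_sq(profile, int(s), overlap)) for s in sizes])
    logs = np.log10(sizes / fs)
    logF = np.log10(fluct)
    slope, intercept, weights = _tukey_bisquare_fit(logs, logF)
    pred = slope * logs + intercept
    ss_res = float(np.sum((logF - pred) ** 2))
    ss_tot = float(np.sum((logF - logF.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(
        exponent=float(slope),
        window_sizes=sizes / fs,
        fluctuation=fluct,
        fit_weights=weights,
        r2=r2,
    )


# ---------------------------------------------------------------------------
# fE/I


@dataclass
class FEIResult:
    fei: float  # NaN when invalid
    valid: bool
    window_amp: np.ndarray
    window_nf: np.ndarray
    dfa_exponent: float


def fei(
    envelope: np.ndarray | NarrowbandEnvelope,
    fs: float | None = None,
    f: float | None = None,
    dfa_exponent: float | None = None,
    window_cycles: int = FEI_WINDOW_CYCLES,
    dfa_threshold: float = DFA_VALIDITY_THRESHOLD,
    overlap: float = 0.8,
    parcel: int = 0,
) -> FEIResult:
    """Functional E/I ratio of a narrowband amplitude envelope.

    The envelope is split into windows of ``window_cycles`` oscillation cycles
    (80% overlap by default).  Per window i: w_amp_i is the mean amplitude;
    the amplitude-normalized profile is cumsum(a - mean(a)) / w_amp_i, which
    is linearly detrended; w_nF_i is the SD of that detrended profile.  Then

        fE/I = 1 - Pearson r(w_amp, w_nF).

    A supplied DFA exponent <= ``dfa_threshold`` marks the result invalid
    (fei = NaN): away from the critical regime the measure is ambiguous.
    """
    if isinstance(envelope, NarrowbandEnvelope):
        x = envelope.valid(parcel)
        fs = envelope.fs
        if f is None:
            f = envelope.center_freq
    else:
        x = np.asarray(envelope, dtype=float)
        if fs is None or f is None:
            raise ValueError("fs and f required when passing a raw array")
    if dfa_exponent is None:
        raise ValueError("dfa_exponent must be supplied (validity gate)")
    win = int(round(window_cycles * fs / f))
    if win < 10:
        raise ValueError(f"window of {win} samples (<10): f too high for fs")
    starts = _window_starts(x.size, win, overlap)
    if starts.size < 20:
        raise ValueError(
            f"only {starts.size} fE/I windows available; need >= 20 "
            f"(window = {window_cycles} cycles = {win} samples)"
        )
    w_amp, w_nf = [], []
    t = np.arange(win, dtype=float)
    t -= t.mean()
    denom = float(np.sum(t * t))
    n_dropped = 0
    for s in starts:
        seg = x[s : s + win]
        amp = float(seg.mean())
        if amp <= 0:
            n_dropped += 1
            continue
        prof = np.cumsum(seg - amp) / amp
        slope = float(np.dot(t, prof)) / denom
        resid = prof - prof.mean() - slope * t
        w_amp.append(amp)
        w_nf.append(float(np.std(resid)))
    if n_dropped:
        log.warning("fei: dropped %d zero-amplitude windows", n_dropped)
    w_amp = np.asarray(w_amp)
    w_nf = np.asarray(w_nf)
    valid = dfa_exponent > dfa_threshold
    if w_amp.size < 2 or np.std(w_amp) == 0 or np.std(w_nf) == 0:
        value = np.nan
        valid = False
    else:
        r = float(sps.pearsonr(w_amp, w_nf).statistic)
        value = 1.0 - r
    return FEIResult(
        fei=value if valid else np.nan,
        valid=bool(valid),
        window_amp=w_amp,
        window_nf=w_nf,
        dfa_exponent=float(dfa_exponent),
    )


# ---------------------------------------------------------------------------
# Bands and aggregation


@dataclass(frozen=True)
class BandRegistry:
    """Canonical frequency bands; membership is half-open [lo, hi)."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "theta": (4.0, 7.0),
            "alpha": (7.0, 12.0),
            "beta": (12.0, 30.0),
        }
    )

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band registry must be non-empty")
        for name, (lo, hi) in self.bands.items():
            if lo >= hi:
                raise ValueError(f"band {name!r}: lo ({lo}) must be < hi ({hi})")

    def names(self) -> list[str]:
        return list(self.bands)

    def membership(self, freqs: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.bands[name]
        return np.flatnonzero((np.asarray(freqs) >= lo) & (np.asarray(freqs) < hi))


def band_average(
    values: np.ndarray,
    freqs: np.ndarray,
    bands: BandRegistry,
    valid: np.ndarray | None = None,
    over_parcels: bool = False,
) -> dict[str, np.ndarray | float]:
    """Mean of a (parcels x freqs) metric within each band.

    Invalid cells are excluded; a band whose every cell is invalid yields NaN.
    With ``over_parcels`` the mean collapses parcels too (whole-brain value).
    """
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    out: dict[str, np.ndarray | float] = {}
    for name in bands.names():
        idx = bands.membership(freqs, name)
        if idx.size == 0:
            raise ValueError(f"band {name!r} contains no grid frequencies")
        v = np.where(mask[:, idx], values[:, idx], np.nan)
        with np.errstate(invalid="ignore"):
            if over_parcels:
                out[name] = float(np.nanmean(v)) if np.any(np.isfinite(v)) else np.nan
            else:
                counts = np.sum(np.isfinite(v), axis=1)
                means = np.full(values.shape[0], np.nan)
                has = counts > 0
                means[has] = np.nanmean(v[has], axis=1)
                out[name] = means
    return out


# ---------------------------------------------------------------------------
# Per-subject maps


@dataclass
class CritMaps:
    """Per-subject DFA and fE/I over parcels x frequencies."""

    dfa: np.ndarray  # (n_parcels, n_freqs)
    fei: np.ndarray  # (n_parcels, n_freqs); NaN where invalid
    valid: np.ndarray  # boolean, fE/I validity (DFA > threshold)
    freqs: np.ndarray
    parcel_ids: list[str]
    system_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    @property
    def n_parcels(self) -> int:
        return int(self.dfa.shape[0])

    def whole_brain(self, metric: str = "dfa") -> np.ndarray:
        """Parcel-mean per frequency; fE/I averages only valid cells."""
        if metric == "dfa":
            return self.dfa.mean(axis=0)
        vals = np.where(self.valid, self.fei, np.nan)
        counts = self.valid.sum(axis=0)
        sums = np.where(self.valid, self.fei, 0.0).sum(axis=0)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    def valid_cell_count(self) -> int:
        return int(self.valid.sum())


def crit_maps(
    ts: ParcelTimeSeries,
    grid: FrequencyGrid,
    dfa_kwargs: dict | None = None,
    fei_kwargs: dict | None = None,
) -> CritMaps:
    """Compute DFA and fE/I for every parcel x grid frequency of one subject."""
    dfa_kwargs = dfa_kwargs or {}
    fei_kwargs = fei_kwargs or {}
    n_p, n_f = ts.n_parcels, len(grid)
    dfa_map = np.empty((n_p, n_f))
    fei_map = np.full((n_p, n_f), np.nan)
    valid = np.zeros((n_p, n_f), dtype=bool)
    for k, f in enumerate(grid.freqs):
        env = morlet_filter(ts, f, grid.m)
        for p in range(n_p):
            d = dfa(env, parcel=p, **dfa_kwargs)
            dfa_map[p, k] = d.exponent
            r = fei(env, parcel=p, dfa_exponent=d.exponent, **fei_kwargs)
            fei_map[p, k] = r.fei
            valid[p, k] = r.valid
    return CritMaps(
        dfa=dfa_map,
        fei=fei_map,
        valid=valid,
        freqs=np.asarray(grid.freqs),
        parcel_ids=list(ts.parcel_ids),
        system_ids=list(ts.system_ids),
        subject_id=ts.subject_id,
    )
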