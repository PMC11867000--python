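"""Narrowband decomposition of parcel time series.

A resting-state recording is analysed per parcel through a bank of complex
Morlet wavelets on a log-equidistant frequency grid.  The modulus of the
convolution is the amplitude envelope on which the criticality metrics
(DFA exponents, functional E/I) operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, welch  # noqa: F401  (welch re-exported for oracles)

FUNCTIONAL_SYSTEMS = ("DMN", "DAN", "FPN", "Lim", "SM", "VAN", "Vis")


@dataclass(frozen=True)
class FrequencyGrid:
    """Log-equidistant grid of wavelet center frequencies.

    Parameters
    ----------
    freqs : ndarray
        Strictly increasing center frequencies in Hz.
    m : float
        Morlet width parameter (cycles-like, dimensionless).
    """

    freqs: np.ndarray
    m: float = 5.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be positive")
        if f.size > 1:
            if np.any(np.diff(f) <= 0):
                raise ValueError("frequencies must be strictly increasing")
            ratios = np.diff(np.log(f))
            if np.max(np.abs(ratios - ratios[0])) > 1e-9:
                raise ValueError("frequencies must be log-equidistant")

    def __len__(self) -> int:
        return int(self.freqs.size)

    def band_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of grid frequencies in the half-open band [lo, hi)."""
        return np.flatnonzero((self.freqs >= lo) & (self.freqs < hi))


def build_frequency_grid(fmin: float, fmax: float, n: int, m: float = 5.0) -> FrequencyGrid:
    """Build ``n`` geometrically spaced center frequencies from ``fmin`` to ``fmax``.

    The default analysis uses 32 wavelets spanning 2-90 Hz with width m = 5.
    """
    if fmin <= 0:
        raise ValueError("fmin must be positive")
    if fmax < fmin:
        raise ValueError("fmax must be >= fmin")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        if fmin != fmax:
            raise ValueError("single-frequency grid requires fmin == fmax")
        return FrequencyGrid(np.array([float(fmin)]), m=m)
    return FrequencyGrid(np.geomspace(fmin, fmax, n), m=m)


@dataclass
class ParcelTimeSeries:
    """One subject's parcellated recording: samples x parcels plus metadata."""

    data: np.ndarray
    fs: float
    parcel_ids: list[str] = field(default_factory=list)
    system_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x parcels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_parcels = self.data.shape[1]
        if not self.parcel_ids:
            self.parcel_ids = [f"p{i:03d}" for i in range(n_parcels)]
        if len(self.parcel_ids) != n_parcels:
            raise ValueError("parcel_ids length mismatch")
        if self.system_ids:
            if len(self.system_ids) != n_parcels:
                raise ValueError("system_ids length mismatch")
            unknown = set(self.system_ids) - set(FUNCTIONAL_SYSTEMS)
            if unknown:
                raise ValueError(f"unknown functional systems: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_parcels(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class NarrowbandEnvelope:
    """Amplitude envelope of a narrowband-filtered signal.

    ``valid_range`` is the (start, stop) slice unaffected by filter edge
    effects; downstream estimators must restrict themselves to it.
    """

    amplitude: np.ndarray
    center_freq: float
    fs: float
    valid_range: tuple[int, int]
    analytic: np.ndarray | None = None

    def valid(self, parcel: int | None = None) -> np.ndarray:
        lo, hi = self.valid_range
        a = self.amplitude[lo:hi]
        return a if parcel is None else a[:, parcel]


def morlet_wavelet(f: float, fs: float, m: float = 5.0) -> np.ndarray:
    """Unit-energy complex Morlet wavelet at center frequency ``f``.

    w(t) = C exp(-t^2 / 2 sigma_t^2) exp(i 2 pi f t) with sigma_t = m / (2 pi f),
    truncated at +/- 3 sigma_t and normalized to unit L2 energy.
    """
    sigma_t = m / (2.0 * np.pi * f)
    half = int(np.ceil(3.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f * t)
    w /= np.sqrt(np.sum(np.abs(w) ** 2))
    return w


def morlet_filter(ts: ParcelTimeSeries, f: float, m: float = 5.0) -> NarrowbandEnvelope:
    """Filter each parcel with a complex Morlet wavelet; return the envelope.

    The complex narrowband signal is kept in ``analytic``; the amplitude is its
    modulus.  ``valid_range`` excludes +/- 3 sigma_t at each edge.
    """
    if f >= ts.fs / 2.0:
        raise ValueError(f"center frequency {f} Hz >= Nyquist ({ts.fs / 2} Hz)")
    w = morlet_wavelet(f, ts.fs, m)
    half = (len(w) - 1) // 2
    if ts.n_samples <= len(w):
        raise ValueError(
            f"signal of {ts.n_samples} samples shorter than wavelet support ({len(w)})"
        )
    analytic = np.empty(ts.data.shape, dtype=complex)
    for p in range(ts.n_parcels):
        analytic[:, p] = fftconvolve(ts.data[:, p], w, mode="same")
    lo, hi = half, ts.n_samples - half
    return NarrowbandEnvelope(
        amplitude=np.abs(analytic),
        center_freq=float(f),
        fs=ts.fs,
        valid_range=(lo, hi),
        analytic=analytic,
    )


def compute_psd(ts: ParcelTimeSeries, grid: FrequencyGrid) -> np.ndarray:
    """Wavelet power spectrum per parcel, normalized to sum to one.

    Power at each grid frequency is the mean squared envelope over the valid
    range; each parcel's spectrum is then divided by its total so spectra are
    comparable across subjects regardless of absolute signal scale.

    Returns an array of shape (n_freqs, n_parcels).
    """
    psd = np.empty((len(grid), ts.n_parcels))
    for k, f in enumerate(grid.freqs):
        env = morlet_filter(ts, f, grid.m)
        lo, hi = env.valid_range
        if hi <= lo:
            raise ValueError(f"empty valid range at {f} Hz; signal too short")
        psd[k] = np.mean(env.amplitude[lo:hi] ** 2, axis=0)
    totals = psd.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero total power in at least one parcel")
    return psd / totals


def alpha_peak_frequency(
    spectrum: np.ndarray,
    grid: FrequencyGrid,
    search_band: tuple[float, float] = (7.0, 13.0),
) -> tuple[float, bool]:
    """Peak frequency of the parcel-mean spectrum within a band.

    Returns ``(frequency, is_local_max)``.  When the in-band spectrum is
    monotone (no interior local maximum), the band-edge argmax is returned
    with the flag set to False so callers can treat it as unreliable.
    """
    lo, hi = search_band
    idx = np.flatnonzero((grid.freqs >= lo) & (grid.freqs <= hi))
    if idx.size == 0:
        raise ValueError(f"search band {search_band} contains no grid frequencies")
    mean_spec = spectrum.mean(axis=1) if spectrum.ndim == 2 else np.asarray(spectrum)
    band = mean_spec[idx]
    k = int(np.argmax(band))
    # interior peak must beat both neighbours within the full spectrum
    g = idx[k]
    left = mean_spec[g - 1] if g > 0 else np.inf
    right = mean_spec[g + 1] if g < mean_spec.size - 1 else np.inf
    is_local = bool(mean_spec[g] >= left and mean_spec[g] >= right)
    return float(grid.freqs[g]), is_local
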