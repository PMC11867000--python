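"""Synthetic signals and cohorts with controlled criticality structure.

The generators provide ground truth for every downstream stage:

* ``generate_fgn`` — exact fractional Gaussian noise (circulant embedding),
  the canonical process with tunable Hurst exponent H, hence tunable DFA
  scaling exponent.
* ``generate_oscillation`` — a narrowband oscillation whose amplitude
  envelope carries fGn-driven long-range temporal correlations, with an
  adjustable coupling between window amplitude and normalized fluctuation
  that moves the functional E/I ratio below (gamma > 0, inhibition-like) or
  above (gamma < 0, excitation-like) unity.
* ``generate_cohort`` / ``generate_longitudinal`` — three-group
  cross-sectional and stable/progressive longitudinal cohorts whose DFA and
  fE/I maps shift in the directions expected for dementia progression
  (HC > SCD > MCI in alpha/beta DFA; MCI above HC in fE/I), with ages, MMSE
  scores and six medial-temporal-lobe volumes drawn from the study cohorts'
  published group means and SDs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .criticality import CritMaps
from .signal import FUNCTIONAL_SYSTEMS, ParcelTimeSeries

log = logging.getLogger(__name__)

GROUPS = ("HC", "SCD", "MCI")

# Published group summary statistics (mean, SD) for the cross-sectional
# cohorts: ages and the six normalized medial-temporal-lobe volumes.
COHORT_AGES = {"HC": (70.21, 4.38), "SCD": (72.16, 5.29), "MCI": (73.45, 5.44)}
MTL_VOLUMES = {
    "vol_l_hippocampus": {"HC": (0.0026, 0.0003), "SCD": (0.0024, 0.0004), "MCI": (0.0022, 0.0004)},
    "vol_r_hippocampus": {"HC": (0.0025, 0.0003), "SCD": (0.0025, 0.0004), "MCI": (0.0022, 0.0004)},
    "vol_l_parahippocampus": {"HC": (0.0014, 0.0003), "SCD": (0.0014, 0.0003), "MCI": (0.0012, 0.0002)},
    "vol_r_parahippocampus": {"HC": (0.0013, 0.0002), "SCD": (0.0012, 0.0002), "MCI": (0.0011, 0.0002)},
    "vol_l_entorhinal": {"HC": (0.0013, 0.0002), "SCD": (0.0013, 0.0003), "MCI": (0.0011, 0.0003)},
    "vol_r_entorhinal": {"HC": (0.0013, 0.0002), "SCD": (0.0012, 0.0003), "MCI": (0.0010, 0.0003)},
}
# Longitudinal MCI subcohorts: baseline/follow-up ages and MMSE (mean, SD).
LONGITUDINAL = {
    "stable": {"n": 22, "age_t1": (71.73, 5.20), "mmse_t1": (27.45, 2.28), "mmse_t2": (26.73, 3.06)},
    "prog": {"n": 23, "age_t1": (73.70, 3.40), "mmse_t1": (25.79, 3.34), "mmse_t2": (23.41, 4.24)},
}
# MMSE group levels for the cross-sectional cohorts are not tabulated in the
# source summaries; these follow the usual clinical ranges for the three
# stages and are consistent with the MCI baseline values above.
MMSE_LEVELS = {"HC": (28.8, 1.1), "SCD": (28.0, 1.6), "MCI": (26.6, 2.9)}


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k) for unit-variance increments."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def generate_fgn(
    hurst: float, n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Exact fractional Gaussian noise of length ``n`` via circulant embedding.

    The 2n-point circulant extension of the fGn autocovariance is diagonalized
    by the FFT; Gaussian noise shaped by the eigenvalue square roots yields a
    sequence with exactly the target covariance.  Should the embedding fail to
    be positive semidefinite (it is for fGn, but guard anyway), negative
    eigenvalues are clipped and a warning is emitted.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    g = fgn_autocovariance(hurst, np.arange(n + 1))
    row = np.concatenate([g, g[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        warnings.warn("circulant embedding not PSD; clipping eigenvalues (approximate)")
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam) * z) / np.sqrt(m)
    return x.real[:n]


# ---------------------------------------------------------------------------
# single oscillation


@dataclass(frozen=True)
class OscillationSpec:
    """Parameters of one synthetic narrowband oscillation.

    coupling gamma: 0 leaves window amplitude and normalized fluctuation
    independent (critical, fE/I ~ 1); gamma > 0 gives high-amplitude windows
    extra relative fluctuation (inhibition-like, fE/I < 1); gamma < 0 the
    reverse (excitation-like, fE/I > 1).
    """

    f0: float = 10.0
    fs: float = 250.0
    duration: float = 120.0
    hurst: float = 0.8
    coupling: float = 0.0
    snr: float = 5.0
    env_sigma: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must be in (0, 1)")
        if self.f0 >= self.fs / 2:
            raise ValueError("f0 must be below Nyquist")
        if self.duration < 50.0:
            raise ValueError("duration must be >= 50 s (2 x largest DFA window)")


def _one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f power spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f**-0.5  # amplitude ~ f^-1/2 -> power ~ 1/f
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_envelope(spec: OscillationSpec, rng: np.random.Generator) -> np.ndarray:
    """LRTC-bearing positive amplitude envelope with optional coupling.

    Base envelope is the lognormal map exp(sigma * fGn(H)): positive, and
    multiplicative, so the absolute fluctuation scale of a window tracks its
    amplitude level.  That scale-invariance is exactly what the uncoupled
    (critical) regime requires — the normalized fluctuation of a window is
    then independent of its mean amplitude and fE/I sits at ~1.  (A
    shifted-linear map 1 + sigma*h fails here: its absolute fluctuation is
    level-independent, so normalized fluctuation falls with amplitude and
    fE/I is biased above 1.  The residual convexity bias of exp is O(sigma^2)
    and negligible at the default sigma.)

    Coupling rescales each 40-cycle window's deviations around its own mean
    by exp(gamma * z(window amplitude)): gamma = 0 is the exact identity (no
    extra noise, scaling structure untouched), gamma > 0 amplifies
    fluctuations in high-amplitude windows (fE/I < 1), gamma < 0 in
    low-amplitude windows (fE/I > 1).
    """
    n = int(round(spec.duration * spec.fs))
    h = generate_fgn(spec.hurst, n, rng=rng)
    env = np.exp(spec.env_sigma * h)
    win = int(round(40 * spec.fs / spec.f0))
    n_win = n // win
    if n_win >= 2 and spec.coupling != 0.0:
        w_amp = np.array([env[i * win : (i + 1) * win].mean() for i in range(n_win)])
        z = (w_amp - w_amp.mean()) / (w_amp.std() + 1e-12)
        for i in range(n_win):
            sl = slice(i * win, (i + 1) * win)
            seg = env[sl]
            env[sl] = seg.mean() + (seg - seg.mean()) * np.exp(spec.coupling * z[i])
        env = np.clip(env, 0.01, None)
    return env


def generate_oscillation(spec: OscillationSpec) -> ParcelTimeSeries:
    """Single-parcel oscillation: carrier x LRTC envelope + 1/f background."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    env = generate_envelope(spec, rng)
    t = np.arange(n) / spec.fs
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * spec.f0 * t + phase)
    signal = env * carrier
    if np.isfinite(spec.snr):
        background = _one_over_f_noise(n, rng)
        signal = signal + background * (signal.std() / spec.snr)
    return ParcelTimeSeries(
        data=signal[:, None],
        fs=spec.fs,
        parcel_ids=["p000"],
        system_ids=["DMN"],
        subject_id="synthetic",
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Cross-sectional three-group cohort specification.

    Shifts are additive offsets applied to the group's DFA / fE/I maps within
    each named band, relative to the HC baseline.  Defaults encode the
    direction of effects reported for the dementia continuum: alpha/beta DFA
    attenuation SCD < HC and MCI < SCD, elevated fE/I in MCI.
    """

    group_sizes: tuple[int, int, int] = (116, 85, 142)
    n_parcels: int = 400
    n_freqs: int = 32
    fmin: float = 2.0
    fmax: float = 90.0
    dfa_shift: dict = field(
        default_factory=lambda: {
            "SCD": {"alpha": -0.020, "beta": -0.010},
            "MCI": {"alpha": -0.035, "beta": -0.030, "theta": -0.010},
        }
    )
    fei_shift: dict = field(
        default_factory=lambda: {
            "SCD": {"alpha": -0.010},
            "MCI": {"alpha": 0.040, "beta": 0.050},
        }
    )
    subject_sd: float = 0.03
    parcel_sd: float = 0.04
    mmse_dfa_coupling: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 2")


@dataclass
class CohortDataset:
    """Subjects with group labels, covariates and criticality maps."""

    subjects: pd.DataFrame  # subject_id, group, age, mmse, vol_* columns
    maps: list[CritMaps]
    freqs: np.ndarray
    system_ids: list[str]
    timeseries: list[ParcelTimeSeries] | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def groups(self) -> list[str]:
        return list(pd.unique(self.subjects["group"]))

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.subjects["group"] == group).to_numpy())


def _dfa_baseline(freqs: np.ndarray) -> np.ndarray:
    """Broad alpha-beta DFA peak over a white-noise floor, per frequency."""
    lf = np.log(freqs)
    return 0.58 + 0.14 * np.exp(-((lf - np.log(11.0)) ** 2) / (2 * 0.45**2))


def _fei_baseline(freqs: np.ndarray) -> np.ndarray:
    """Slightly inhibition-dominated baseline (~0.85-0.95) across frequencies."""
    lf = np.log(freqs)
    return 0.92 - 0.04 * np.exp(-((lf - np.log(10.0)) ** 2) / (2 * 0.6**2))


_BAND_EDGES = {"theta": (4.0, 7.0), "alpha": (7.0, 12.0), "beta": (12.0, 30.0)}


def _band_offsets(freqs: np.ndarray, shifts: dict[str, float]) -> np.ndarray:
    out = np.zeros_like(freqs)
    for band, delta in shifts.items():
        lo, hi = _BAND_EDGES[band]
        out[(freqs >= lo) & (freqs < hi)] += delta
    return out


def _assign_systems(n_parcels: int) -> list[str]:
    return [FUNCTIONAL_SYSTEMS[i % len(FUNCTIONAL_SYSTEMS)] for i in range(n_parcels)]


def _sample_maps(
    rng: np.random.Generator,
    freqs: np.ndarray,
    n_parcels: int,
    dfa_offset: np.ndarray,
    fei_offset: np.ndarray,
    subject_sd: float,
    parcel_sd: float,
    subject_id: str,
    system_ids: list[str],
) -> CritMaps:
    dfa_subj = rng.normal(0.0, subject_sd)
    fei_subj = rng.normal(0.0, subject_sd)
    # parcel noise smoothed along frequency so maps look spectrally coherent
    dfa_noise = gaussian_filter1d(rng.normal(0.0, parcel_sd, (n_parcels, freqs.size)), 1.5, axis=1)
    fei_noise = gaussian_filter1d(rng.normal(0.0, parcel_sd, (n_parcels, freqs.size)), 1.5, axis=1)
    dfa_map = _dfa_baseline(freqs) + dfa_offset + dfa_subj + dfa_noise
    fei_map = _fei_baseline(freqs) + fei_offset + fei_subj + fei_noise
    dfa_map = np.clip(dfa_map, 0.4, 1.0)
    valid = dfa_map > 0.6
    fei_map = np.where(valid, fei_map, np.nan)
    return CritMaps(
        dfa=dfa_map,
        fei=fei_map,
        valid=valid,
        freqs=freqs,
        parcel_ids=[f"p{i:03d}" for i in range(n_parcels)],
        system_ids=system_ids,
        subject_id=subject_id,
    )


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Feature-level cohort: subjects' DFA/fE/I maps sampled directly.

    Group structure enters as band-limited additive shifts on the baseline
    spectra; covariates (age, six MTL volumes) are drawn from the published
    group means/SDs, and MMSE is generated with a positive dependence on each
    subject's alpha-band DFA so criticality-cognition correlations exist.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.geomspace(spec.fmin, spec.fmax, spec.n_freqs)
    system_ids = _assign_systems(spec.n_parcels)
    alpha_idx = (freqs >= 7.0) & (freqs < 12.0)

    rows, maps = [], []
    for group, size in zip(GROUPS, spec.group_sizes):
        dfa_off = _band_offsets(freqs, spec.dfa_shift.get(group, {}))
        fei_off = _band_offsets(freqs, spec.fei_shift.get(group, {}))
        age_m, age_sd = COHORT_AGES[group]
        mmse_m, mmse_sd = MMSE_LEVELS[group]
        for i in range(size):
            sid = f"{group}_{i:03d}"
            cm = _sample_maps(
                rng, freqs, spec.n_parcels, dfa_off, fei_off,
                spec.subject_sd, spec.parcel_sd, sid, system_ids,
            )
            alpha_dfa = float(cm.dfa[:, alpha_idx].mean())
            mmse = (
                mmse_m
                + spec.mmse_dfa_coupling * (alpha_dfa - 0.68) / spec.subject_sd * mmse_sd * 0.3
                + rng.normal(0.0, mmse_sd)
            )
            row = {
                "subject_id": sid,
                "group": group,
                "age": rng.normal(age_m, age_sd),
                "mmse": float(np.clip(mmse, 0.0, 30.0)),
            }
            for vol, stats in MTL_VOLUMES.items():
                m, sd = stats[group]
                row[vol] = max(rng.normal(m, sd), 1e-5)
            rows.append(row)
            maps.append(cm)
    return CohortDataset(
        subjects=pd.DataFrame(rows), maps=maps, freqs=freqs, system_ids=system_ids
    )


def generate_signal_cohort(
    spec: CohortSpec,
    f0: float = 10.0,
    fs: float = 250.0,
    duration: float = 120.0,
    n_parcels: int = 20,
    hurst_by_group: dict[str, float] | None = None,
    coupling_by_group: dict[str, float] | None = None,
) -> CohortDataset:
    """Signal-level cohort: per-subject multi-parcel oscillation time series.

    Group contrasts are induced at the generator level (Hurst exponent for
    DFA, amplitude-fluctuation coupling for fE/I) so that running the full
    filter -> DFA -> fE/I chain reproduces the same direction of effects as
    the feature-level mode.  Scaled for desk use: few parcels, one carrier.
    """
    hurst_by_group = hurst_by_group or {"HC": 0.78, "SCD": 0.72, "MCI": 0.66}
    coupling_by_group = coupling_by_group or {"HC": 0.0, "SCD": 0.1, "MCI": -0.4}
    rng = np.random.default_rng(spec.seed)
    system_ids = _assign_systems(n_parcels)
    rows, series = [], []
    for group, size in zip(GROUPS, spec.group_sizes):
        age_m, age_sd = COHORT_AGES[group]
        mmse_m, mmse_sd = MMSE_LEVELS[group]
        for i in range(size):
            sid = f"{group}_{i:03d}"
            data = np.empty((int(round(duration * fs)), n_parcels))
            for p in range(n_parcels):
                ospec = OscillationSpec(
                    f0=f0, fs=fs, duration=duration,
                    hurst=float(np.clip(hurst_by_group[group] + rng.normal(0, 0.02), 0.05, 0.95)),
                    coupling=coupling_by_group[group],
                    seed=int(rng.integers(2**31)),
                )
                data[:, p] = generate_oscillation(ospec).data[:, 0]
            series.append(
                ParcelTimeSeries(data=data, fs=fs, system_ids=system_ids, subject_id=sid)
            )
            row = {
                "subject_id": sid, "group": group,
                "age": rng.normal(age_m, age_sd),
                "mmse": float(np.clip(rng.normal(mmse_m, mmse_sd), 0, 30)),
            }
            for vol, stats in MTL_VOLUMES.items():
                m, sd = stats[group]
                row[vol] = max(rng.normal(m, sd), 1e-5)
            rows.append(row)
    return CohortDataset(
        subjects=pd.DataFrame(rows), maps=[], freqs=np.array([f0]),
        system_ids=system_ids, timeseries=series,
    )


# ---------------------------------------------------------------------------
# longitudinal


@dataclass(frozen=True)
class LongitudinalSpec:
    """Stable vs progressive MCI subcohorts at two timepoints."""

    n_stable: int = 22
    n_prog: int = 23
    n_parcels: int = 400
    n_freqs: int = 32
    fmin: float = 2.0
    fmax: float = 90.0
    # timepoint-2 shifts for the progressive group (stable group drifts ~0)
    prog_dfa_shift_t2: dict = field(default_factory=lambda: {"alpha": -0.030, "beta": 0.020})
    prog_fei_shift_t2: dict = field(default_factory=lambda: {"alpha": 0.030, "beta": 0.040})
    subject_sd: float = 0.03
    parcel_sd: float = 0.04
    seed: int | None = None


def generate_longitudinal(spec: LongitudinalSpec) -> tuple[CohortDataset, CohortDataset]:
    """Paired two-timepoint cohorts (baseline, follow-up).

    Both subcohorts start from MCI-like maps; at follow-up the progressive
    group receives additional band shifts (DFA attenuation in alpha, elevated
    fE/I) while the stable group stays put.  MMSE at both timepoints is drawn
    from the published subcohort means/SDs.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.geomspace(spec.fmin, spec.fmax, spec.n_freqs)
    system_ids = _assign_systems(spec.n_parcels)
    base_dfa = _band_offsets(freqs, {"alpha": -0.035, "beta": -0.030})
    base_fei = _band_offsets(freqs, {"alpha": 0.040, "beta": 0.050})

    def make(group: str, n: int, t2: bool) -> tuple[list[dict], list[CritMaps]]:
        info = LONGITUDINAL[group]
        mmse_m, mmse_sd = info["mmse_t2"] if t2 else info["mmse_t1"]
        age_m, age_sd = info["age_t1"]
        rows, maps = [], []
        for i in range(n):
            sid = f"{group}_{i:03d}"
            dfa_off = base_dfa.copy()
            fei_off = base_fei.copy()
            if t2 and group == "prog":
                dfa_off = dfa_off + _band_offsets(freqs, spec.prog_dfa_shift_t2)
                fei_off = fei_off + _band_offsets(freqs, spec.prog_fei_shift_t2)
            cm = _sample_maps(
                rng, freqs, spec.n_parcels, dfa_off, fei_off,
                spec.subject_sd, spec.parcel_sd, sid, system_ids,
            )
            rows.append({
                "subject_id": sid, "group": group,
                "age": rng.normal(age_m, age_sd) + (2.0 if t2 else 0.0),
                "mmse": float(np.clip(rng.normal(mmse_m, mmse_sd), 0, 30)),
            })
            maps.append(cm)
        return rows, maps

    datasets = []
    for t2 in (False, True):
        # per-timepoint subject draws are independent across covariates but
        # map construction shares the same rng stream for determinism
        rows_s, maps_s = make("stable", spec.n_stable, t2)
        rows_p, maps_p = make("prog", spec.n_prog, t2)
        datasets.append(
            CohortDataset(
                subjects=pd.DataFrame(rows_s + rows_p),
                maps=maps_s + maps_p,
                freqs=freqs,
                system_ids=system_ids,
            )
        )
    return datasets[0], datasets[1]
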