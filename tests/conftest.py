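"""Shared fixtures and independent oracle implementations.

Oracles deliberately share no code with the package: brute-force DFA uses
plain loops + ordinary least squares, the Wilcoxon oracle enumerates label
assignments, and the BH oracle applies the step-up rule literally.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from neurocrit.synth import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# oracles


def brute_force_dfa(x: np.ndarray, fs: float, fit_lo: float = 2.0, fit_hi: float = 25.0,
                    n_sizes: int = 10, overlap: float = 0.5) -> float:
    """Independent DFA: explicit loops, polyfit detrending, plain OLS slope."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - np.mean(x))
    sizes = np.unique(np.round(np.geomspace(fit_lo * fs, fit_hi * fs, n_sizes)).astype(int))
    log_s, log_f = [], []
    for s in sizes:
        step = max(1, int(round(s * (1 - overlap))))
        sq_sum, count = 0.0, 0
        t = np.arange(s)
        for start in range(0, len(y) - s + 1, step):
            seg = y[start:start + s]
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            sq_sum += np.sum(resid**2)
            count += s
        log_s.append(np.log10(s / fs))
        log_f.append(0.5 * np.log10(sq_sum / count))
    slope, _ = np.polyfit(log_s, log_f, 1)
    return float(slope)


def exact_ranksum_p(a, b) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of label assignments."""
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n1 = len(a)
    observed = ranks[:n1].sum()
    sums = np.array([ranks[list(c)].sum() for c in combinations(range(len(pooled)), n1)])
    mu = sums.mean()
    p = np.mean(np.abs(sums - mu) >= np.abs(observed - mu) - 1e-12)
    return float(p)


def _midranks(v):
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_force_bh_mask(pvals: np.ndarray, q: float) -> np.ndarray:
    """Literal step-up rule: largest i with p_(i) <= i/m * q; reject 1..i."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    mask = np.zeros(m, dtype=bool)
    cut = -1
    for i in range(m):
        if p[order[i]] <= (i + 1) / m * q:
            cut = i
    if cut >= 0:
        mask[order[:cut + 1]] = True
    return mask


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_cohort():
    """Feature-level three-group cohort, desk-scale (85 subjects)."""
    spec = CohortSpec(group_sizes=(30, 25, 30), n_parcels=21, n_freqs=12, seed=11)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
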