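"""Nonparametric group statistics for criticality metrics.

The battery mirrors a standard cross-sectional electrophysiology analysis:
Kruskal-Wallis omnibus tests across the three cohorts per frequency,
pairwise Wilcoxon contrasts (rank-sum for independent cohorts, signed-rank
for paired longitudinal data), Benjamini-Hochberg FDR control over each test
family, eta-squared / r effect sizes, percentile-bootstrap confidence
intervals, Spearman correlations (optionally partialled on a covariate), and
pooled-variance t statistics recomputable from printed summary data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# elementary tests


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float, float]:
    """Kruskal-Wallis H with tie correction, chi-square p, and eta-squared.

    eta^2 = (H - k + 1) / (n - k), clipped at 0, is the rank-based analogue
    of the ANOVA effect size.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    n = sum(g.size for g in groups)
    if n < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, 0.0
    h, p = sps.kruskal(*groups)
    k = len(groups)
    eta2 = max(0.0, (h - k + 1) / (n - k))
    return float(h), float(p), float(eta2)


def pairwise_wilcoxon(
    a: np.ndarray, b: np.ndarray, paired: bool = False
) -> tuple[float, float, float]:
    """Two-sided Wilcoxon contrast with effect size r = |Z| / sqrt(N).

    Unpaired data use the rank-sum (Mann-Whitney) test, paired data the
    signed-rank test.  Exact p-values are used for small samples without
    ties; larger samples use the tie/continuity-corrected normal
    approximation.  Identical paired samples give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0, 0.0
        n_eff = np.count_nonzero(d)
        method = "exact" if n_eff <= 25 else "approx"
        res = sps.wilcoxon(a, b, zero_method="wilcox", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        # recover |Z| from the signed-rank null moments
        mu = n_eff * (n_eff + 1) / 4.0
        sigma = np.sqrt(n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0)
        z = (stat - mu) / sigma if sigma > 0 else 0.0
        r = abs(z) / np.sqrt(a.size)
    else:
        method = "exact" if (a.size <= 25 and b.size <= 25) else "asymptotic"
        try:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:  # ties prevent the exact path
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        n1, n2 = a.size, b.size
        mu = n1 * n2 / 2.0
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (stat - mu) / sigma if sigma > 0 else 0.0
        r = abs(z) / np.sqrt(n1 + n2)
    return stat, p, float(r)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and mask at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def bootstrap_ci(
    x: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    statistic=np.mean,
) -> tuple[float, float]:
    """Percentile bootstrap interval of a statistic of ``x`` (default mean)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]):
        c = float(statistic(x))
        return c, c
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    reps = statistic(x[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def spearman_corr(
    x: np.ndarray, y: np.ndarray, covariate: np.ndarray | None = None
) -> tuple[float, float]:
    """Spearman rank correlation, optionally partialled on a covariate.

    Partial form: the ranks of x and y are residualized on the covariate by
    least squares before the product-moment correlation, i.e. a partial
    Spearman correlation.  Zero-variance input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    if covariate is None:
        rho, p = sps.spearmanr(x, y)
        return float(rho), float(p)
    c = np.asarray(covariate, dtype=float)
    rx, ry, rc = (sps.rankdata(v) for v in (x, y, c))
    design = np.column_stack([np.ones_like(rc), rc])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    if np.std(ex) == 0 or np.std(ey) == 0:
        return float("nan"), float("nan")
    rho, p = sps.pearsonr(ex, ey)
    return float(rho), float(p)


def ttest_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, level: float = 0.95
) -> tuple[float, int, tuple[float, float]]:
    """Pooled-variance two-sample t from printed means, SDs and sizes.

    Returns (t, df, CI of the mean difference m1 - m2).  This recomputes the
    independent-samples t statistics reported for cohort demographics
    directly from their summary rows.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    tcrit = sps.t.ppf(0.5 + level / 2.0, df)
    diff = m1 - m2
    return float(t), int(df), (float(diff - tcrit * se), float(diff + tcrit * se))


# ---------------------------------------------------------------------------
# battery over a cohort


@dataclass(frozen=True)
class StatConfig:
    q_wholebrain: float = 0.1
    q_parcel: float = 0.2
    alphas: tuple[float, ...] = (0.05, 0.01)
    n_boot: int = 10_000
    seed: int | None = None


def _pair_name(a: str, b: str) -> str:
    return f"{a}-{b}"


def run_stat_battery(
    cohort,
    metric: str = "dfa",
    config: StatConfig | None = None,
    parcel_level: bool = True,
) -> pd.DataFrame:
    """Omnibus + pairwise contrasts of a criticality metric across cohorts.

    Whole-brain scope: per frequency, a Kruskal-Wallis omnibus over all
    groups plus pairwise rank-sum contrasts; one BH-FDR family per test type
    at q_wholebrain.  Parcel scope: pairwise contrasts per parcel x frequency
    with a single BH-FDR family spanning all parcels, frequencies and
    contrasts at q_parcel.  Significance flags use the smallest configured
    alpha screen on adjusted p-values, as column ``sig_<alpha>``.

    Returns a tidy table keyed by (contrast, scope, frequency, parcel).
    """
    config = config or StatConfig()
    groups = cohort.groups()
    n_freqs = cohort.freqs.size
    # stack whole-brain (parcel-mean) values: subjects x freqs
    wb = np.vstack([m.whole_brain(metric) for m in cohort.maps])
    by_group = {g: wb[cohort.group_indices(g)] for g in groups}

    rows: list[dict] = []
    # --- whole-brain omnibus
    omni_p = np.empty(n_freqs)
    for k in range(n_freqs):
        samples = [by_group[g][:, k] for g in groups]
        samples = [s[np.isfinite(s)] for s in samples]
        h, p, eta2 = kruskal_wallis(*samples)
        omni_p[k] = p
        rows.append(
            {"contrast": "omnibus", "scope": "whole-brain", "freq": cohort.freqs[k],
             "parcel": "", "statistic": h, "p": p, "effect": eta2}
        )
    # --- whole-brain pairwise
    pair_rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            for k in range(n_freqs):
                xa = by_group[a][:, k]
                xb = by_group[b][:, k]
                xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
                stat, p, r = pairwise_wilcoxon(xa, xb)
                pair_rows.append(
                    {"contrast": _pair_name(a, b), "scope": "whole-brain",
                     "freq": cohort.freqs[k], "parcel": "", "statistic": stat,
                     "p": p, "effect": r}
                )
    # FDR: one family per test type at the whole-brain level
    omni_adj, _ = bh_fdr(omni_p, config.q_wholebrain)
    for row, adj in zip(rows, omni_adj):
        row["p_adj"] = adj
    pair_p = np.array([r["p"] for r in pair_rows])
    if pair_p.size:
        pair_adj, _ = bh_fdr(pair_p, config.q_wholebrain)
        for row, adj in zip(pair_rows, pair_adj):
            row["p_adj"] = adj
    rows.extend(pair_rows)

    # --- parcel level: one family across parcels x freqs x contrasts
    if parcel_level:
        n_parcels = cohort.maps[0].n_parcels
        stack = np.stack(
            [m.dfa if metric == "dfa" else np.where(m.valid, m.fei, np.nan) for m in cohort.maps]
        )  # subjects x parcels x freqs
        parcel_rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                xa = stack[cohort.group_indices(a)]
                xb = stack[cohort.group_indices(b)]
                stat, p = _vectorized_ranksum(xa, xb)
                for pi in range(n_parcels):
                    for k in range(n_freqs):
                        parcel_rows.append(
                            {"contrast": _pair_name(a, b), "scope": "parcel",
                             "freq": cohort.freqs[k],
                             "parcel": cohort.maps[0].parcel_ids[pi],
                             "statistic": stat[pi, k], "p": p[pi, k],
                             "effect": np.nan}
                        )
        pp = np.array([r["p"] for r in parcel_rows])
        finite = np.isfinite(pp)
        adj = np.full(pp.size, np.nan)
        if finite.any():
            adj[finite], _ = bh_fdr(pp[finite], config.q_parcel)
        for row, a_ in zip(parcel_rows, adj):
            row["p_adj"] = a_
        rows.extend(parcel_rows)

    table = pd.DataFrame(rows)
    for alpha in config.alphas:
        table[f"sig_{alpha}"] = table["p_adj"] <= alpha
    return table


def _vectorized_ranksum(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mann-Whitney U along axis 0 for (subjects x parcels x freqs) stacks.

    NaN cells (fE/I invalidity) are handled by scipy's nan policy: a cell's
    test uses only its finite subjects; all-NaN cells yield NaN.
    """
    with np.errstate(invalid="ignore"):
        res = sps.mannwhitneyu(
            xa, xb, alternative="two-sided", axis=0, nan_policy="omit", method="asymptotic"
        )
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    return stat, p


def percent_significant(table: pd.DataFrame, contrast: str, alpha: float = 0.05) -> pd.Series:
    """Percent of parcels significant per frequency for one parcel-level contrast."""
    sub = table[(table["scope"] == "parcel") & (table["contrast"] == contrast)]
    col = f"sig_{alpha}"
    if col not in sub.columns:
        raise ValueError(f"alpha {alpha} not in table (columns: {list(sub.columns)})")
    return sub.groupby("freq")[col].mean() * 100.0
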