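"""Dementia-stage classification from criticality and volumetric features.

The feature matrix holds, per subject, the DFA exponent and fE/I value
averaged within each canonical band (theta/alpha/beta) and functional system
(7 systems) — 2 x 3 x 7 = 42 functional columns — plus the six bilateral
medial-temporal-lobe volumes.  A minimum-redundancy-maximum-relevance
(mRMR) ranking reduces dimensionality; a k-nearest-neighbors classifier is
tuned by leave-one-out grid search over k and the number of features on a
stratified 75/25 train/test split, and evaluated on the held-out quarter by
ROC/AUC plus threshold metrics.

Leakage discipline: the parcel mask, z-scoring parameters and mRMR ranking
are all derived inside the training data only (re-derived inside every LOO
fold); fitted components carry provenance tags asserting which rows they saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier

from .criticality import BandRegistry
from .signal import FUNCTIONAL_SYSTEMS
from .synth import MTL_VOLUMES

VOLUME_COLUMNS = tuple(MTL_VOLUMES)


# ---------------------------------------------------------------------------
# feature assembly


@dataclass
class FeatureMatrix:
    X: pd.DataFrame  # subjects x features
    y: np.ndarray  # binary labels (1 = second class of the pair)
    classes: tuple[str, str]
    subject_ids: list[str]
    mask_provenance: str = "all-parcels"

    @property
    def n_features(self) -> int:
        return int(self.X.shape[1])

    def rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            classes=self.classes,
            subject_ids=[self.subject_ids[i] for i in idx],
            mask_provenance=self.mask_provenance,
        )


def assemble_features(
    cohort,
    pair: tuple[str, str],
    bands: BandRegistry | None = None,
    systems: tuple[str, ...] = FUNCTIONAL_SYSTEMS,
    parcel_mask: np.ndarray | None = None,
    mask_provenance: str = "all-parcels",
    include_volumes: bool = True,
) -> FeatureMatrix:
    """Build the subject x feature table for one cohort pair.

    Per subject, metric, band and system: the mean of the metric over masked
    parcels of that system and grid frequencies of that band (invalid fE/I
    cells excluded).  A (band, system) cell whose mask leaves no parcel falls
    back to all parcels of the system with a warning-level provenance note.
    Feature names follow ``<metric>_<band>_<system>`` and ``vol_<side>_<region>``.
    """
    import logging

    log = logging.getLogger(__name__)
    bands = bands or BandRegistry()
    sel = cohort.subjects["group"].isin(pair).to_numpy()
    idx = np.flatnonzero(sel)
    labels = (cohort.subjects["group"].to_numpy()[idx] == pair[1]).astype(int)
    system_arr = np.asarray(cohort.system_ids)
    freqs = cohort.freqs
    if parcel_mask is None:
        parcel_mask = np.ones(system_arr.size, dtype=bool)

    cells: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for band in bands.names():
        fidx = bands.membership(freqs, band)
        if fidx.size == 0:
            raise ValueError(f"band {band!r} has no grid frequencies")
        for system in systems:
            pidx = np.flatnonzero((system_arr == system) & parcel_mask)
            if pidx.size == 0:
                pidx = np.flatnonzero(system_arr == system)
                log.warning(
                    "empty mask for (%s, %s); falling back to all parcels", band, system
                )
            cells[(band, system)] = (pidx, fidx)

    rows = []
    for i in idx:
        cm = cohort.maps[i]
        row = {}
        for metric in ("dfa", "fei"):
            vals = cm.dfa if metric == "dfa" else np.where(cm.valid, cm.fei, np.nan)
            for (band, system), (pidx, fidx) in cells.items():
                cell = vals[np.ix_(pidx, fidx)]
                finite = np.isfinite(cell)
                row[f"{metric}_{band}_{system}"] = (
                    float(cell[finite].mean()) if finite.any() else np.nan
                )
        rows.append(row)
    X = pd.DataFrame(rows)
    if include_volumes:
        for col in VOLUME_COLUMNS:
            X[col] = cohort.subjects[col].to_numpy()[idx]
    # median imputation for residual NaNs (all-invalid fE/I cells)
    X = X.fillna(X.median(numeric_only=True))
    return FeatureMatrix(
        X=X,
        y=labels,
        classes=tuple(pair),
        subject_ids=[cohort.subjects["subject_id"].iloc[i] for i in idx],
        mask_provenance=mask_provenance,
    )


def derive_parcel_mask(cohort, pair: tuple[str, str], train_idx: np.ndarray,
                       metric: str = "dfa", alpha: float = 0.05) -> np.ndarray:
    """Parcels showing a significant pairwise contrast, from training rows only.

    Uncorrected rank-sum per parcel on band-collapsed maps; used as the
    feature-averaging mask.  Returns an all-parcels mask if nothing reaches
    alpha (so feature assembly never sees an empty mask).
    """
    from scipy import stats as sps

    sub = cohort.subjects.iloc[train_idx]
    ia = train_idx[(sub["group"] == pair[0]).to_numpy()]
    ib = train_idx[(sub["group"] == pair[1]).to_numpy()]
    stack = np.stack(
        [m.dfa if metric == "dfa" else np.where(m.valid, m.fei, np.nan) for m in cohort.maps]
    )
    xa = np.nanmean(stack[ia], axis=2)  # subjects x parcels
    xb = np.nanmean(stack[ib], axis=2)
    with np.errstate(invalid="ignore"):
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", axis=0,
                               nan_policy="omit", method="asymptotic")
    mask = np.asarray(res.pvalue) < alpha
    return mask if mask.any() else np.ones(mask.size, dtype=bool)


# ---------------------------------------------------------------------------
# mRMR


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning (rank-based), robust to ties."""
    ranks = pd.Series(x).rank(method="average").to_numpy()
    return np.minimum((ranks - 1) / len(x) * n_bins, n_bins - 1).astype(int)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in nats from the joint contingency of two discrete codes."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_select(X: np.ndarray, y: np.ndarray, n_select: int) -> list[int]:
    """Greedy mRMR (MID scheme): maximize MI(f; y) - mean MI(f; selected).

    Features are discretized into equal-frequency bins (sqrt(n) rule); the
    class label is used as-is.  Returns feature indices in selection order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, m = X.shape
    if n_select > m:
        raise ValueError(f"n_select ({n_select}) > n_features ({m})")
    n_bins = max(2, int(np.sqrt(n)))
    disc = np.column_stack([_discretize(X[:, j], n_bins) for j in range(m)])
    relevance = np.array([_mutual_information(disc[:, j], y) for j in range(m)])
    selected: list[int] = [int(np.argmax(relevance))]
    red_cache = np.zeros(m)
    pairwise: dict[tuple[int, int], float] = {}

    def mi_pair(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in pairwise:
            pairwise[key] = _mutual_information(disc[:, i], disc[:, j])
        return pairwise[key]

    while len(selected) < n_select:
        last = selected[-1]
        remaining = [j for j in range(m) if j not in selected]
        for j in remaining:
            red_cache[j] += mi_pair(j, last)
        scores = relevance[remaining] - red_cache[remaining] / len(selected)
        selected.append(remaining[int(np.argmax(scores))])
    return selected


# ---------------------------------------------------------------------------
# kNN grid search with leave-one-out


@dataclass
class FittedModel:
    k: int
    n_features: int
    feature_order: list[int]  # mRMR order on the full training set
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    train_provenance: list[str]
    knn: KNeighborsClassifier
    loo_auc: float
    grid: pd.DataFrame  # (k, nf, auc) for every evaluated cell

    def scores(self, X: np.ndarray) -> np.ndarray:
        cols = self.feature_order[: self.n_features]
        Z = (X[:, cols] - self.scaler_mean) / self.scaler_std
        return self.knn.predict_proba(Z)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        cols = self.feature_order[: self.n_features]
        Z = (X[:, cols] - self.scaler_mean) / self.scaler_std
        return self.knn.predict(Z)


def _zscale(train: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < eps, 1.0, sd)
    return mu, sd


def loo_scores(
    X: np.ndarray, y: np.ndarray, k_range: range, nf_range: range
) -> dict[tuple[int, int], np.ndarray]:
    """Leave-one-out positive-class scores for every (k, Nf) grid cell.

    For each held-out row the scaler and the mRMR ranking are re-derived
    from the remaining rows (no leakage).  One ranking serves all Nf
    prefixes; squared distances accumulate over the ranked features so each
    extra feature is a rank-1 update, and all k values read the same sorted
    neighbor list.  The scores are identical to refitting a Euclidean kNN
    per (k, Nf) cell.
    """
    n = X.shape[0]
    max_nf = min(max(nf_range), X.shape[1])
    out = {(k, nf): np.empty(n) for k in k_range for nf in nf_range if nf <= max_nf and k < n - 1}
    if not out:
        raise ValueError(
            f"empty LOO grid: n_train = {n}, k_range = {list(k_range)}, "
            f"nf_range = {list(nf_range)}, n_features = {X.shape[1]}"
        )
    ks = [k for k in k_range if k < n - 1]
    nfs = [nf for nf in nf_range if nf <= max_nf]
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        Xtr, ytr = X[tr], y[tr]
        mu, sd = _zscale(Xtr)
        order = mrmr_select(Xtr, ytr, max_nf)
        Ztr = (Xtr - mu) / sd
        zte = (X[i] - mu) / sd
        d2 = np.zeros(n - 1)
        nf_seen = 0
        for nf in nfs:
            for col in order[nf_seen:nf]:
                d2 += (Ztr[:, col] - zte[col]) ** 2
            nf_seen = nf
            neighbor_y = ytr[np.argsort(d2, kind="stable")]
            for k in ks:
                out[(k, nf)][i] = neighbor_y[:k].mean()
    return out


def knn_grid_search(
    train: FeatureMatrix,
    k_range: range = range(11, 20),
    nf_range: range = range(6, 35),
) -> FittedModel:
    """Pick (k, Nf) maximizing leave-one-out AUC on the training rows.

    Ties break toward fewer features, then smaller k.  The returned model is
    refit on the full training set (scaling + mRMR + kNN) and carries the
    subject ids it was trained on as provenance.
    """
    X = train.X.to_numpy(dtype=float)
    y = train.y
    n = X.shape[0]
    if n < max(k_range) + 1:
        import logging

        logging.getLogger(__name__).warning(
            "train size %d skips k >= %d cells", n, n - 1
        )
    scores = loo_scores(X, y, k_range, nf_range)
    records = []
    for (k, nf), s in scores.items():
        auc = roc_auc_score(y, s) if len(np.unique(y)) == 2 else np.nan
        records.append({"k": k, "nf": nf, "auc": auc})
    grid = pd.DataFrame(records)
    best = grid.sort_values(["auc", "nf", "k"], ascending=[False, True, True]).iloc[0]
    k_best, nf_best = int(best["k"]), int(best["nf"])

    mu, sd = _zscale(X)
    order = mrmr_select(X, y, min(max(nf_range), X.shape[1]))
    cols = order[:nf_best]
    knn = KNeighborsClassifier(n_neighbors=k_best)
    knn.fit((X[:, cols] - mu[cols]) / sd[cols], y)
    return FittedModel(
        k=k_best,
        n_features=nf_best,
        feature_order=order,
        scaler_mean=mu[cols],
        scaler_std=sd[cols],
        train_provenance=list(train.subject_ids),
        knn=knn,
        loo_auc=float(best["auc"]),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassifierReport:
    classes: tuple[str, str]
    k: int
    n_features: int
    feature_names: list[str]
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray] = field(repr=False, default=(np.array([]), np.array([])))
    loo_auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "k": self.k,
            "n_features": self.n_features,
            "feature_names": self.feature_names,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
            "loo_auc": self.loo_auc,
        }


def evaluate(model: FittedModel, test: FeatureMatrix) -> ClassifierReport:
    """Held-out metrics: kNN neighbor-fraction scores, ROC/AUC, vote metrics."""
    overlap = set(model.train_provenance) & set(test.subject_ids)
    if overlap:
        raise ValueError(f"test rows overlap training rows: {sorted(overlap)[:5]}")
    X = test.X.to_numpy(dtype=float)
    y = test.y
    s = model.scores(X)
    yhat = model.predict(X)
    tp = int(np.sum((yhat == 1) & (y == 1)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    acc = (tp + tn) / max(1, len(y))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    bal = np.nanmean([sens, spec])
    prec = tp / (tp + fp) if (tp + fp) else np.nan
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, s))
        fpr, tpr, _ = roc_curve(y, s)
    else:
        auc = float("nan")
        fpr = tpr = np.array([])
    names = list(test.X.columns[model.feature_order[: model.n_features]])
    return ClassifierReport(
        classes=test.classes,
        k=model.k,
        n_features=model.n_features,
        feature_names=names,
        accuracy=float(acc),
        balanced_accuracy=float(bal),
        precision=float(prec) if prec == prec else float("nan"),
        recall=float(sens) if sens == sens else float("nan"),
        auc=auc,
        roc=(fpr, tpr),
        loo_auc=model.loo_auc,
    )


def permutation_importance(
    model: FittedModel, test: FeatureMatrix, n_perm: int = 20, seed: int | None = None
) -> pd.Series:
    """Mean held-out AUC drop when one feature column is shuffled.

    Columns outside the model's selected subset have exactly zero importance
    (the model never reads them).
    """
    rng = np.random.default_rng(seed)
    X = test.X.to_numpy(dtype=float)
    y = test.y
    base = roc_auc_score(y, model.scores(X))
    used = set(model.feature_order[: model.n_features])
    drops = {}
    for j, name in enumerate(test.X.columns):
        if j not in used:
            drops[name] = 0.0
            continue
        acc = 0.0
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            acc += base - roc_auc_score(y, model.scores(Xp))
        drops[name] = acc / n_perm
    return pd.Series(drops, name="auc_drop")


def stratified_split(
    y: np.ndarray, test_fraction: float = 0.25, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test row split (75/25 by default)."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * idx.size)))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))
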