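"""End-to-end orchestration: simulate -> metrics -> stats -> classify -> report.

Every stage writes plain artifacts (CSV/JSON/HDF5) into the run directory
and a manifest records the config, seeds and row counts, so a run is fully
reproducible from its manifest.  All randomness is funneled through
per-stage seeds derived from the single run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ncio
from .config import RunConfig
from .criticality import BandRegistry, band_average, crit_maps
from .ml import (assemble_features, derive_parcel_mask, evaluate, knn_grid_search,
                 permutation_importance, stratified_split)
from .signal import build_frequency_grid
from .stats import StatConfig, run_stat_battery
from .synth import (CohortDataset, CohortSpec, LongitudinalSpec, generate_cohort,
                    generate_longitudinal, generate_signal_cohort)

log = logging.getLogger(__name__)

STAGES = ("simulate", "metrics", "stats", "classify", "report")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _bands(config: RunConfig) -> BandRegistry:
    return BandRegistry(bands=dict(config.synthetic.bands))


def simulate_stage(config: RunConfig, out: Path) -> CohortDataset:
    seed = _stage_seed(config.seed, "simulate")
    mode = config.synthetic.mode
    if mode == "features":
        spec = CohortSpec(
            group_sizes=config.synthetic.group_sizes,
            n_parcels=config.synthetic.n_parcels,
            n_freqs=config.grid.nfreq,
            fmin=config.grid.fmin,
            fmax=config.grid.fmax,
            seed=seed,
        )
        cohort = generate_cohort(spec)
    elif mode == "signal":
        spec = CohortSpec(group_sizes=config.synthetic.group_sizes, seed=seed)
        cohort = generate_signal_cohort(spec, n_parcels=config.synthetic.n_parcels)
    elif mode == "longitudinal":
        t1, t2 = generate_longitudinal(LongitudinalSpec(seed=seed))
        t2.subjects.to_csv(out / "subjects_t2.csv", index=False)
        cohort = t1
    else:  # pragma: no cover - config validation rejects this
        raise ValueError(mode)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    return cohort


def metrics_stage(config: RunConfig, cohort: CohortDataset, out: Path) -> CohortDataset:
    """Signal-level cohorts get their maps computed here; feature-level pass through."""
    if cohort.timeseries:
        grid = build_frequency_grid(
            config.grid.fmin, config.grid.fmax, config.grid.nfreq, config.grid.m
        )
        dfa_kw = {
            "fit_range": (config.dfa.fit_lo, config.dfa.fit_hi),
            "overlap": config.dfa.overlap,
            "n_sizes": config.dfa.n_sizes,
        }
        fei_kw = {
            "window_cycles": config.fei.window_cycles,
            "overlap": config.fei.overlap,
            "dfa_threshold": config.fei.dfa_threshold,
        }
        cohort.maps = [
            crit_maps(ts, grid, dfa_kwargs=dfa_kw, fei_kwargs=fei_kw)
            for ts in cohort.timeseries
        ]
        cohort.freqs = np.asarray(grid.freqs)
    n_invalid = sum(int((~m.valid).sum()) for m in cohort.maps)
    n_total = sum(m.valid.size for m in cohort.maps)
    log.info("metrics: %d/%d parcel-frequency cells excluded by fE/I validity",
             n_invalid, n_total)
    bands = _bands(config)

    def nanmean_or_nan(v: np.ndarray) -> float:
        v = np.asarray(v, dtype=float)
        finite = np.isfinite(v)
        return float(v[finite].mean()) if finite.any() else float("nan")

    rows = []
    for m, sid in zip(cohort.maps, cohort.subjects["subject_id"]):
        systems = np.asarray(m.system_ids) if m.system_ids else np.array([])
        for metric in ("dfa", "fei"):
            vals = m.dfa if metric == "dfa" else m.fei
            valid = None if metric == "dfa" else m.valid
            per_parcel = band_average(vals, m.freqs, bands, valid=valid)
            for band, series in per_parcel.items():
                if systems.size:
                    for system in np.unique(systems):
                        rows.append({"subject": sid, "metric": metric, "band": band,
                                     "system": system,
                                     "value": nanmean_or_nan(np.asarray(series)[systems == system])})
                rows.append({"subject": sid, "metric": metric, "band": band,
                             "system": "whole-brain",
                             "value": nanmean_or_nan(series)})
    ncio.write_band_means(out / "band_means.csv", pd.DataFrame(rows))
    return cohort


def stats_stage(config: RunConfig, cohort: CohortDataset, out: Path) -> dict:
    sc = StatConfig(
        q_wholebrain=config.stats.q_wholebrain,
        q_parcel=config.stats.q_parcel,
        alphas=config.stats.alphas,
        n_boot=config.stats.n_boot,
        seed=_stage_seed(config.seed, "stats"),
    )
    counts = {}
    for metric in ("dfa", "fei"):
        table = run_stat_battery(cohort, metric=metric, config=sc)
        table.to_csv(out / f"stats_{metric}.csv", index=False)
        wb = table[table["scope"] == "whole-brain"]
        counts[metric] = {
            "rows": int(len(table)),
            "wholebrain_sig": int(wb[f"sig_{min(config.stats.alphas)}"].sum()),
        }
    return counts


def classify_stage(config: RunConfig, cohort: CohortDataset, out: Path) -> dict:
    seed = _stage_seed(config.seed, "classify")
    bands = _bands(config)
    groups = cohort.groups()
    results = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pair = (groups[i], groups[j])
            sel = cohort.subjects["group"].isin(pair).to_numpy()
            pair_rows = np.flatnonzero(sel)
            labels = (cohort.subjects["group"].to_numpy()[pair_rows] == pair[1]).astype(int)
            tr_loc, te_loc = stratified_split(
                labels, config.ml.test_fraction, seed=seed + i * 7 + j
            )
            if config.ml.mask == "train":
                mask = derive_parcel_mask(cohort, pair, pair_rows[tr_loc])
                provenance = "train-derived"
            else:
                mask = None
                provenance = "all-parcels"
            fm = assemble_features(cohort, pair, bands=bands, parcel_mask=mask,
                                   mask_provenance=provenance)
            train, test = fm.rows(tr_loc), fm.rows(te_loc)
            model = knn_grid_search(train, config.ml.k_range, config.ml.nf_range)
            report = evaluate(model, test)
            importance = permutation_importance(model, test, seed=seed)
            payload = report.to_dict()
            payload["mask_provenance"] = provenance
            payload["importance_top5"] = (
                importance.sort_values(ascending=False).head(5).to_dict()
            )
            name = f"{pair[0]}_{pair[1]}"
            ncio.write_report(out / f"classifier_{name}.json", payload)
            results[name] = payload
    return results


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in order; returns the run directory."""
    config.validate()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": list(stages),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
    }
    cohort = None
    if "simulate" in stages:
        cohort = simulate_stage(config, out)
        manifest["n_subjects"] = cohort.n_subjects
    for stage in ("metrics", "stats", "classify"):
        if stage in stages:
            if cohort is None:
                raise RuntimeError(
                    f"stage {stage!r} requires the simulate stage (no cohort in memory)"
                )
            if stage == "metrics":
                cohort = metrics_stage(config, cohort, out)
            elif stage == "stats":
                manifest["stats"] = stats_stage(config, cohort, out)
            else:
                manifest["classifiers"] = classify_stage(config, cohort, out)
    if "report" in stages:
        config_bytes = json.dumps(config.to_dict(), sort_keys=True).encode()
        manifest["config_hash"] = hashlib.sha256(config_bytes).hexdigest()[:16]
        ncio.write_report(out / "manifest.json", manifest)
    return out
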