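"""Validated run configuration.

Defaults reproduce the study's analysis parameters: 32 wavelets spanning
2-90 Hz with width m = 5, DFA fit range 2-25 s with 50% window overlap,
40-cycle fE/I windows gated at DFA > 0.6, FDR q = 0.1 (whole-brain) and 0.2
(parcel level), and a stratified 75/25 train/test split for classification.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class GridConfig:
    fmin: float = 2.0
    fmax: float = 90.0
    nfreq: int = 32
    m: float = 5.0

    def validate(self) -> None:
        if self.fmin <= 0 or self.fmax < self.fmin:
            raise ValueError(f"grid: need 0 < fmin <= fmax, got ({self.fmin}, {self.fmax})")
        if self.nfreq < 1:
            raise ValueError("grid.nfreq must be >= 1")


@dataclass(frozen=True)
class DFAConfig:
    fit_lo: float = 2.0
    fit_hi: float = 25.0
    overlap: float = 0.5
    n_sizes: int = 10

    def validate(self) -> None:
        if not 0 < self.fit_lo < self.fit_hi:
            raise ValueError("dfa: need 0 < fit_lo < fit_hi")
        if not 0 <= self.overlap < 1:
            raise ValueError("dfa.overlap must be in [0, 1)")


@dataclass(frozen=True)
class FEIConfig:
    window_cycles: int = 40
    overlap: float = 0.8
    dfa_threshold: float = 0.6

    def validate(self) -> None:
        if self.window_cycles < 1:
            raise ValueError("fei.window_cycles must be >= 1")
        if not 0 <= self.overlap < 1:
            raise ValueError("fei.overlap must be in [0, 1)")


@dataclass(frozen=True)
class StatsConfig:
    q_wholebrain: float = 0.1
    q_parcel: float = 0.2
    alphas: tuple[float, ...] = (0.05, 0.01)
    n_boot: int = 10_000

    def validate(self) -> None:
        for q in (self.q_wholebrain, self.q_parcel, *self.alphas):
            if not 0 < q < 1:
                raise ValueError(f"stats: rates must be in (0, 1), got {q}")


@dataclass(frozen=True)
class MLConfig:
    k_lo: int = 11
    k_hi: int = 19
    nf_lo: int = 6
    nf_hi: int = 34
    test_fraction: float = 0.25
    mask: str = "train"  # train | all-parcels

    def validate(self) -> None:
        if self.k_lo > self.k_hi or self.nf_lo > self.nf_hi:
            raise ValueError("ml: ranges must satisfy lo <= hi")
        if not 0 < self.test_fraction < 1:
            raise ValueError("ml.test_fraction must be in (0, 1)")
        if self.mask not in ("train", "all-parcels"):
            raise ValueError(f"ml.mask must be 'train' or 'all-parcels', got {self.mask!r}")

    @property
    def k_range(self) -> range:
        return range(self.k_lo, self.k_hi + 1)

    @property
    def nf_range(self) -> range:
        return range(self.nf_lo, self.nf_hi + 1)


@dataclass(frozen=True)
class SyntheticConfig:
    mode: str = "features"  # features | signal | longitudinal
    group_sizes: tuple[int, int, int] = (116, 85, 142)
    n_parcels: int = 400
    bands: dict = field(
        default_factory=lambda: {"theta": (4.0, 7.0), "alpha": (7.0, 12.0), "beta": (12.0, 30.0)}
    )

    def validate(self) -> None:
        if self.mode not in ("features", "signal", "longitudinal"):
            raise ValueError(f"synthetic.mode invalid: {self.mode!r}")
        for name, (lo, hi) in self.bands.items():
            if lo >= hi:
                raise ValueError(f"band {name!r}: lo ({lo}) must be < hi ({hi})")


@dataclass(frozen=True)
class RunConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    dfa: DFAConfig = field(default_factory=DFAConfig)
    fei: FEIConfig = field(default_factory=FEIConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    ml: MLConfig = field(default_factory=MLConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    out_dir: str = "runs/latest"

    def validate(self) -> "RunConfig":
        for section in (self.grid, self.dfa, self.fei, self.stats, self.ml, self.synthetic):
            section.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file (missing sections fall back to defaults)."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update(overrides)

    def build(cls, key):
        section = raw.get(key, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section {key!r} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(section) - known
        if unknown:
            raise ValueError(f"config section {key!r}: unknown fields {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) and k in ("alphas", "group_sizes") else v
            for k, v in section.items()
        }
        if "bands" in coerced:
            coerced["bands"] = {n: tuple(b) for n, b in coerced["bands"].items()}
        return cls(**coerced)

    cfg = RunConfig(
        grid=build(GridConfig, "grid"),
        dfa=build(DFAConfig, "dfa"),
        fei=build(FEIConfig, "fei"),
        stats=build(StatsConfig, "stats"),
        ml=build(MLConfig, "ml"),
        synthetic=build(SyntheticConfig, "synthetic"),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "runs/latest")),
    )
    return cfg.validate()
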