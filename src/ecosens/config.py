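"""Configuration objects and deterministic seed fan-out.

A single integer seed drives every stochastic stage. Stages draw from
independent streams derived with :class:`numpy.random.SeedSequence` and a
fixed per-stage ``spawn_key``, so each stage is reproducible in isolation
and adding a stage never perturbs the randomness of another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError

# Fixed stream ids for seed fan-out (stable across versions).
STREAM_CLIMATE = 1
STREAM_EVI = 2
STREAM_RANGES = 3
STREAM_PHYLO = 4
STREAM_TRAITS = 5
STREAM_NULL = 6
STREAM_BETA = 7
STREAM_SAR = 8


def rng_for(seed: int, stream: int) -> np.random.Generator:
    """Return the generator for one named stream of a global seed."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(stream),)))


def int_seed_for(seed: int, stream: int) -> int:
    """A plain 31-bit integer sub-seed (for libraries wanting ``random.Random``)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(stream),))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system.

    The defaults describe the emulated study conditions: a 20-year monthly
    record on a 20x20 half-degree-like lattice, a few dozen vascular-plant
    species with spatially coherent ranges, an ultrametric phylogeny scaled
    to a 100 Myr root, and eight correlated functional traits with a fifth
    of the values missing.
    """

    n_rows: int = 20
    n_cols: int = 20
    n_years: int = 20
    n_species: int = 60
    seed: int = 0

    # climate
    base_temp: float = 24.0          # degC at row 0 (equatorward edge)
    lat_gradient: float = -1.2       # degC per row (poleward cooling)
    seasonal_amplitude_T: float = 8.0   # degC
    trend_T: float = 0.3             # degC per decade
    noise_sd_T: float = 1.0          # degC, month-to-month
    interannual_sd_T: float = 0.4    # degC, year-effect (ENSO-like) variability
    precip_mean: float = 80.0        # mm / month
    seasonal_amplitude_P: float = 40.0  # mm / month
    precip_phase: float = np.pi / 3  # radians offset vs temperature cycle
    noise_sd_P: float = 15.0         # mm / month, month-to-month
    interannual_sd_P: float = 8.0    # mm / month, year-effect variability

    # vegetation index construction
    beta_T_field: Optional[np.ndarray] = None   # (n_rows, n_cols) true coefficients
    beta_P_field: Optional[np.ndarray] = None
    beta_field_mode: str = "smooth"  # "smooth" | "iid" (used when fields are None)
    beta_T_mean: float = 0.45
    beta_T_sd: float = 0.15
    beta_P_mean: float = 0.25
    beta_P_sd: float = 0.10
    beta_smooth_sigma: float = 3.0   # cells, for the smooth mode
    beta_scale_mode: str = "both"    # "both" | "seasonal_only" | "interannual_only"
    evi_noise_sd: float = 0.05
    evi_base: float = 0.5
    evi_scale: float = 0.15

    # species ranges
    range_radius_mean: float = 6.0   # cells
    richness_gradient: float = 1.0   # >0 biases range centres equatorward

    # phylogeny
    tree_height: float = 100.0       # Myr root height
    n_trees: int = 10                # size of the perturbed tree set
    nni_moves_mean: float = 1.0      # Poisson mean of NNI moves per set member

    # traits
    n_traits: int = 8
    n_trait_factors: int = 3         # 0 => mutually independent Brownian traits
    bm_rate: float = 1.0             # trait variance per Myr
    trait_noise_sd: float = 0.5      # iid observational noise
    missing_frac: float = 0.2

    # biomes
    n_biomes: int = 3

    def __post_init__(self) -> None:
        self.validate()

    # -- derived sizes -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    def validate(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.n_years < 3:
            raise ConfigurationError("n_years must be >= 3")
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        for name in ("noise_sd_T", "noise_sd_P", "interannual_sd_T",
                     "interannual_sd_P", "evi_noise_sd", "trait_noise_sd", "bm_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ConfigurationError("missing_frac must be in [0, 1)")
        if self.beta_scale_mode not in ("both", "seasonal_only", "interannual_only"):
            raise ConfigurationError(f"unknown beta_scale_mode {self.beta_scale_mode!r}")
        if self.beta_field_mode not in ("smooth", "iid"):
            raise ConfigurationError(f"unknown beta_field_mode {self.beta_field_mode!r}")
        for name in ("beta_T_field", "beta_P_field"):
            f = getattr(self, name)
            if f is not None:
                f = np.asarray(f, dtype=float)
                if f.shape != (self.n_rows, self.n_cols):
                    raise ConfigurationError(
                        f"{name} shape {f.shape} does not match grid "
                        f"({self.n_rows}, {self.n_cols})"
                    )
                setattr(self, name, f)
        if self.n_biomes < 1 or self.n_biomes > self.n_rows:
            raise ConfigurationError("n_biomes must be in [1, n_rows]")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("beta_T_field", "beta_P_field"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for k in ("beta_T_field", "beta_P_field"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class PipelineConfig:
    """Full-pipeline configuration. Serialized verbatim into the run manifest
    (minus the output directory, so identical runs into different directories
    produce byte-identical artifacts)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    scales: Sequence[str] = ("seasonal", "interannual")
    climate_vars: Sequence[str] = ("T", "P")
    n_null_reps: int = 199
    seed: int = 0
    # toggles; defaults follow the source analysis choices
    null_pool: str = "global"            # "global" | "biome"
    limiting_rule: str = "absolute"      # "absolute" | "signed"
    pe_retention: str = "threshold"      # "threshold" | "fixed"
    pe_variance_threshold: float = 0.03
    pe_fixed_count: int = 6
    standardize_response: bool = False
    candidate_distances: Sequence[float] = (1.5, 2.5, 3.5, 5.0, 7.5, 10.0)
    min_biome_cells: int = 10

    def __post_init__(self) -> None:
        for s in self.scales:
            if s not in ("seasonal", "interannual"):
                raise ConfigurationError(f"unknown scale {s!r}")
        for v in self.climate_vars:
            if v not in ("T", "P"):
                raise ConfigurationError(f"unknown climate variable {v!r}")
        if self.n_null_reps < 2:
            raise ConfigurationError("n_null_reps must be >= 2")
        if self.null_pool not in ("global", "biome"):
            raise ConfigurationError(f"unknown null_pool {self.null_pool!r}")
        if self.limiting_rule not in ("absolute", "signed"):
            raise ConfigurationError(f"unknown limiting_rule {self.limiting_rule!r}")
        if self.pe_retention not in ("threshold", "fixed"):
            raise ConfigurationError(f"unknown pe_retention {self.pe_retention!r}")
        # keep the synthetic generator on the same global seed
        self.synthetic.seed = self.seed

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "synthetic"}
        d["scales"] = list(self.scales)
        d["climate_vars"] = list(self.climate_vars)
        d["candidate_distances"] = list(self.candidate_distances)
        d["synthetic"] = self.synthetic.to_jsonable()
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["synthetic"] = SyntheticConfig.from_jsonable(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_jsonable(json.load(fh))
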