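"""Configuration objects and shared vocabularies.

All simulation and pipeline parameters live in small validated dataclasses so
that a run is fully determined by (config, seed).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

FRACTIONS: tuple[str, ...] = ("DRM", "DSF", "SP", "IM")
MEMBRANE_FRACTIONS: tuple[str, ...] = ("DRM", "DSF")
REFERENCE_FRACTIONS: tuple[str, ...] = ("SP", "IM")

LIPID_CLASSES: tuple[str, ...] = (
    "PC", "PE", "PG", "PI", "PS", "Cer", "GlcCer",
    "DAG", "MGDG", "DGDG", "SQDG", "TAG",
)

#: classes excluded from the total-ion normalization denominator
NORMALIZATION_EXCLUDED_CLASSES: tuple[str, ...] = ("TAG",)


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


def _check_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class MissingnessModel:
    """Intensity-dependent dropout: a decreasing logistic in log10 intensity.

    P(missing | intensity I) = ``max_rate * expit(-(log10 I - log10_midpoint) / log10_width)``

    ``max_rate = 0`` disables dropout entirely.
    """

    max_rate: float = 0.0
    log10_midpoint: float = 6.0
    log10_width: float = 0.5

    def __post_init__(self) -> None:
        _check_proportion("missingness max_rate", self.max_rate)
        if self.log10_width <= 0:
            raise ConfigError("missingness log10_width must be > 0")

    def dropout_probability(self, intensity):
        import numpy as np
        from scipy.special import expit

        logi = np.log10(np.asarray(intensity, dtype=float))
        return self.max_rate * expit(-(logi - self.log10_midpoint) / self.log10_width)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for the synthetic evidence / lipid / peak generators."""

    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (3, 8)
    genotypes: tuple[str, ...] = ("wildtype", "mutant")
    fractions: tuple[str, ...] = FRACTIONS
    n_replicates: int = 4
    n_injections: int = 1
    frac_shifted: float = 0.1
    shift_log2: float = 2.0
    frac_copurifying: float = 0.1
    noise_cv: float = 0.2
    missing: MissingnessModel = field(default_factory=MissingnessModel)
    # lipid side
    n_lipids_per_class: int | Mapping[str, int] = 4
    lipid_classes: tuple[str, ...] = LIPID_CLASSES
    n_lipid_replicates: int | None = None
    frac_lipids_differential: float = 0.2
    lipid_fc_log2: float = 1.0
    lipid_noise_cv: float = 0.1
    mode_overlap: float = 0.2
    # coupling between planted protein shifts and a planted lipid change
    coupled_class: str | None = None
    coupled_fc_log2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ConfigError("peptides_per_protein must be an increasing range >= 1")
        if len(self.genotypes) < 2:
            raise ConfigError("need at least two genotypes (first is the wildtype)")
        if set(self.fractions) != set(FRACTIONS):
            raise ConfigError(f"fractions must be exactly {set(FRACTIONS)}")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.n_injections < 1:
            raise ConfigError("n_injections must be >= 1")
        for name in ("frac_shifted", "frac_copurifying", "frac_lipids_differential",
                     "mode_overlap"):
            _check_proportion(name, getattr(self, name))
        for name in ("shift_log2", "noise_cv", "lipid_fc_log2", "lipid_noise_cv",
                     "coupled_fc_log2"):
            v = getattr(self, name)
            if not (v == v and abs(v) < float("inf")):
                raise ConfigError(f"{name} must be finite")
        if self.noise_cv < 0 or self.lipid_noise_cv < 0:
            raise ConfigError("noise CVs must be >= 0")
        if self.coupled_class is not None and self.coupled_class not in self.lipid_classes:
            raise ConfigError(f"coupled_class {self.coupled_class!r} not in lipid_classes")

    @property
    def wildtype(self) -> str:
        return self.genotypes[0]

    @property
    def mutants(self) -> tuple[str, ...]:
        return tuple(self.genotypes[1:])

    def lipid_counts(self) -> dict[str, int]:
        if isinstance(self.n_lipids_per_class, Mapping):
            return {c: int(self.n_lipids_per_class.get(c, 0)) for c in self.lipid_classes}
        return {c: int(self.n_lipids_per_class) for c in self.lipid_classes}

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class AnalysisParams:
    """Downstream statistical parameters with the study defaults pre-filled."""

    min_presence: float = 0.70          # peptide fraction-presence rule
    presence_per_genotype: bool = False
    require_all_fractions: bool = False
    ratio_fdr: float = 0.01             # partitioning-shift FDR
    score_center: str = "mean"          # bootstrap location statistic
    n_boot: int = 1000
    n_perm: int = 200
    copurify_alpha: float = 0.01
    lipid_alpha: float = 0.05
    edge_fdr: float = 0.01
    edge_n_perm: int = 200
    ppm_tol: float = 5.0
    rt_tol: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_presence", "ratio_fdr", "copurify_alpha", "lipid_alpha",
                     "edge_fdr"):
            _check_proportion(name, getattr(self, name))
        for name in ("n_boot", "n_perm", "edge_n_perm"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.ppm_tol < 0 or self.rt_tol < 0:
            raise ConfigError("tolerances must be >= 0")
        if self.score_center not in ("mean", "median"):
            raise ConfigError("score_center must be 'mean' or 'median'")

    def replace(self, **kwargs) -> "AnalysisParams":
        return dataclasses.replace(self, **kwargs)
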