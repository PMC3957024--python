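"""Synthetic data generators with planted ground truth.

Generates peptide evidence tables, sample designs, lipid intensity tables,
peak/marker tables and protein annotation tables whose statistical structure
matches what the downstream analysis assumes: log-normal baselines, a
per-peptide ionization efficiency constant across samples, multiplicative
log-normal replicate noise, intensity-dependent dropout, and planted
DRM/DSF-partitioning shifts, co-purifying proteins and lipid fold changes.

Independent RNG streams are spawned for structure, noise and dropout so that
e.g. disabling dropout reproduces the exact same intensities for a given seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .config import ConfigError, MissingnessModel, SimulationConfig

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

LOCALIZATIONS = ("PM", "Pl", "ER", "V", "Go", "Ex", "Mi", "Pe", "Nu", "Cyt")
_LOC_WEIGHTS = (0.35, 0.12, 0.12, 0.06, 0.08, 0.05, 0.08, 0.04, 0.04, 0.06)

_POSITIVE_MODE_CLASSES = frozenset({"PC", "PE", "DAG", "TAG", "Cer", "GlcCer"})

_EVIDENCE_COLUMNS = ["peptide_id", "protein_id", "sample_id", "intensity"]


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each synthetic table."""

    shifted_proteins: dict[str, float] = field(default_factory=dict)
    copurifying_proteins: dict[str, str] = field(default_factory=dict)
    differential_lipids: dict[str, float] = field(default_factory=dict)
    true_edges: list[tuple[str, str]] = field(default_factory=list)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(
            shifted_proteins={**self.shifted_proteins, **other.shifted_proteins},
            copurifying_proteins={**self.copurifying_proteins, **other.copurifying_proteins},
            differential_lipids={**self.differential_lipids, **other.differential_lipids},
            true_edges=sorted(set(self.true_edges) | set(other.true_edges)),
        )
        return out

    def to_json(self, path) -> None:
        payload = {
            "shifted_proteins": self.shifted_proteins,
            "copurifying_proteins": self.copurifying_proteins,
            "differential_lipids": self.differential_lipids,
            "true_edges": [list(e) for e in self.true_edges],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            shifted_proteins=payload["shifted_proteins"],
            copurifying_proteins=payload["copurifying_proteins"],
            differential_lipids=payload["differential_lipids"],
            true_edges=[tuple(e) for e in payload["true_edges"]],
        )


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = _lognormal_sigma(cv)
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# protein-side structure (shared between evidence and lipid coupling)
# ---------------------------------------------------------------------------

@dataclass
class _ProteinStructure:
    protein_ids: list[str]
    baselines: np.ndarray              # (n_proteins,)
    weights: np.ndarray                # (n_proteins, 4) fraction profile DRM/DSF/SP/IM
    shifts: dict[str, float]           # protein_id -> signed log2 DRM shift in mutants
    copurifying: dict[str, str]        # protein_id -> top fraction (SP or IM)
    peptide_counts: np.ndarray         # (n_proteins,) peptides per protein


def _protein_structure(config: SimulationConfig) -> _ProteinStructure:
    rng = _rngs(config.seed, 4)[0]
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    baselines = np.exp(rng.normal(np.log(1e7), 1.0, size=n))

    # membrane-weighted fraction profiles; co-purifiers peak in SP or IM
    weights = rng.dirichlet([4.0, 4.0, 1.0, 1.0], size=n)
    n_cop = int(round(config.frac_copurifying * n))
    cop_idx = rng.choice(n, size=n_cop, replace=False) if n_cop else np.array([], dtype=int)
    copurifying: dict[str, str] = {}
    for i in cop_idx:
        top = "SP" if rng.random() < 0.5 else "IM"
        copurifying[ids[i]] = top
        # co-purifiers are abundant and dominate the SP/IM totals, so that
        # per-sample fraction-of-total shares of membrane proteins stay
        # DRM/DSF-topped (the share comparison is compositional)
        baselines[i] *= 10.0
        top_w = 0.7 + 0.2 * rng.random()
        rest = rng.dirichlet([1.0, 1.0, 1.0]) * (1.0 - top_w)
        w = np.empty(4)
        fractions = list(config.fractions)
        others = [f for f in fractions if f != top]
        w[fractions.index(top)] = top_w
        for j, f in enumerate(others):
            w[fractions.index(f)] = rest[j]
        weights[i] = w

    n_shift = int(round(config.frac_shifted * n))
    shift_idx = rng.choice(n, size=n_shift, replace=False) if n_shift else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_shift)
    shifts = {ids[i]: float(s * config.shift_log2) for i, s in zip(shift_idx, signs)}

    lo, hi = config.peptides_per_protein
    pep_counts = rng.integers(lo, hi + 1, size=n)
    return _ProteinStructure(ids, baselines, weights, shifts, copurifying, pep_counts)


def _peptide_sequences(rng: np.random.Generator, n: int) -> list[str]:
    lengths = rng.integers(8, 16, size=n)
    return ["".join(rng.choice(AMINO_ACIDS, size=l)) + "K" for l in lengths]


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample design: genotype x fraction x replicate (x optional injection)."""
    rows = []
    for g in config.genotypes:
        for f in config.fractions:
            for r in range(1, config.n_replicates + 1):
                for k in range(1, config.n_injections + 1):
                    sid = f"{g}_{f}_r{r}"
                    if config.n_injections > 1:
                        sid += f"_inj{k}"
                    rows.append((sid, g, f, r, k))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "fraction", "replicate", "injection"])


def simulate_evidence(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a long-format peptide evidence table plus design and truth.

    Intensity of peptide j of protein i in sample (g, f, r):

        baseline_i * weight_i[f] * 2**(shift_i * [g is mutant and f == DRM])
                   * efficiency_ij * lognormal_noise(cv)

    followed by intensity-dependent dropout. The planted shift moves only the
    mutant DRM intensity, so a shifted protein's mutant/wildtype DRM/DSF ratio
    equals ``2**shift_i`` exactly in the noiseless limit.
    """
    struct = _protein_structure(config)
    _, rng_pep, rng_noise, rng_drop = _rngs(config.seed, 4)

    design = make_design(config)
    n_samples = len(design)
    frac_idx = np.array([list(config.fractions).index(f) for f in design["fraction"]])
    is_mutant = (design["genotype"] != config.wildtype).to_numpy()
    is_drm = (design["fraction"] == "DRM").to_numpy()

    n_pep_total = int(struct.peptide_counts.sum())
    pep_protein = np.repeat(np.arange(config.n_proteins), struct.peptide_counts)
    sequences = _peptide_sequences(rng_pep, n_pep_total)
    efficiency = np.exp(rng_pep.normal(0.0, 0.5, size=n_pep_total))

    shift_log2 = np.zeros(config.n_proteins)
    for pid, s in struct.shifts.items():
        shift_log2[struct.protein_ids.index(pid)] = s

    base = struct.baselines[pep_protein, None] * efficiency[:, None]   # (n_pep, 1)
    w = struct.weights[pep_protein][:, frac_idx]                       # (n_pep, n_samples)
    shift_factor = np.where(
        is_mutant & is_drm,
        2.0 ** shift_log2[pep_protein][:, None],
        1.0,
    )
    intensity = base * w * shift_factor
    intensity = intensity * _noise_factors(rng_noise, config.noise_cv, intensity.shape)

    p_drop = config.missing.dropout_probability(intensity)
    keep = rng_drop.random(intensity.shape) >= p_drop

    pep_ids = np.repeat(np.array(sequences, dtype=object), n_samples)
    prot_ids = np.repeat(np.array([struct.protein_ids[i] for i in pep_protein], dtype=object), n_samples)
    sample_ids = np.tile(design["sample_id"].to_numpy(dtype=object), n_pep_total)
    flat_keep = keep.ravel()

    evidence = pd.DataFrame(
        {
            "peptide_id": pep_ids[flat_keep],
            "protein_id": prot_ids[flat_keep],
            "sample_id": sample_ids[flat_keep],
            "intensity": intensity.ravel()[flat_keep],
        }
    )
    truth = GroundTruth(
        shifted_proteins=dict(struct.shifts),
        copurifying_proteins=dict(struct.copurifying),
    )
    return evidence, design, truth


# ---------------------------------------------------------------------------
# lipids
# ---------------------------------------------------------------------------

_CLASS_CARBON_RANGE = {
    "Cer": (34, 44), "GlcCer": (34, 44), "DAG": (32, 38), "TAG": (48, 58),
}


def _species_metadata(rng: np.random.Generator, cls: str, n: int) -> list[dict]:
    lo, hi = _CLASS_CARBON_RANGE.get(cls, (32, 42))
    grid = [(c, d) for c in range(lo, hi + 1, 2) for d in range(0, 7)]
    picks = rng.choice(len(grid), size=min(n, len(grid)), replace=False)
    out = []
    for k in picks:
        c, d = grid[k]
        meta = {"class": cls, "acyl_carbons": c, "double_bonds": d,
                "lipid_id": f"{cls}({c}:{d})"}
        if cls in ("Cer", "GlcCer"):
            h = int(rng.integers(0, 3))
            meta["hydroxylation"] = h
            meta["lipid_id"] = f"{cls}(d{c}:{d}-{h}OH)"
        out.append(meta)
    return out


def simulate_lipids(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate positive- and negative-mode lipid tables with planted FCs.

    Species sets of the two modes overlap (a ``mode_overlap`` proportion of
    species appears in both modes with a mode-specific gain) but are not
    identical. Planted log2 fold changes multiply mutant intensities. If
    ``coupled_class`` is set, one species of that class carries
    ``coupled_fc_log2`` and is coupled to every planted-shift protein
    (``true_edges``).
    """
    rng = _rngs(config.seed, 6)[4]
    counts = config.lipid_counts()
    species: list[dict] = []
    for cls in config.lipid_classes:
        species.extend(_species_metadata(rng, cls, counts[cls]))
    if not species:
        raise ConfigError("no lipid species configured")
    n_spec = len(species)
    ids = [s["lipid_id"] for s in species]

    n_rep = config.n_lipid_replicates or config.n_replicates
    samples = [f"{g}_r{r}" for g in config.genotypes for r in range(1, n_rep + 1)]
    is_mutant = np.array([not s.startswith(config.wildtype + "_") for s in samples])

    baselines = np.exp(rng.normal(np.log(1e6), 1.0, size=n_spec))
    n_diff = int(round(config.frac_lipids_differential * n_spec))
    diff_idx = rng.choice(n_spec, size=n_diff, replace=False) if n_diff else np.array([], dtype=int)
    fc = np.zeros(n_spec)
    fc[diff_idx] = rng.choice([-1.0, 1.0], size=n_diff) * config.lipid_fc_log2

    truth = GroundTruth()
    coupled_id = None
    if config.coupled_class is not None:
        cls_idx = [i for i, s in enumerate(species) if s["class"] == config.coupled_class]
        if not cls_idx:
            raise ConfigError(f"no species generated for coupled_class {config.coupled_class!r}")
        ci = cls_idx[0]
        fc[ci] = config.coupled_fc_log2
        coupled_id = ids[ci]
        shifted = _protein_structure(config).shifts
        truth.shifted_proteins = dict(shifted)
        truth.true_edges = sorted((pid, coupled_id) for pid in shifted)
    truth.differential_lipids = {ids[i]: float(fc[i]) for i in range(n_spec) if fc[i] != 0.0}

    intensity = baselines[:, None] * np.where(is_mutant[None, :], 2.0 ** fc[:, None], 1.0)
    intensity = intensity * _noise_factors(rng, config.lipid_noise_cv, intensity.shape)

    primary_pos = np.array([s["class"] in _POSITIVE_MODE_CLASSES for s in species])
    both = rng.random(n_spec) < config.mode_overlap
    secondary_gain = np.exp(rng.normal(-0.7, 0.3, size=n_spec))

    def _table(mode: str) -> pd.DataFrame:
        in_pos = mode == "positive"
        sel = primary_pos == in_pos
        sel = sel | both
        rows = []
        for i in np.flatnonzero(sel):
            gain = 1.0 if (primary_pos[i] == in_pos) else secondary_gain[i]
            row = {
                "lipid_id": ids[i],
                "class": species[i]["class"],
                "acyl_carbons": species[i]["acyl_carbons"],
                "double_bonds": species[i]["double_bonds"],
                "hydroxylation": species[i].get("hydroxylation", np.nan),
                "mode": mode,
            }
            row.update({s: intensity[i, j] * gain for j, s in enumerate(samples)})
            rows.append(row)
        return pd.DataFrame(rows)

    return _table("positive"), _table("negative"), truth


def lipid_design(config: SimulationConfig) -> pd.DataFrame:
    n_rep = config.n_lipid_replicates or config.n_replicates
    rows = [(f"{g}_r{r}", g, r) for g in config.genotypes for r in range(1, n_rep + 1)]
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate"])


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    library: pd.DataFrame,
    drift: Callable[[np.ndarray], np.ndarray] | None = None,
    *,
    ppm_jitter: float = 0.0,
    n_decoys: int = 0,
    decoy_ppm_offset: float = 20.0,
    marker_stride: int = 3,
    n_samples: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a lipid library into an observed peak table plus a marker table.

    Peaks are the library entries with m/z jitter uniform in
    ``[-ppm_jitter, +ppm_jitter]`` ppm and retention times pushed through the
    ``drift`` function, plus ``n_decoys`` decoy peaks offset by
    ``decoy_ppm_offset`` ppm. Markers are every ``marker_stride``-th library
    entry, reported with both the library and the observed retention time.
    """
    required = {"name", "mz", "rt"}
    if not required.issubset(library.columns):
        raise ConfigError(f"library must have columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    drift = drift if drift is not None else (lambda rt: rt)

    mz = library["mz"].to_numpy(dtype=float)
    rt = library["rt"].to_numpy(dtype=float)
    jitter = rng.uniform(-ppm_jitter, ppm_jitter, size=len(library)) * 1e-6
    obs_mz = mz * (1.0 + jitter)
    obs_rt = np.asarray(drift(rt), dtype=float)

    sample_cols = [f"s{j+1}" for j in range(n_samples)]
    peak_rows = []
    for i in range(len(library)):
        row = {"peak_id": f"peak{i:04d}", "mz": obs_mz[i], "rt": obs_rt[i]}
        row.update({c: float(np.exp(rng.normal(np.log(1e5), 0.5))) for c in sample_cols})
        peak_rows.append(row)
    for d in range(n_decoys):
        i = int(rng.integers(0, len(library)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        row = {
            "peak_id": f"decoy{d:04d}",
            "mz": mz[i] * (1.0 + sign * decoy_ppm_offset * 1e-6),
            "rt": float(obs_rt[i]),
        }
        row.update({c: float(np.exp(rng.normal(np.log(1e4), 0.5))) for c in sample_cols})
        peak_rows.append(row)
    peaks = pd.DataFrame(peak_rows)

    marker_idx = np.arange(0, len(library), marker_stride)
    markers = pd.DataFrame(
        {
            "name": library["name"].to_numpy()[marker_idx],
            "mz": mz[marker_idx],
            "library_rt": rt[marker_idx],
            "observed_rt": obs_rt[marker_idx],
        }
    )
    return peaks, markers


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    protein_ids: Iterable[str],
    *,
    seed: int = 0,
    mean_group_size: float = 2.0,
) -> pd.DataFrame:
    """Localization, protein-group and PTM-flag annotations for a protein set."""
    ids = list(protein_ids)
    rng = np.random.default_rng(seed)
    loc = rng.choice(LOCALIZATIONS, size=len(ids), p=_LOC_WEIGHTS)
    groups = []
    g = 0
    i = 0
    while i < len(ids):
        size = max(1, int(rng.poisson(mean_group_size - 1)) + 1)
        groups.extend([f"G{g:04d}"] * min(size, len(ids) - i))
        i += size
        g += 1
    flags = {
        "phospho": rng.random(len(ids)) < 0.3,
        "palmitoyl": rng.random(len(ids)) < 0.1,
        "myristoyl": rng.random(len(ids)) < 0.05,
        "gpi_anchor": rng.random(len(ids)) < 0.05,
    }
    return pd.DataFrame({"protein_id": ids, "localization": loc, "group": groups, **flags})
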