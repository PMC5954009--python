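"""Synthetic single-cell qPCR data generator.

Emulates the statistical structure of a multiplexed single-cell qPCR
experiment on sorted hematopoietic stem/progenitor populations:

* bimodal per-gene expression — each gene is *detected* in a cell with a
  population-specific probability ``pi``, and, when detected, its value is
  drawn from a normal with population-specific positive mean ``mu`` and sd
  ``sigma`` on the Et/dCt scale, truncated to stay strictly positive
  (draws <= 0 are rejected and redrawn, so 0 always means "not detected");
* cell-cycle phase structure — each cell is assigned G0/G1 or S/G2/M with
  population-specific probability; phase-matched signature genes receive an
  additive ``phase_effect`` on their positive mean (S/G2/M genes in S/G2/M
  cells, G1 genes in G0/G1 cells);
* batch structure — additive per-batch offsets on detected values;
* division-tracking dye — log2 intensity halves per division with normal
  measurement noise.

Randomness is hierarchical: one global seed spawns an independent stream
per (population, gene) keyed by name, so adding genes or populations never
perturbs the draws of existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CC_G1_GENES,
    CC_SG2M_GENES,
    SYNTHETIC_HSC_GENES,
    SYNTHETIC_MEP_PLATELET_GENES,
    ExpressionMatrix,
    GenePanel,
)

G0G1 = "G0G1"
SG2M = "SG2M"

#: Default per-(population, category) generative parameters (pi, mu, sigma)
#: on the Et scale.  Chosen so that, with the default phase effect of 3
#: (3 sigma), populations and phases separate the way the downstream
#: analyses assume: HSCs mostly lack MEP/platelet expression, restricted
#: progenitors express it strongly, and cell-cycle genes carry the phase
#: signal but no population signal.
DEFAULT_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "HSC": {
        "hsc": (0.90, 8.0, 1.0),
        "mep_platelet": (0.20, 3.0, 1.0),
        "cc_g1": (0.95, 4.0, 1.0),
        "cc_sg2m": (0.95, 4.0, 1.0),
    },
    "CMP": {
        "hsc": (0.50, 5.0, 1.0),
        "mep_platelet": (0.50, 5.0, 1.0),
        "cc_g1": (0.95, 4.0, 1.0),
        "cc_sg2m": (0.95, 4.0, 1.0),
    },
    "PreME": {
        "hsc": (0.30, 3.0, 1.0),
        "mep_platelet": (0.85, 8.0, 1.0),
        "cc_g1": (0.95, 4.0, 1.0),
        "cc_sg2m": (0.95, 4.0, 1.0),
    },
    "PreMeg": {
        "hsc": (0.20, 3.0, 1.0),
        "mep_platelet": (0.95, 10.0, 1.0),
        "cc_g1": (0.95, 4.0, 1.0),
        "cc_sg2m": (0.95, 4.0, 1.0),
    },
}

#: Default G0/G1 fraction per population: HSCs are largely quiescent
#: (~90% G0/G1), restricted progenitors are mostly cycling with about a
#: third still in G0/G1.
DEFAULT_PHASE_FRACTIONS: dict[str, dict[str, float]] = {
    "HSC": {G0G1: 0.90, SG2M: 0.10},
    "CMP": {G0G1: 0.50, SG2M: 0.50},
    "PreME": {G0G1: 0.33, SG2M: 0.67},
    "PreMeg": {G0G1: 0.33, SG2M: 0.67},
}


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Full generative specification for one synthetic cohort.

    ``pi``, ``mu`` and ``sigma`` are nested ``{population: {gene: value}}``
    maps; ``gene_categories`` tags each gene with its panel category.
    """

    populations: list[str]
    cells_per_population: list[int]
    gene_categories: dict[str, str]
    pi: dict[str, dict[str, float]]
    mu: dict[str, dict[str, float]]
    sigma: dict[str, dict[str, float]]
    phase_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    phase_effect: float = 3.0
    batch_offsets: dict[str, float] = field(default_factory=lambda: {"b1": 0.0})
    dye_sigma: float = 0.2
    lod_ct: float = 24.0
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.gene_categories)

    def panel(self) -> GenePanel:
        return GenePanel(dict(self.gene_categories))

    def validate(self) -> None:
        if len(self.populations) != len(self.cells_per_population):
            raise ConfigurationError(
                "populations and cells_per_population length mismatch"
            )
        for pop, n in zip(self.populations, self.cells_per_population):
            if n <= 0:
                raise ConfigurationError(f"cells_per_population[{pop}] must be > 0")
        for pop in self.populations:
            for gene in self.genes:
                p = self.pi[pop][gene]
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"pi[{pop}][{gene}] = {p} outside [0, 1]"
                    )
                s = self.sigma[pop][gene]
                if not s > 0:
                    raise ConfigurationError(
                        f"sigma[{pop}][{gene}] = {s} must be > 0"
                    )
                m = self.mu[pop][gene]
                if m < 0:
                    raise ConfigurationError(
                        f"mu[{pop}][{gene}] = {m} must be >= 0"
                    )
            fr = self.phase_fractions.get(pop, {G0G1: 1.0, SG2M: 0.0})
            if abs(fr.get(G0G1, 0.0) + fr.get(SG2M, 0.0) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"phase_fractions[{pop}] must sum to 1"
                )
        if not self.batch_offsets:
            raise ConfigurationError("at least one batch required")

    # ------------------------------------------------------------------
    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Default cohort: 42 HSC, 7 CMP, 15 PreME, 20 PreMeg cells on the
        packaged 35-gene panel."""
        panel = GenePanel.default()
        populations = ["HSC", "CMP", "PreME", "PreMeg"]
        cfg = cls(
            populations=populations,
            cells_per_population=[42, 7, 15, 20],
            gene_categories=dict(panel.categories),
            pi={}, mu={}, sigma={},
            phase_fractions={p: dict(DEFAULT_PHASE_FRACTIONS[p]) for p in populations},
            seed=seed,
        )
        for pop in populations:
            cfg.pi[pop], cfg.mu[pop], cfg.sigma[pop] = {}, {}, {}
            for gene, cat in cfg.gene_categories.items():
                p, m, s = DEFAULT_PARAMS[pop][cat]
                cfg.pi[pop][gene] = p
                cfg.mu[pop][gene] = m
                cfg.sigma[pop][gene] = s
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise ConfigurationError(f"unknown config field: {k}")
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    @classmethod
    def reference_hsc(cls, n_cells: int = 1000, seed: int = 0) -> "SyntheticConfig":
        """A pure reference-HSC cohort (control HSCs before transplantation)
        used to calibrate the cell-cycle threshold."""
        cfg = cls.default(seed=seed)
        cfg.populations = ["HSC"]
        cfg.cells_per_population = [n_cells]
        cfg.validate()
        return cfg

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "populations": self.populations,
            "cells_per_population": self.cells_per_population,
            "gene_categories": self.gene_categories,
            "pi": self.pi,
            "mu": self.mu,
            "sigma": self.sigma,
            "phase_fractions": self.phase_fractions,
            "phase_effect": self.phase_effect,
            "batch_offsets": self.batch_offsets,
            "dye_sigma": self.dye_sigma,
            "lod_ct": self.lod_ct,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from JSON or YAML."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ----------------------------------------------------------------------
def _stream(seed: int, *names: str) -> np.random.Generator:
    """Independent generator stream keyed by the global seed and a tuple of
    names (hashed with CRC32 so streams survive panel re-ordering)."""
    entropy = [int(seed)] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     size: int) -> np.ndarray:
    """Normal draws rejected-and-redrawn until strictly positive."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def generate_cells(
    config: SyntheticConfig, is_reference: bool = False
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw one cohort: expression matrix plus per-cell annotation.

    Cells are ordered by population (in config order) then index; batches
    are assigned round-robin over ``batch_offsets`` within each population.
    The annotation records the ground-truth population, phase and batch.

    Returns
    -------
    (ExpressionMatrix, annotation DataFrame indexed by cell id)
    """
    config.validate()
    genes = config.genes
    batches = list(config.batch_offsets)

    cell_ids: list[str] = []
    pops: list[str] = []
    phases: list[str] = []
    batch_of: list[str] = []
    for pop, n in zip(config.populations, config.cells_per_population):
        phase_rng = _stream(config.seed, pop, "__phase__")
        frac = config.phase_fractions.get(pop, {G0G1: 1.0, SG2M: 0.0})
        draws = phase_rng.random(n)
        for i in range(n):
            cell_ids.append(f"{pop}_{i:04d}")
            pops.append(pop)
            phases.append(G0G1 if draws[i] < frac.get(G0G1, 1.0) else SG2M)
            batch_of.append(batches[i % len(batches)])

    n_cells = len(cell_ids)
    values = np.zeros((n_cells, len(genes)))
    cell_row = {c: r for r, c in enumerate(cell_ids)}

    for pop, n in zip(config.populations, config.cells_per_population):
        rows = [cell_row[f"{pop}_{i:04d}"] for i in range(n)]
        for j, gene in enumerate(genes):
            rng = _stream(config.seed, pop, gene)
            det = rng.random(n) < config.pi[pop][gene]
            cat = config.gene_categories[gene]
            for local_i, r in enumerate(rows):
                if not det[local_i]:
                    continue
                mean = config.mu[pop][gene]
                phase = phases[r]
                if (cat == "cc_sg2m" and phase == SG2M) or (
                    cat == "cc_g1" and phase == G0G1
                ):
                    mean += config.phase_effect
                mean += config.batch_offsets[batch_of[r]]
                values[r, j] = _positive_normal(
                    rng, mean, config.sigma[pop][gene], 1
                )[0]

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=cell_ids, columns=genes)
    )
    annotation = pd.DataFrame(
        {
            "population": pops,
            "batch": batch_of,
            "is_reference": is_reference,
            "true_phase": phases,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return matrix, annotation


def generate_dye_intensities(
    generations: Sequence[int] | np.ndarray,
    base_log2: float,
    dye_sigma: float,
    seed: int,
) -> np.ndarray:
    """Division-tracking dye intensities under the halving model.

    ``log2(intensity) = base_log2 - generation + N(0, dye_sigma)``;
    generation 0 is an undivided (reference-scale) cell.  Returns linear
    intensities.
    """
    gen = np.asarray(generations, dtype=float)
    if (gen < 0).any():
        raise ValueError("generations must be >= 0")
    rng = _stream(seed, "__dye__")
    noise = rng.normal(0.0, dye_sigma, gen.shape) if dye_sigma > 0 else 0.0
    return np.power(2.0, base_log2 - gen + noise)
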