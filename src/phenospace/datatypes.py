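"""Core data containers for cross-species wild/domestic phenotype studies.

A *study* bundles, per species, a tidy phenotype table (individuals x traits,
keyed by accession, form and replicate), near-infrared spectra per organ, and
species-level metadata (domestication timing, mating system, life cycle).
These containers are deliberately thin wrappers around pandas/numpy objects:
all analysis code receives and returns them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

KEY_COLUMNS = ("species_id", "accession_id", "form")

WILD = "wild"
DOMESTIC = "domestic"
FORMS = (WILD, DOMESTIC)


class TraitType(str, Enum):
    CONTINUOUS = "continuous"
    DISCRETE = "discrete"
    QUALITATIVE = "qualitative"

    @property
    def is_quantitative(self) -> bool:
        return self in (TraitType.CONTINUOUS, TraitType.DISCRETE)


@dataclass(frozen=True)
class TraitMeta:
    """Declaration of a single trait column.

    ``shared_id`` carries the cross-species ontology identity: two species
    whose trait declarations share a ``shared_id`` measure a homologous
    trait. Seed-NIRS ordination axes are flagged ``is_seed_nirs`` because
    those axes are not homologous across species and are excluded from the
    convergence analysis; leaf-NIRS-derived control traits are flagged
    ``is_control`` and are excluded from the "all other traits" space.
    """

    trait_name: str
    trait_type: TraitType
    shared_id: Optional[str] = None
    is_control: bool = False
    is_seed_nirs: bool = False

    def __post_init__(self):
        if not isinstance(self.trait_type, TraitType):
            object.__setattr__(self, "trait_type", TraitType(self.trait_type))


@dataclass
class TraitTable:
    """Tidy individuals-by-traits records for one species.

    ``data`` holds one row per phenotyped individual (= accession x replicate
    when the design has replicates) with the key columns ``species_id``,
    ``accession_id``, ``form`` and optionally ``replicate_id``, plus one
    column per declared trait.
    """

    data: pd.DataFrame
    traits: list[TraitMeta]

    def __post_init__(self):
        for col in KEY_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"TraitTable requires key column '{col}'")
        for tm in self.traits:
            if tm.trait_name not in self.data.columns:
                raise ValueError(f"declared trait '{tm.trait_name}' absent from table")
        bad = set(self.data["form"]) - set(FORMS)
        if bad:
            raise ValueError(f"unknown form labels: {sorted(bad)}")
        for form in FORMS:
            if (self.data["form"] == form).sum() == 0:
                continue  # validate_study reports missing forms; not fatal here
        # coerce declared types
        df = self.data
        for tm in self.traits:
            if tm.trait_type.is_quantitative:
                df[tm.trait_name] = pd.to_numeric(df[tm.trait_name], errors="coerce")
            else:
                df[tm.trait_name] = df[tm.trait_name].astype("string").str.strip().astype("category")

    @property
    def species_id(self) -> str:
        return str(self.data["species_id"].iloc[0])

    @property
    def has_replicates(self) -> bool:
        return "replicate_id" in self.data.columns and self.data["replicate_id"].nunique() > 1

    def trait_meta(self, name: str) -> TraitMeta:
        for tm in self.traits:
            if tm.trait_name == name:
                return tm
        raise KeyError(name)

    @property
    def quantitative_traits(self) -> list[str]:
        return [t.trait_name for t in self.traits if t.trait_type.is_quantitative]

    @property
    def qualitative_traits(self) -> list[str]:
        return [t.trait_name for t in self.traits if not t.trait_type.is_quantitative]

    def subset_traits(self, names: Sequence[str]) -> "TraitTable":
        keep = [t for t in self.traits if t.trait_name in set(names)]
        cols = [c for c in self.data.columns if c in KEY_COLUMNS or c == "replicate_id"]
        cols += [t.trait_name for t in keep]
        return TraitTable(self.data[cols].copy(), keep)

    def individual_ids(self) -> pd.Series:
        """Stable per-row individual identifier (accession x replicate)."""
        if "replicate_id" in self.data.columns:
            return self.data["accession_id"].astype(str) + "_" + self.data["replicate_id"].astype(str)
        return self.data["accession_id"].astype(str)


@dataclass
class SpectraSet:
    """Wavelength-gridded spectra, one row per technical replicate.

    ``values`` is indexed by (individual_id, replicate_id); columns are the
    wavelength grid in nm, strictly increasing and shared by every spectrum.
    """

    values: pd.DataFrame  # MultiIndex (individual_id, replicate_id) x wavelengths
    organ: str  # "leaf" | "seed"

    def __post_init__(self):
        if self.organ not in ("leaf", "seed"):
            raise ValueError(f"organ must be 'leaf' or 'seed', got {self.organ!r}")
        grid = self.wavelengths
        if len(grid) == 0:
            raise ValueError("empty wavelength grid")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.values.isna().any().any():
            raise ValueError("missing values inside retained spectra")
        if self.values.index.nlevels != 2:
            raise ValueError("values must be indexed by (individual_id, replicate_id)")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    def spectra_of(self, individual_id: str) -> pd.DataFrame:
        return self.values.loc[individual_id]

    def with_values(self, values: pd.DataFrame) -> "SpectraSet":
        return SpectraSet(values=values, organ=self.organ)


@dataclass(frozen=True)
class SpeciesMeta:
    species_id: str
    timing_generations: float
    mating_system: str  # "selfer" | "outcrosser"
    life_cycle: str = "annual"  # "annual" | "biennial" | "perennial"
    diversity_ratio: Optional[float] = None  # domestic/wild genomic diversity
    family: Optional[str] = None

    def __post_init__(self):
        if self.timing_generations <= 0:
            raise ValueError("timing_generations must be > 0")
        if self.mating_system not in ("selfer", "outcrosser"):
            raise ValueError(f"unknown mating system {self.mating_system!r}")
        if self.life_cycle not in ("annual", "biennial", "perennial"):
            raise ValueError(f"unknown life cycle {self.life_cycle!r}")
        if self.diversity_ratio is not None and self.diversity_ratio <= 0:
            raise ValueError("diversity_ratio must be > 0 when present")


@dataclass(frozen=True)
class StudyConfig:
    """Study-wide analysis settings.

    Defaults follow the study design this pipeline implements: BH-FDR at 5%,
    10 000 resampling iterations for the convergence null, 10 000 random
    skewers, and a Savitzky-Golay filter with window 37 and order 2 for
    spectra derivatives.
    """

    fdr_level: float = 0.05
    resample_iterations: int = 10_000
    skewer_vectors: int = 10_000
    rank_tolerance: float = 1e-8
    rng_seed: int = 0
    sg_window: int = 37
    sg_order: int = 2

    def __post_init__(self):
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0,1)")
        if self.resample_iterations <= 0 or self.skewer_vectors <= 0:
            raise ValueError("iteration counts must be positive")
        if self.rank_tolerance <= 0:
            raise ValueError("rank_tolerance must be positive")
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and exceed sg_order")

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, rng_seed=int(seed))


@dataclass
class StudyBundle:
    """One multi-species study: everything the end-to-end analysis consumes."""

    trait_tables: dict[str, TraitTable] = field(default_factory=dict)
    spectra: dict[tuple[str, str], SpectraSet] = field(default_factory=dict)  # (species, organ)
    species_meta: list[SpeciesMeta] = field(default_factory=list)

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.trait_tables)

    def meta_of(self, species_id: str) -> SpeciesMeta:
        for m in self.species_meta:
            if m.species_id == species_id:
                return m
        raise KeyError(species_id)
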