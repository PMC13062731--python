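"""Reading, writing and validating study files.

All tabular I/O is UTF-8 CSV/TSV with a header row. Phenotype tables are
wide (one column per trait); spectra are one matrix per organ with
``individual_id``, ``replicate_id`` as the first two columns and one column
per wavelength.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FORMS,
    KEY_COLUMNS,
    SpeciesMeta,
    SpectraSet,
    StudyConfig,
    TraitMeta,
    TraitTable,
    TraitType,
)

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "N/A", "na"}


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_trait_table(path, meta: Sequence[TraitMeta]) -> TraitTable:
    """Read a wide phenotype table and type its trait columns.

    Unparseable quantitative cells (e.g. "NA") become missing values and the
    row is retained; a missing key column or a declared-but-absent trait is
    fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required key column '{col}'")
    for tm in meta:
        if tm.trait_name not in df.columns:
            raise ValueError(f"{path.name}: declared trait '{tm.trait_name}' not found")
    df = df.replace(sorted(_MISSING_TOKENS), np.nan)
    return TraitTable(df, list(meta))


def write_trait_table(table: TraitTable, path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path), index=False)


def read_spectra(path, organ: str) -> SpectraSet:
    """Read one spectra matrix; wavelength header must be strictly increasing."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("individual_id", "replicate_id"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column '{col}'")
    wl_cols = [c for c in df.columns if c not in ("individual_id", "replicate_id")]
    try:
        grid = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"{path.name}: non-numeric wavelength column header") from exc
    if not np.all(np.diff(grid) > 0):
        raise ValueError(f"{path.name}: wavelength columns are not strictly increasing")
    values = df.set_index(["individual_id", "replicate_id"])[wl_cols].astype(float)
    values.columns = grid
    return SpectraSet(values=values, organ=organ)


def write_spectra(spectra: SpectraSet, path) -> None:
    path = Path(path)
    out = spectra.values.copy()
    out.columns = [repr(float(c)) for c in out.columns]
    out.reset_index().to_csv(path, sep=_sep_for(path), index=False)


def read_species_meta(path) -> list[SpeciesMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SpeciesMeta(
                species_id=str(row["species_id"]),
                timing_generations=float(row["timing_generations"]),
                mating_system=str(row["mating_system"]),
                life_cycle=str(row.get("life_cycle", "annual")),
                diversity_ratio=(float(row["diversity_ratio"])
                                 if "diversity_ratio" in row and pd.notna(row["diversity_ratio"])
                                 else None),
                family=(str(row["family"]) if "family" in row and pd.notna(row["family"]) else None),
            )
        )
    return metas


def read_trait_meta(path) -> list[TraitMeta]:
    """Read a trait ontology table (trait_name, trait_type, shared_id, flags)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    metas = []
    for _, row in df.iterrows():
        metas.append(
            TraitMeta(
                trait_name=str(row["trait_name"]),
                trait_type=TraitType(str(row["trait_type"])),
                shared_id=(str(row["shared_id"])
                           if "shared_id" in row and pd.notna(row["shared_id"]) else None),
                is_control=bool(row.get("is_control", False)),
                is_seed_nirs=bool(row.get("is_seed_nirs", False)),
            )
        )
    return metas


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(StudyConfig)}
    return StudyConfig(**{k: v for k, v in raw.items() if k in fields})


def validate_study(tables: dict[str, TraitTable],
                   meta: Sequence[SpeciesMeta] | None = None) -> list[dict]:
    """Report structural issues without mutating anything.

    Returned issues are dicts with keys ``species``, ``issue`` and optionally
    ``trait``. An empty list means the study is analysable as-is.
    """
    issues: list[dict] = []
    known = {m.species_id for m in meta} if meta else None
    for sp, table in tables.items():
        df = table.data
        if known is not None and sp not in known:
            issues.append({"species": sp, "issue": "no species metadata"})
        for form in FORMS:
            if (df["form"] == form).sum() == 0:
                issues.append({"species": sp, "issue": f"missing form: {form}"})
        for tm in table.traits:
            col = df[tm.trait_name].dropna()
            if col.empty:
                issues.append({"species": sp, "trait": tm.trait_name, "issue": "no observations"})
            elif col.nunique() < 2:
                issues.append({"species": sp, "trait": tm.trait_name, "issue": "constant trait"})
        if "replicate_id" in df.columns:
            counts = df.groupby("accession_id", observed=True)["replicate_id"].nunique()
            if counts.nunique() > 1:
                issues.append({"species": sp, "issue": "replicate imbalance"})
    return issues
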