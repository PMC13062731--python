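"""Design-preserving resampling test for cross-species trait convergence.

The observed quantity is the number of shared-trait identities that are
domestication-associated (DA) in exactly one species, exactly two, or three
or more. The null preserves the measured design — how many traits each
species measured and which of them are shared — by drawing, in each
iteration, n species-trait slots uniformly without replacement from the t
measured slots and re-counting the sharing classes. Seed-NIRS ordination
axes are excluded upstream (their axes are not homologous across species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import TraitTable
from .syndrome import DATraitCall

CLASSES = ("unique", "two", "three_plus")


@dataclass
class ConvergenceDesign:
    """Species x shared-trait incidence and DA flags.

    Rows = species, columns = trait identities (shared_id where declared,
    otherwise a species-private identity). DA flags imply incidence.
    """

    incidence: pd.DataFrame
    da_flags: pd.DataFrame

    def __post_init__(self):
        if not self.incidence.index.equals(self.da_flags.index) or \
           not self.incidence.columns.equals(self.da_flags.columns):
            raise ValueError("incidence and da_flags must be aligned")
        if (self.da_flags.to_numpy() & ~self.incidence.to_numpy()).any():
            raise ValueError("da_flags set where trait is not measured")

    @property
    def t(self) -> int:
        return int(self.incidence.to_numpy().sum())

    @property
    def n(self) -> int:
        return int(self.da_flags.to_numpy().sum())

    def subset_species(self, species: Sequence[str]) -> "ConvergenceDesign":
        inc = self.incidence.loc[list(species)]
        da = self.da_flags.loc[list(species)]
        keep = inc.any(axis=0)
        return ConvergenceDesign(inc.loc[:, keep], da.loc[:, keep])


@dataclass
class ConvergenceResult:
    observed: dict
    null_counts: pd.DataFrame          # iterations x classes
    p_enrichment: dict
    p_deficit: dict
    p_enrichment_raw: dict
    p_deficit_raw: dict
    iterations: int
    seed: int
    t: int = 0
    n: int = 0
    label: str = ""


def design_from_calls(calls_by_species: Mapping[str, Sequence[DATraitCall]],
                      tables: Mapping[str, TraitTable]) -> ConvergenceDesign:
    """Build the incidence/DA design from per-species DA calls.

    Trait identity = shared_id when declared, else '<species>::<trait>'.
    Seed-NIRS axis traits are excluded.
    """
    species = sorted(tables)
    inc_cells, da_cells = {}, {}
    for sp in species:
        table = tables[sp]
        da_names = {c.trait_name for c in calls_by_species.get(sp, []) if c.is_da}
        for tm in table.traits:
            if tm.is_seed_nirs or tm.is_control:
                continue
            ident = tm.shared_id if tm.shared_id else f"{sp}::{tm.trait_name}"
            inc_cells[(sp, ident)] = True
            if tm.trait_name in da_names:
                da_cells[(sp, ident)] = True
    idents = sorted({k[1] for k in inc_cells})
    inc = pd.DataFrame(False, index=species, columns=idents)
    da = pd.DataFrame(False, index=species, columns=idents)
    for (sp, ident) in inc_cells:
        inc.loc[sp, ident] = True
    for (sp, ident) in da_cells:
        da.loc[sp, ident] = True
    return ConvergenceDesign(inc, da)


def count_sharing(design: ConvergenceDesign) -> dict:
    """Counts of trait identities DA in exactly 1, exactly 2, and >= 3 species."""
    m = design.da_flags.to_numpy().sum(axis=0)
    return {"unique": int((m == 1).sum()), "two": int((m == 2).sum()),
            "three_plus": int((m >= 3).sum())}


def resample_null(design: ConvergenceDesign, iterations: int,
                  seed: int) -> pd.DataFrame:
    """Null class counts from drawing n of the t measured slots per iteration."""
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    t, n = design.t, design.n
    if not 0 < n <= t:
        raise ValueError(f"need 0 < n <= t, got n={n}, t={t}")
    rng = np.random.default_rng(seed)
    # canonical slot order: invariant to how species/trait rows were supplied
    inc_df = design.incidence.sort_index(axis=0).sort_index(axis=1)
    inc = inc_df.to_numpy()
    slot_species, slot_ident = np.nonzero(inc)
    K = inc.shape[1]
    # membership matrix: slot -> identity
    M = np.zeros((t, K))
    M[np.arange(t), slot_ident] = 1.0
    if n == t:
        draws = np.ones((iterations, t), dtype=bool)
    else:
        u = rng.random((iterations, t))
        idx = np.argpartition(u, n - 1, axis=1)[:, :n]
        draws = np.zeros((iterations, t), dtype=bool)
        np.put_along_axis(draws, idx, True, axis=1)
    counts = draws.astype(float) @ M  # iterations x identities: DA multiplicity
    out = pd.DataFrame({
        "unique": (counts == 1).sum(axis=1).astype(int),
        "two": (counts == 2).sum(axis=1).astype(int),
        "three_plus": (counts >= 3).sum(axis=1).astype(int),
    })
    return out


def convergence_pvalue(observed: Mapping[str, int], null_counts: pd.DataFrame):
    """Empirical tail p-values per class, with and without add-one smoothing."""
    if len(null_counts) == 0:
        raise ValueError("empty null distribution")
    iters = len(null_counts)
    p_enr, p_def, p_enr_raw, p_def_raw = {}, {}, {}, {}
    for cls in CLASSES:
        null = null_counts[cls].to_numpy()
        ge = int((null >= observed[cls]).sum())
        le = int((null <= observed[cls]).sum())
        p_enr[cls] = (1 + ge) / (1 + iters)
        p_def[cls] = (1 + le) / (1 + iters)
        p_enr_raw[cls] = ge / iters
        p_def_raw[cls] = le / iters
    return p_enr, p_def, p_enr_raw, p_def_raw


def convergence_test(design: ConvergenceDesign, iterations: int = 10_000,
                     seed: int = 0, label: str = "") -> ConvergenceResult:
    observed = count_sharing(design)
    null = resample_null(design, iterations, seed)
    p_enr, p_def, p_enr_raw, p_def_raw = convergence_pvalue(observed, null)
    return ConvergenceResult(
        observed=observed, null_counts=null,
        p_enrichment=p_enr, p_deficit=p_def,
        p_enrichment_raw=p_enr_raw, p_deficit_raw=p_def_raw,
        iterations=iterations, seed=seed, t=design.t, n=design.n, label=label,
    )


def poaceae_sensitivity(design: ConvergenceDesign,
                        family_labels: Mapping[str, str], family: str,
                        iterations: int = 10_000, seed: int = 0) -> list[ConvergenceResult]:
    """Re-run the test keeping one member of the named family at a time."""
    members = [sp for sp in design.incidence.index if family_labels.get(sp) == family]
    if not members:
        raise ValueError(f"no species in family {family!r}")
    results = []
    for keep in members:
        retained = [sp for sp in design.incidence.index
                    if family_labels.get(sp) != family or sp == keep]
        sub = design.subset_species(retained)
        results.append(convergence_test(sub, iterations, seed, label=f"keep:{keep}"))
    return results
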