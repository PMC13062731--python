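"""Synthetic multi-species wild/domestic phenotype studies.

The generator emulates the statistical structure the downstream analysis
assumes: quantitative traits follow the randomized-block mixed model

    X_ijk = mu + B_i + F_j + A_k + (AxF)_jk + eps_ijk

with B_i a block (replicate) effect shared across accessions, F_j the fixed
wild/domestic contrast (delta, expressed in residual-SD units), A_k an
accession-level random intercept with variance sigma2_accession, (AxF)_jk a
form-specific accession variance, and eps the residual. Qualitative traits
are drawn once per accession from form-specific multinomials and repeated
across replicates (accession-level genetic determination). NIRS-like spectra
are smooth sums of Gaussian bumps per individual, with per-technical-replicate
additive drift, multiplicative gain and white noise; seed spectra optionally
carry a form-dependent spectral signature while leaf spectra never do — the
premise behind using leaf spectra as a domestication-neutral control.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DOMESTIC,
    WILD,
    SpeciesMeta,
    SpectraSet,
    StudyBundle,
    TraitMeta,
    TraitTable,
    TraitType,
)


@dataclass
class SimParams:
    """Study-design parameters for the generator.

    Defaults mirror the study design this pipeline targets: 18 wild and 19
    domestic accessions phenotyped in 3 randomized replicates, with
    domestication effect sizes delta drawn in [0.5, 3] residual SD for
    domestication-associated traits. Leaf spectra span 2150 wavelengths with
    3 technical replicates; seed spectra 1300 wavelengths with 4 technical
    replicates.
    """

    n_species: int = 13
    n_wild_accessions: int = 18
    n_dom_accessions: int = 19
    n_replicates: int = 3
    n_quant_traits: int = 20
    n_qual_traits: int = 6
    mu: float = 0.0
    block_effect_sd: float = 0.5
    var_accession: float = 1.0
    # domestication bottleneck: domesticates keep less accession-level variance
    var_form_accession: dict = field(default_factory=lambda: {WILD: 0.75, DOMESTIC: 0.25})
    var_residual: float = 1.0
    da_fraction: float = 0.5
    # convergence: a subset of shared identities is domestication-prone in
    # every species measuring it (repeated targeting of homologous traits)
    convergent_fraction: float = 0.35
    convergent_da_prob: float = 0.9
    form_effect_range: tuple = (0.5, 3.0)
    qual_levels: int = 3
    qual_base_probs: tuple = (0.6, 0.3, 0.1)
    qual_da_probs: tuple = (0.1, 0.3, 0.6)
    # cross-species sharing
    n_shared_traits: int = 40
    trait_sharing_design: Optional[pd.DataFrame] = None  # species x shared_id booleans
    da_assignment: Optional[dict] = None  # species_id -> set of trait names with delta != 0
    # spectra
    n_leaf_wavelengths: int = 2150
    n_seed_wavelengths: int = 1300
    leaf_tech_reps: int = 3
    seed_tech_reps: int = 4
    drift_sd: float = 0.02
    multiplicative_sd: float = 0.05
    spectra_noise_sd: float = 0.005
    seed_form_shift: float = 0.3
    n_outlier_replicates: int = 0
    outlier_offset: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("var_accession", "var_residual", "block_effect_sd",
                     "drift_sd", "multiplicative_sd", "spectra_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.var_residual < 0:
            raise ValueError("var_residual must be >= 0")
        for form, v in self.var_form_accession.items():
            if v < 0:
                raise ValueError(f"var_form_accession[{form}] must be >= 0")
        for probs in (self.qual_base_probs, self.qual_da_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("qualitative level probabilities must sum to 1")


def species_rng(params: SimParams, species_id: str, salt: str = "") -> np.random.Generator:
    """Per-species substream: invariant to the order species are simulated in."""
    key = zlib.crc32(f"{species_id}|{salt}".encode())
    return np.random.default_rng([params.rng_seed & 0x7FFFFFFF, key])


def _species_ids(params: SimParams) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(params.n_species)]


def default_sharing_design(params: SimParams) -> pd.DataFrame:
    """Species x shared-trait incidence emulating uneven cross-species sharing.

    Most shared identities are measured by few species and a handful by many
    (the number of measurable homologous traits falls off with taxonomic
    distance); each species devotes at most half its quantitative-trait
    budget to shared identities, the rest being species-specific.
    """
    rng = np.random.default_rng([params.rng_seed & 0x7FFFFFFF, zlib.crc32(b"sharing")])
    species = _species_ids(params)
    shared_ids = [f"ST{i + 1:02d}" for i in range(params.n_shared_traits)]
    inc = pd.DataFrame(False, index=species, columns=shared_ids)
    if params.n_species < 2:
        return inc.iloc[:, :0]
    max_shareable = max(2, params.n_quant_traits // 2)
    for sid in shared_ids:
        # skewed breadth: mostly 2-4 species, occasionally most of them
        k = 2 + int(rng.geometric(0.35)) - 1
        k = min(k, params.n_species)
        order = rng.permutation(species)
        placed = 0
        for sp in order:
            if placed >= k:
                break
            if inc.loc[sp].sum() < max_shareable:
                inc.loc[sp, sid] = True
                placed += 1
        if inc[sid].sum() < 2:  # a "shared" trait needs >= 2 measuring species
            inc[sid] = False
    return inc


def _trait_plan(params: SimParams, species_id: str):
    """Per-species trait list: (name, type, shared_id, delta)."""
    inc = params.trait_sharing_design
    if inc is None:
        inc = default_sharing_design(params)
    if species_id not in inc.index:
        raise ValueError(f"species {species_id!r} absent from trait_sharing_design")
    shared = [c for c in inc.columns if inc.loc[species_id, c]]
    n_specific = params.n_quant_traits - len(shared)
    if n_specific < 0:
        raise ValueError("n_quant_traits smaller than shared-trait count")
    quant_names = shared + [f"{species_id}_q{i + 1:02d}" for i in range(n_specific)]
    qual_names = [f"{species_id}_c{i + 1:02d}" for i in range(params.n_qual_traits)]

    # the most broadly measured shared identities are the convergence-prone
    # ones (widely measurable homologous traits — organ size, height — are
    # also the repeated targets of selection under cultivation)
    n_conv = int(round(params.convergent_fraction * inc.shape[1]))
    breadth = inc.sum(axis=0)
    convergent_set = set(breadth.sort_values(ascending=False, kind="stable")
                         .index[:n_conv])
    if params.da_assignment is not None:
        da = set(params.da_assignment.get(species_id, set()))
        unknown = da - set(quant_names) - set(qual_names)
        if unknown:
            raise ValueError(f"da_assignment references unmeasured traits: {sorted(unknown)}")
    else:
        # convergence-prone traits are DA nearly everywhere they are measured;
        # everything else is species-independent at da_fraction
        rng = species_rng(params, species_id, "da")
        da = set()
        for n in quant_names + qual_names:
            p_da = (params.convergent_da_prob if n in convergent_set
                    else params.da_fraction)
            if rng.random() < p_da:
                da.add(n)

    rng_eff = species_rng(params, species_id, "effects")
    lo, hi = params.form_effect_range
    mid = 0.5 * (lo + hi)
    plan = []
    for name in quant_names:
        if name in da:
            # convergence-prone traits carry strong, repeatable effects
            # (organ-size gigantism); others span the full range
            delta = float(rng_eff.uniform(mid, hi) if name in convergent_set
                          else rng_eff.uniform(lo, hi))
        else:
            delta = 0.0
        plan.append((name, TraitType.CONTINUOUS, name if name in shared else None, delta))
    for name in qual_names:
        delta = 1.0 if name in da else 0.0  # flag: shifted level probabilities
        plan.append((name, TraitType.QUALITATIVE, None, delta))
    return plan


def simulate_species_traits(params: SimParams, species_id: str) -> TraitTable:
    """Draw one species' phenotype table under the block mixed model."""
    plan = _trait_plan(params, species_id)
    rng = species_rng(params, species_id, "traits")

    accs = ([f"W{i + 1:02d}" for i in range(params.n_wild_accessions)]
            + [f"D{i + 1:02d}" for i in range(params.n_dom_accessions)])
    forms = [WILD] * params.n_wild_accessions + [DOMESTIC] * params.n_dom_accessions
    reps = [f"R{i + 1}" for i in range(params.n_replicates)]

    rows = {
        "species_id": [], "accession_id": [], "form": [], "replicate_id": [],
    }
    for acc, form in zip(accs, forms):
        for rep in reps:
            rows["species_id"].append(species_id)
            rows["accession_id"].append(acc)
            rows["form"].append(form)
            rows["replicate_id"].append(rep)
    df = pd.DataFrame(rows)
    n_acc = len(accs)
    acc_form = np.array(forms)
    dom = (df["form"] == DOMESTIC).to_numpy()
    acc_idx = df["accession_id"].map({a: i for i, a in enumerate(accs)}).to_numpy()
    rep_idx = df["replicate_id"].map({r: i for i, r in enumerate(reps)}).to_numpy()

    sd_e = np.sqrt(params.var_residual)
    metas = []
    for name, ttype, shared_id, delta in plan:
        if ttype is TraitType.QUALITATIVE:
            levels = [f"L{i + 1}" for i in range(params.qual_levels)]
            acc_levels = []
            for form in acc_form:
                probs = params.qual_base_probs
                if delta != 0.0 and form == DOMESTIC:
                    probs = params.qual_da_probs
                acc_levels.append(levels[rng.choice(params.qual_levels, p=np.asarray(probs))])
            df[name] = pd.Categorical(np.asarray(acc_levels)[acc_idx], categories=levels)
        else:
            block = rng.normal(0.0, params.block_effect_sd, size=params.n_replicates)
            a_k = rng.normal(0.0, np.sqrt(params.var_accession), size=n_acc)
            af_sd = np.sqrt([params.var_form_accession[f] for f in acc_form])
            af_k = rng.normal(0.0, 1.0, size=n_acc) * af_sd
            eps = rng.normal(0.0, sd_e, size=len(df))
            values = (params.mu + block[rep_idx] + delta * sd_e * dom
                      + a_k[acc_idx] + af_k[acc_idx] + eps)
            df[name] = values
        metas.append(TraitMeta(name, ttype, shared_id=shared_id))
    return TraitTable(df, metas)


def simulate_spectra(params: SimParams, organ: str,
                     individuals: Sequence[tuple[str, str]],
                     rng: Optional[np.random.Generator] = None) -> SpectraSet:
    """Draw smooth NIRS-like spectra for (individual_id, form) pairs.

    Leaf spectra carry no form signal by construction; seed spectra shift
    domestic individuals by ``seed_form_shift`` times a smooth signature
    curve (unit RMS), emulating domestication-altered seed composition.
    """
    if len(individuals) == 0:
        raise ValueError("empty individual list")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if organ == "leaf":
        grid = 350.0 + np.arange(params.n_leaf_wavelengths)
        n_reps = params.leaf_tech_reps
    else:
        grid = np.linspace(700.0, 2500.0, params.n_seed_wavelengths)
        n_reps = params.seed_tech_reps
    span = grid[-1] - grid[0]

    def smooth_curve(n_bumps: int) -> np.ndarray:
        centers = rng.uniform(grid[0], grid[-1], size=n_bumps)
        widths = rng.uniform(span / 50, span / 8, size=n_bumps)
        amps = rng.normal(0.0, 1.0, size=n_bumps)
        return (amps[:, None] * np.exp(-0.5 * ((grid[None, :] - centers[:, None])
                                               / widths[:, None]) ** 2)).sum(axis=0)

    signature = np.zeros_like(grid)
    if organ == "seed" and params.seed_form_shift != 0.0:
        sig = smooth_curve(5)
        signature = sig / max(np.sqrt(np.mean(sig ** 2)), 1e-12)

    index, data = [], []
    for ind, form in individuals:
        base = smooth_curve(int(rng.integers(8, 16))) + rng.uniform(0.5, 1.5)
        if form == DOMESTIC:
            base = base + params.seed_form_shift * signature
        for r in range(n_reps):
            gain = 1.0 + rng.normal(0.0, params.multiplicative_sd)
            offset = rng.normal(0.0, params.drift_sd)
            noise = rng.normal(0.0, params.spectra_noise_sd, size=len(grid))
            index.append((str(ind), f"T{r + 1}"))
            data.append(gain * base + offset + noise)
    values = pd.DataFrame(np.asarray(data),
                          index=pd.MultiIndex.from_tuples(index, names=["individual_id", "replicate_id"]),
                          columns=grid)
    if params.n_outlier_replicates > 0:
        pick = rng.choice(len(values), size=min(params.n_outlier_replicates, len(values)),
                          replace=False)
        values.iloc[pick] += params.outlier_offset
    return SpectraSet(values=values, organ=organ)


def simulate_multispecies(params: SimParams) -> StudyBundle:
    """Full study bundle: trait tables, leaf/seed spectra and species metadata.

    Shared traits carry identical ``shared_id`` across species; seed spectra
    are generated for roughly 8/13 of the species, mirroring uneven organ
    availability.
    """
    if params.trait_sharing_design is None:
        params = SimParams(**{**params.__dict__, "trait_sharing_design": default_sharing_design(params)})
    species = _species_ids(params)
    if set(params.trait_sharing_design.index) != set(species):
        raise ValueError("trait_sharing_design rows must match the simulated species")

    bundle = StudyBundle()
    n_seed_species = int(round(params.n_species * 8 / 13))
    timing_rng = np.random.default_rng([params.rng_seed & 0x7FFFFFFF, zlib.crc32(b"meta")])
    timings = np.exp(timing_rng.uniform(np.log(400.0), np.log(12000.0), size=len(species)))
    for i, sp in enumerate(species):
        table = simulate_species_traits(params, sp)
        bundle.trait_tables[sp] = table
        individuals = list(zip(table.individual_ids(), table.data["form"]))
        # deduplicate (qualitative replicate rows share the individual id only
        # when the design has no replicates; here ids are accession x replicate)
        bundle.spectra[(sp, "leaf")] = simulate_spectra(
            params, "leaf", individuals, rng=species_rng(params, sp, "leaf"))
        if i < n_seed_species:
            bundle.spectra[(sp, "seed")] = simulate_spectra(
                params, "seed", individuals, rng=species_rng(params, sp, "seed"))
        bundle.species_meta.append(SpeciesMeta(
            species_id=sp,
            timing_generations=float(timings[i]),
            mating_system="selfer" if i % 2 == 0 else "outcrosser",
            life_cycle="annual",
            diversity_ratio=float(timing_rng.uniform(0.3, 1.0)),
            family="Poaceae" if i < max(2, params.n_species // 3) else f"fam{i}",
        ))
    return bundle
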