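"""End-to-end study runner: chains every stage for a multi-species bundle.

Per species: leaf spectra -> control traits (LNIRS1/2) and QC; seed spectra
(when present) -> SNIRS1/2 appended to the trait table as ordinary
quantitative traits (flagged non-homologous across species); per-trait DA
calls; covariance hypervolume log ratio; FAMD + Pillai -> mPDI; accession-mean
correlation matrices and random skewers. Across species: the resampling
convergence test and the comparative statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import compare as cmp
from .convergence import ConvergenceResult, convergence_test, design_from_calls
from .datatypes import DOMESTIC, WILD, StudyBundle, StudyConfig, TraitMeta, TraitTable
from .matrices import compare_mean_abs_corr, gmatrix_pair, accession_means, spearman_matrix
from .nirs import nirs_control_traits
from .space import (EncodedMatrix, drop_linear_combinations, encode_traits,
                    hypervolume_log_ratio, species_disjunction)
from .syndrome import call_da_traits

log = logging.getLogger(__name__)


@dataclass
class SpeciesResult:
    species_id: str
    da_calls: list
    da_fraction: float
    space: object
    disjunction: object
    gpair: object
    mean_abs_corr: tuple
    leaf_qc: object
    control_log_ratio: Optional[float] = None


@dataclass
class StudyResult:
    species: dict = field(default_factory=dict)
    convergence: Optional[ConvergenceResult] = None
    report: Optional[dict] = None
    control_diversity: Optional[object] = None

    def per_species_frame(self) -> pd.DataFrame:
        rows = []
        for sp, r in sorted(self.species.items()):
            w, d, t, p = r.mean_abs_corr
            rows.append({
                "species_id": sp,
                "da_fraction": r.da_fraction,
                "log_ratio": r.space.log_ratio,
                "pillai_all": r.disjunction.pillai_all,
                "pillai_control": r.disjunction.pillai_control,
                "mpdi": r.disjunction.mpdi,
                "mpdi_per_baseline": r.disjunction.mpdi_per_baseline,
                "skewers_similarity": r.gpair.skewers_similarity,
                "mean_abs_corr_wild": w, "mean_abs_corr_dom": d,
                "mean_abs_corr_p": p,
                "rand_index_leaf": r.leaf_qc.rand_index,
                "control_log_ratio": r.control_log_ratio,
            })
        return pd.DataFrame(rows).set_index("species_id")


def _append_axis_traits(table: TraitTable, axis_traits: pd.DataFrame,
                        is_seed: bool) -> TraitTable:
    ids = table.individual_ids()
    data = table.data.copy()
    metas = list(table.traits)
    for col in axis_traits.columns:
        data[col] = ids.map(axis_traits[col]).to_numpy()
        metas.append(TraitMeta(col, "continuous",
                               is_seed_nirs=is_seed, is_control=not is_seed))
    return TraitTable(data, metas)


def control_space_log_ratio(leaf_coords: pd.DataFrame, forms: pd.Series,
                            var_target: float = 0.95) -> float:
    """Log ratio of form hypervolumes on the leaf-PCoA axis space.

    Axes are per-individual means of replicate projections; the axis count is
    capped so each form keeps more rows than columns (the leading axes up to
    ``var_target`` cumulative variance, at most min-form-size minus 2).
    """
    counts = forms.value_counts()
    cap = int(counts.min()) - 2
    var = leaf_coords.var(axis=0)
    cum = var.cumsum() / var.sum()
    k = int(np.searchsorted(cum.to_numpy(), var_target) + 1)
    k = max(2, min(k, cap, leaf_coords.shape[1]))
    sub = leaf_coords.iloc[:, :k]
    em = EncodedMatrix(sub, [(c, c, None) for c in sub.columns], forms)
    return hypervolume_log_ratio(em.subset_form(WILD), em.subset_form(DOMESTIC)).log_ratio


def run_species(table: TraitTable, leaf_spectra, seed_spectra=None,
                config: Optional[StudyConfig] = None) -> SpeciesResult:
    if config is None:
        config = StudyConfig()
    sp = table.species_id

    leaf_traits, leaf_qc = nirs_control_traits(leaf_spectra, config, prefix="LNIRS")
    if seed_spectra is not None:
        seed_traits, _ = nirs_control_traits(seed_spectra, config, prefix="SNIRS")
        table = _append_axis_traits(table, seed_traits, is_seed=True)

    # spectra QC may drop every replicate of an individual; such individuals
    # have no control-trait value and leave the multivariate stages
    covered = set(leaf_traits.index.astype(str))
    ids = table.individual_ids()
    if not set(ids).issubset(covered):
        missing = sorted(set(ids) - covered)
        log.warning("%s: %d individuals lost to spectra QC; excluded from analysis",
                    sp, len(missing))
        keep = ids.isin(covered).to_numpy()
        table = TraitTable(table.data.loc[keep].copy(), table.traits)

    calls = call_da_traits(table, config=config)
    da_fraction = float(np.mean([c.is_da for c in calls])) if calls else np.nan

    em = encode_traits(table, [tm for tm in table.traits if not tm.is_control])
    space = hypervolume_log_ratio(em.subset_form(WILD), em.subset_form(DOMESTIC),
                                  species_id=sp, tol=config.rank_tolerance)

    disjunction = species_disjunction(table, leaf_traits, config=config)

    gpair = gmatrix_pair(table, n_vectors=config.skewer_vectors, seed=config.rng_seed)
    means = accession_means(table)
    corr_w = spearman_matrix(means[means["form"] == WILD])
    corr_d = spearman_matrix(means[means["form"] == DOMESTIC])
    mac = compare_mean_abs_corr(corr_w, corr_d)

    # leaf-PCoA space log ratio (drift control): per-individual mean coordinates
    from .nirs import discard_outlier_replicates, pcoa, preprocess_spectra
    retained, _ = discard_outlier_replicates(leaf_spectra)
    pre = preprocess_spectra(retained, config)
    res = pcoa(pre)
    coords = res.coordinates.groupby(level=0, sort=False).mean()
    ids = table.individual_ids()
    form_by_id = pd.Series(table.data["form"].to_numpy(), index=ids)
    form_by_id = form_by_id[~form_by_id.index.duplicated()]
    coords = coords.loc[[i for i in coords.index if i in set(form_by_id.index)]]
    ctrl_lr = control_space_log_ratio(coords, form_by_id.loc[coords.index])

    return SpeciesResult(
        species_id=sp, da_calls=calls, da_fraction=da_fraction, space=space,
        disjunction=disjunction, gpair=gpair, mean_abs_corr=mac, leaf_qc=leaf_qc,
        control_log_ratio=ctrl_lr,
    )


def run_study(bundle: StudyBundle, config: Optional[StudyConfig] = None) -> StudyResult:
    if config is None:
        config = StudyConfig()
    out = StudyResult()
    tables_with_axes = {}
    calls_by_species = {}
    for sp in bundle.species_ids:
        table = bundle.trait_tables[sp]
        leaf = bundle.spectra.get((sp, "leaf"))
        seed = bundle.spectra.get((sp, "seed"))
        if leaf is None:
            log.warning("species %s has no leaf spectra; skipped", sp)
            continue
        r = run_species(table, leaf, seed, config)
        out.species[sp] = r
        calls_by_species[sp] = r.da_calls
        # rebuild the augmented table for the convergence design
        t = table
        if seed is not None:
            seed_traits, _ = nirs_control_traits(seed, config, prefix="SNIRS")
            t = _append_axis_traits(t, seed_traits, is_seed=True)
        tables_with_axes[sp] = t

    design = design_from_calls(calls_by_species, tables_with_axes)
    out.convergence = convergence_test(design, iterations=config.resample_iterations,
                                       seed=config.rng_seed)

    per_species = out.per_species_frame()
    out.report = cmp.build_report(per_species, bundle.species_meta)
    ctrl = {sp: r.control_log_ratio for sp, r in out.species.items()
            if r.control_log_ratio is not None}
    out.control_diversity = cmp.diversity_ratio_check(ctrl, bundle.species_meta)
    return out
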