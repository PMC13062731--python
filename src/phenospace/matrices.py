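"""Trait-correlation structure between forms: Spearman matrices and random skewers.

Traits are first averaged across replicates to one value per accession; all
correlation/covariance work is then done on these accession means,
quantitative traits only. The random-skewers similarity applies a common
random selection gradient beta (unit-norm Gaussian direction) to both
variance-covariance matrices via Lande's equation (Delta z = G beta) and
averages the cosine between the two response vectors over many draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DOMESTIC, WILD, TraitTable


@dataclass
class GMatrixPair:
    species_id: str
    cov_wild: pd.DataFrame
    cov_dom: pd.DataFrame
    n_traits: int
    skewers_similarity: float
    skewers_vectors: int
    seed: int


def accession_means(table: TraitTable) -> pd.DataFrame:
    """Per-accession means of quantitative traits (qualitative excluded)."""
    quant = table.quantitative_traits
    if not quant:
        raise ValueError("no quantitative traits")
    df = table.data[["accession_id", "form"] + quant]
    means = df.groupby(["accession_id", "form"], observed=True)[quant].mean().reset_index()
    empty = means[quant].isna().all(axis=1)
    if empty.any():
        import warnings
        warnings.warn(f"dropping {int(empty.sum())} accessions with no quantitative data")
        means = means.loc[~empty]
    return means


def spearman_matrix(means: pd.DataFrame, traits: Optional[list] = None) -> pd.DataFrame:
    """Pairwise Spearman correlations (mid-ranks, pairwise-complete)."""
    if traits is None:
        traits = [c for c in means.columns if c not in ("accession_id", "form")]
    if len(means) < 3:
        raise ValueError("need at least 3 accessions")
    sub = means[traits]
    constant = [c for c in traits if sub[c].dropna().nunique() < 2]
    corr = sub.corr(method="spearman")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _upper_abs(corr: pd.DataFrame) -> np.ndarray:
    arr = corr.to_numpy()
    iu = np.triu_indices_from(arr, k=1)
    vals = np.abs(arr[iu])
    return vals[~np.isnan(vals)]


def compare_mean_abs_corr(wild_corr: pd.DataFrame, dom_corr: pd.DataFrame,
                          welch: bool = True):
    """Two-sample t-test on the absolute upper-triangle correlations of each form.

    Returns (mean|r| wild, mean|r| dom, t, p).
    """
    w, d = _upper_abs(wild_corr), _upper_abs(dom_corr)
    if len(w) < 2 or len(d) < 2:
        raise ValueError("need at least 2 trait pairs per form")
    t, p = stats.ttest_ind(w, d, equal_var=not welch)
    return float(w.mean()), float(d.mean()), float(t), float(p)


def random_skewers(cov_wild: np.ndarray, cov_dom: np.ndarray,
                   n_vectors: int = 10_000, seed: int = 0,
                   pearson: bool = False) -> float:
    """Mean response-vector correlation of the two matrices to common skewers."""
    Cw = np.asarray(cov_wild, dtype=float)
    Cd = np.asarray(cov_dom, dtype=float)
    if Cw.shape != Cd.shape or Cw.shape[0] != Cw.shape[1]:
        raise ValueError("covariance matrices must share a square shape")
    for name, C in (("wild", Cw), ("domestic", Cd)):
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError(f"{name} covariance matrix is not symmetric")
    rng = np.random.default_rng(seed)
    p = Cw.shape[0]
    betas = rng.normal(size=(n_vectors, p))
    betas /= np.linalg.norm(betas, axis=1, keepdims=True)
    zw = betas @ Cw.T
    zd = betas @ Cd.T
    if pearson:
        zw = zw - zw.mean(axis=1, keepdims=True)
        zd = zd - zd.mean(axis=1, keepdims=True)
    nw = np.linalg.norm(zw, axis=1)
    nd = np.linalg.norm(zd, axis=1)
    ok = (nw > 0) & (nd > 0)
    n_skipped = int((~ok).sum())
    if n_skipped > 0.01 * n_vectors:
        import warnings
        warnings.warn(f"random skewers: {n_skipped} draws gave a zero response vector")
    cos = np.einsum("ij,ij->i", zw[ok], zd[ok]) / (nw[ok] * nd[ok])
    return float(cos.mean())


def gmatrix_pair(table: TraitTable, n_vectors: int = 10_000,
                 seed: int = 0) -> GMatrixPair:
    """Accession-mean covariance matrices per form and their skewers similarity."""
    means = accession_means(table)
    traits = [c for c in means.columns if c not in ("accession_id", "form")]
    # shared complete trait set across forms
    usable = []
    for c in traits:
        ok = True
        for form in (WILD, DOMESTIC):
            v = means.loc[means["form"] == form, c].dropna()
            if len(v) < 3 or v.nunique() < 2:
                ok = False
        if ok:
            usable.append(c)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable traits shared by both forms")
    covs = {}
    for form in (WILD, DOMESTIC):
        sub = means.loc[means["form"] == form, usable].dropna()
        covs[form] = sub.cov()
    sim = random_skewers(covs[WILD].to_numpy(), covs[DOMESTIC].to_numpy(),
                         n_vectors=n_vectors, seed=seed)
    return GMatrixPair(
        species_id=str(table.species_id), cov_wild=covs[WILD], cov_dom=covs[DOMESTIC],
        n_traits=len(usable), skewers_similarity=sim,
        skewers_vectors=n_vectors, seed=seed,
    )
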