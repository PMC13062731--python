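"""Multivariate phenotypic space: hypervolume log ratios, FAMD, Pillai trace, mPDI.

The *size* of a form's phenotypic space is measured by the determinant of the
variance-covariance matrix of its encoded traits. Because linearly dependent
columns are eliminated separately per form, determinants of different
dimension are made comparable by taking the r-th root with r the larger of
the two dimensions; the reported statistic is the natural-log ratio of the
domestic to the wild normalized size.

*Disjunction* between forms is the Pillai trace of a one-way MANOVA with form
as the factor and the FAMD axes of all (non-control) traits as responses;
the same statistic computed on the first two leaf-NIRS PCoA axes gives the
baseline disjunction Pillai_control, and their difference is the
multivariate phenotypic divergence index, mPDI = Pillai_all - Pillai_control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import DOMESTIC, WILD, StudyConfig, TraitMeta, TraitTable, TraitType

log = logging.getLogger(__name__)


@dataclass
class EncodedMatrix:
    matrix: pd.DataFrame          # rows = individuals, numeric columns
    provenance: list              # (column, source trait, level or None)
    forms: pd.Series              # aligned with matrix rows

    def subset_form(self, form: str) -> "EncodedMatrix":
        mask = (self.forms == form).to_numpy()
        return EncodedMatrix(self.matrix.loc[mask], self.provenance,
                             self.forms.loc[mask])


@dataclass
class SpaceSummary:
    species_id: str
    dim_wild: int
    dim_dom: int
    r: int
    logdet_wild: float
    logdet_dom: float
    norm_size_wild: float
    norm_size_dom: float
    log_ratio: float


@dataclass
class DisjunctionSummary:
    species_id: str
    pillai_all: float
    pillai_control: float
    mpdi: float
    mpdi_per_baseline: float
    baseline_undefined: bool = False
    n_axes_all: int = 0
    axes_truncated: bool = False


def encode_traits(table: TraitTable, meta: Optional[Sequence[TraitMeta]] = None,
                  impute: Optional[str] = None) -> EncodedMatrix:
    """Numeric encoding: z-scored quantitative columns, all-level indicators.

    Quantitative traits are standardized across *all* individuals (both forms
    pooled, sample SD); qualitative traits expand into one {0,1} column per
    level, summing to 1 per row. Zero-variance quantitative traits are
    dropped with a warning. Rows with missing values are dropped
    (complete-case) unless ``impute='form_mean'``.
    """
    if meta is None:
        meta = table.traits
    if len(table.data) < 2:
        raise ValueError("need at least 2 individuals")
    df = table.data
    cols, prov = [], []
    for tm in meta:
        name = tm.trait_name
        if tm.trait_type.is_quantitative:
            x = pd.to_numeric(df[name], errors="coerce")
            if impute == "form_mean":
                x = x.fillna(x.groupby(df["form"]).transform("mean"))
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"dropping zero-variance quantitative trait {name!r}")
                continue
            cols.append(((x - x.mean()) / sd).rename(name))
            prov.append((name, name, None))
        else:
            levels = df[name].astype("category")
            if impute == "form_mean" and levels.isna().any():
                # modal level within form
                fill = df.groupby("form", observed=True)[name].transform(
                    lambda s: s.mode().iloc[0] if not s.mode().empty else np.nan)
                levels = levels.fillna(fill)
            dummies = pd.get_dummies(levels, prefix=name, dtype=float)
            dummies[levels.isna().to_numpy()] = np.nan
            for lvl, col in zip(levels.cat.categories, dummies.columns):
                cols.append(dummies[col])
                prov.append((col, name, lvl))
    if not cols:
        raise ValueError("no usable (non-constant) traits to encode")
    mat = pd.concat(cols, axis=1)
    mat.index = table.individual_ids()
    forms = pd.Series(df["form"].to_numpy(), index=mat.index)
    keep = ~mat.isna().any(axis=1)
    if not keep.all():
        log.info("complete-case filter dropped %d of %d individuals",
                 int((~keep).sum()), len(mat))
    return EncodedMatrix(matrix=mat.loc[keep], provenance=prov, forms=forms.loc[keep])


def drop_linear_combinations(matrix: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Greedy left-to-right removal of columns linearly dependent on kept ones.

    Dependence is judged on centered columns (the covariance matrix is the
    downstream consumer), with threshold ``tol`` relative to the largest
    centered column norm; order-stable and idempotent.
    """
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    scale = max(np.linalg.norm(Xc, axis=0).max(), 1e-300)
    kept_idx: list[int] = []
    Q: list[np.ndarray] = []
    for j in range(Xc.shape[1]):
        v = Xc[:, j].copy()
        for q in Q:
            v -= (q @ v) * q
        # second orthogonalization pass for numerical stability
        for q in Q:
            v -= (q @ v) * q
        nrm = np.linalg.norm(v)
        if nrm > tol * scale:
            kept_idx.append(j)
            Q.append(v / nrm)
    return matrix.iloc[:, kept_idx]


def _log_det_cov(X: np.ndarray, label: str) -> float:
    n, p = X.shape
    if p < 1:
        raise ValueError(f"{label}: no non-degenerate trait columns left")
    if n < p + 1:
        raise ValueError(f"{label}: need at least {p + 1} rows for a {p}-column covariance")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (n - 1)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError(f"{label}: covariance not positive definite after reduction")
    return float(logdet)


def hypervolume_log_ratio(wild: EncodedMatrix | pd.DataFrame,
                          dom: EncodedMatrix | pd.DataFrame,
                          species_id: str = "", tol: float = 1e-8) -> SpaceSummary:
    """Covariance-determinant space sizes and their r-root-normalized log ratio."""
    w = wild.matrix if isinstance(wild, EncodedMatrix) else wild
    d = dom.matrix if isinstance(dom, EncodedMatrix) else dom
    w_red = drop_linear_combinations(w, tol)
    d_red = drop_linear_combinations(d, tol)
    logdet_w = _log_det_cov(w_red.to_numpy(dtype=float), "wild")
    logdet_d = _log_det_cov(d_red.to_numpy(dtype=float), "domestic")
    r = max(w_red.shape[1], d_red.shape[1])
    return SpaceSummary(
        species_id=species_id,
        dim_wild=w_red.shape[1], dim_dom=d_red.shape[1], r=r,
        logdet_wild=logdet_w, logdet_dom=logdet_d,
        norm_size_wild=float(np.exp(logdet_w / r)),
        norm_size_dom=float(np.exp(logdet_d / r)),
        log_ratio=float((logdet_d - logdet_w) / r),
    )


def famd(table: TraitTable, meta: Optional[Sequence[TraitMeta]] = None,
         tol: float = 1e-8):
    """Factorial analysis of mixed data: joint ordination of both trait types.

    Quantitative columns are standardized (population SD); each qualitative
    level indicator is scaled by 1/sqrt(level proportion) and centered. Row
    scores are the projections on the right singular vectors of the combined
    matrix; eigenvalues are squared singular values / n. All axes with
    singular value above tolerance are returned.
    """
    if meta is None:
        meta = table.traits
    if len(table.data) < 3:
        raise ValueError("FAMD requires at least 3 individuals")
    em = encode_traits(table, meta)
    return famd_from_encoded(em, meta, tol)


def famd_from_encoded(em: EncodedMatrix, meta: Sequence[TraitMeta], tol: float = 1e-8):
    df = em.matrix
    n = len(df)
    qual_sources = {tm.trait_name for tm in meta if not tm.trait_type.is_quantitative}
    blocks = []
    for col, source, level in em.provenance:
        if col not in df.columns:
            continue
        x = df[col].to_numpy(dtype=float)
        if source in qual_sources:
            p = x.mean()
            if p in (0.0, 1.0):
                continue  # level absent or universal in complete cases
            blocks.append((x - p) / np.sqrt(p))
        else:
            mu, sd = x.mean(), x.std(ddof=0)
            if sd == 0:
                continue
            blocks.append((x - mu) / sd)
    Z = np.column_stack(blocks)
    U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    keep = s > tol * max(s[0], 1e-300)
    scores = Z @ Vt[keep].T
    eigenvalues = s[keep] ** 2
    scores_df = pd.DataFrame(scores, index=df.index,
                             columns=[f"FAMD{i + 1}" for i in range(scores.shape[1])])
    return scores_df, eigenvalues


def pillai_trace(axes: pd.DataFrame | np.ndarray, forms: Sequence[str],
                 max_axes: Optional[int] = None) -> float:
    """Pillai trace of the one-way two-group MANOVA form ~ axes.

    Axes are assumed ordered by decreasing importance; if the total
    cross-product matrix H+E is singular at the given dimensionality, the
    trailing axes are truncated until it is invertible (logged).
    """
    X = np.asarray(axes, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    f = np.asarray(forms)
    groups = np.unique(f)
    if len(groups) < 2:
        raise ValueError("both forms must be present")
    N = X.shape[0]
    limit = X.shape[1] if max_axes is None else min(max_axes, X.shape[1])
    limit = min(limit, N - 2)
    if limit < 1:
        raise ValueError("not enough individuals for any response axis")
    for p in range(limit, 0, -1):
        Xp = X[:, :p]
        grand = Xp.mean(axis=0)
        H = np.zeros((p, p))
        E = np.zeros((p, p))
        for g in groups:
            sub = Xp[f == g]
            m = sub.mean(axis=0)
            H += len(sub) * np.outer(m - grand, m - grand)
            centered = sub - m
            E += centered.T @ centered
        T = H + E
        # guard against numerically singular total scatter
        if np.linalg.cond(T) > 1e12:
            continue
        if p < limit:
            log.info("Pillai: truncated responses from %d to %d axes", limit, p)
        val = float(np.trace(np.linalg.solve(T, H)))
        return float(np.clip(val, 0.0, min(len(groups) - 1, p)))
    raise ValueError("total cross-product matrix singular at every dimensionality")


def compute_mpdi(pillai_all: float, pillai_control: float,
                 species_id: str = "") -> DisjunctionSummary:
    """mPDI = Pillai_all - Pillai_control, plus the per-baseline variant."""
    for name, v in (("pillai_all", pillai_all), ("pillai_control", pillai_control)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    mpdi = pillai_all - pillai_control
    undefined = pillai_control == 0.0
    per_baseline = np.nan if undefined else mpdi / pillai_control
    return DisjunctionSummary(
        species_id=species_id, pillai_all=pillai_all, pillai_control=pillai_control,
        mpdi=mpdi, mpdi_per_baseline=float(per_baseline),
        baseline_undefined=bool(undefined),
    )


def species_disjunction(table: TraitTable, leaf_axes: pd.DataFrame,
                        meta: Optional[Sequence[TraitMeta]] = None,
                        config: Optional[StudyConfig] = None) -> DisjunctionSummary:
    """Pillai_all from FAMD of all non-control traits; Pillai_control from
    the two leaf-NIRS PCoA axis traits; assembled into the mPDI.

    ``leaf_axes`` must be indexed by individual id and cover every individual
    in the trait table.
    """
    if config is None:
        config = StudyConfig()
    if meta is None:
        meta = table.traits
    meta = [tm for tm in meta if not tm.is_control]
    ids = table.individual_ids()
    missing = sorted(set(ids) - set(leaf_axes.index.astype(str)))
    if missing:
        raise ValueError(f"individuals missing from leaf control axes: {missing[:10]}")

    em = encode_traits(table, meta)
    scores, _ = famd_from_encoded(em, meta, tol=config.rank_tolerance)
    n = len(scores)
    limit = n - 2
    truncated = scores.shape[1] > limit
    pillai_all = pillai_trace(scores, em.forms, max_axes=limit)

    form_by_id = pd.Series(table.data["form"].to_numpy(), index=ids)
    form_by_id = form_by_id[~form_by_id.index.duplicated()]
    ctrl = leaf_axes.loc[form_by_id.index]
    pillai_control = pillai_trace(ctrl.iloc[:, :2], form_by_id.to_numpy())

    out = compute_mpdi(pillai_all, pillai_control, species_id=table.species_id)
    out.n_axes_all = min(scores.shape[1], limit)
    out.axes_truncated = bool(truncated)
    return out
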