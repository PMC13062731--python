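"""Per-trait domestication-syndrome calling.

Quantitative traits are tested for a wild/domestic mean difference with the
randomized-block mixed model (random accession intercepts with form-specific
variance) when the design has replicates, or a simple fixed-effect linear
model otherwise; qualitative traits use Fisher's exact test on the
levels-by-form contingency table. Within each species the form-effect
p-values are converted to Benjamini-Hochberg q-values, and a trait is called
domestication-associated (DA) when q <= the FDR level (default 5%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .datatypes import DOMESTIC, WILD, StudyConfig, TraitMeta, TraitTable
from .lmm import fit_reml

log = logging.getLogger(__name__)

HIGHER = "higher_in_domestic"
LOWER = "lower_in_domestic"
SHIFT = "distribution_shift"


@dataclass
class LMMFit:
    trait_name: str
    estimate: float          # domestic - wild contrast
    std_error: float
    df: float
    t_value: float
    p_value: float
    sigma2_accession: float
    sigma2_form: dict        # per-form interaction variance
    sigma2_residual: float
    model_used: str          # "mixed" | "linear"


@dataclass
class DATraitCall:
    trait_name: str
    p_value: float
    q_value: float
    direction: str
    is_da: bool
    model_used: str
    estimate: Optional[float] = None


def _design(table: TraitTable, trait: str):
    df = table.data[["accession_id", "form", "replicate_id", trait]].dropna(subset=[trait])
    y = df[trait].to_numpy(dtype=float)
    dom = (df["form"] == DOMESTIC).to_numpy(dtype=float)
    reps = pd.Categorical(df["replicate_id"])
    cols = [np.ones(len(df))]
    if len(reps.categories) > 1:
        for cat in reps.categories[1:]:
            cols.append((reps == cat).astype(float))
    cols.append(dom)
    X = np.column_stack(cols)
    return df, X, y, dom, X.shape[1] - 1


def fit_trait_lmm(table: TraitTable, trait: str) -> LMMFit:
    """REML fit of the block + form model with per-accession random intercepts.

    Falls back to an accession-mean linear model (flagged ``model_used='linear'``)
    when the REML optimizer fails to converge.
    """
    if not table.has_replicates:
        raise ValueError("fit_trait_lmm requires a replicated design")
    df, X, y, dom, form_col = _design(table, trait)
    for form in (WILD, DOMESTIC):
        if df.loc[df["form"] == form, "accession_id"].nunique() < 2:
            raise ValueError(f"trait {trait!r}: fewer than 2 {form} accessions with data")
    res = fit_reml(X, y, df["accession_id"].to_numpy(), dom, form_col)
    if not res.converged:
        log.warning("REML did not converge for %s; falling back to accession-mean OLS", trait)
        means = df.groupby(["accession_id", "form"], observed=True)[trait].mean().reset_index()
        fit = fit_trait_lm(TraitTable(
            means.assign(species_id=table.species_id),
            [TraitMeta(trait, "continuous")]), trait)
        fit.model_used = "linear"
        return fit
    sigma2_k = min(res.tau2_wild, res.tau2_dom)
    return LMMFit(
        trait_name=trait, estimate=res.estimate, std_error=res.std_error,
        df=res.df, t_value=res.t_value, p_value=res.p_value,
        sigma2_accession=sigma2_k,
        sigma2_form={WILD: res.tau2_wild - sigma2_k, DOMESTIC: res.tau2_dom - sigma2_k},
        sigma2_residual=res.sigma2_e, model_used="mixed",
    )


def fit_trait_lm(table: TraitTable, trait: str) -> LMMFit:
    """OLS with a single form fixed effect; t-test on the domestic contrast."""
    df = table.data[["form", trait]].dropna(subset=[trait])
    y = df[trait].to_numpy(dtype=float)
    dom = (df["form"] == DOMESTIC).to_numpy(dtype=float)
    n_w, n_d = int((dom == 0).sum()), int(dom.sum())
    if n_w == 0 or n_d == 0:
        raise ValueError(f"trait {trait!r}: both forms required")
    n = n_w + n_d
    if n - 2 <= 0:
        raise ValueError(f"trait {trait!r}: zero residual degrees of freedom")
    mean_w, mean_d = y[dom == 0].mean(), y[dom == 1].mean()
    rss = float(np.sum((y[dom == 0] - mean_w) ** 2) + np.sum((y[dom == 1] - mean_d) ** 2))
    s2 = rss / (n - 2)
    se = np.sqrt(s2 * (1.0 / n_w + 1.0 / n_d))
    est = mean_d - mean_w
    if se == 0.0:
        tval, p = 0.0, 1.0
    else:
        tval = est / se
        p = float(2.0 * stats.t.sf(abs(tval), n - 2))
    return LMMFit(
        trait_name=trait, estimate=float(est), std_error=float(se), df=float(n - 2),
        t_value=float(tval), p_value=p, sigma2_accession=0.0,
        sigma2_form={WILD: 0.0, DOMESTIC: 0.0}, sigma2_residual=float(s2),
        model_used="linear",
    )


# ---------------------------------------------------------------------------
# Fisher exact test on levels x form tables


def _log_table_prob(tbl: np.ndarray, logfact_margins: float, logfact_N: float) -> float:
    return logfact_margins - logfact_N - float(gammaln(tbl + 1.0).sum())


def _enumerate_tables(row_sums, col_sums, cap=500_000):
    """Yield all non-negative integer tables with the given margins (or None if > cap)."""
    tables = []
    r, c = len(row_sums), len(col_sums)

    def rec(i, remaining_cols, current):
        if len(tables) > cap:
            raise OverflowError
        if i == r - 1:
            last = remaining_cols
            if (last >= 0).all() and last.sum() == row_sums[-1]:
                tables.append(np.vstack(current + [last]))
            return
        def fill(j, left, row):
            if j == c - 1:
                v = left
                if 0 <= v <= remaining_cols[-1]:
                    rec(i + 1, remaining_cols - np.array(row + [v]), current + [np.array(row + [v])])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, row + [v])
        fill(0, row_sums[i], [])

    try:
        rec(0, np.asarray(col_sums), [])
    except OverflowError:
        return None
    return tables


def fisher_exact_rxc(table: np.ndarray, rng: Optional[np.random.Generator] = None,
                     mc_draws: int = 100_000):
    """Fisher exact p for an r x c contingency table.

    Small tables are computed by full enumeration of fixed-margin tables;
    larger ones by a seeded permutation Monte Carlo (the permutation null is
    exactly the conditional hypergeometric distribution), flagged approximate.
    Returns (p_value, approximate_flag).
    """
    tbl = np.asarray(table, dtype=int)
    tbl = tbl[tbl.sum(axis=1) > 0][:, tbl.sum(axis=0) > 0]
    if tbl.size == 0 or min(tbl.shape) < 2:
        return 1.0, False
    if tbl.shape == (2, 2):
        return float(stats.fisher_exact(tbl)[1]), False
    row_sums, col_sums = tbl.sum(axis=1), tbl.sum(axis=0)
    logfact_margins = float(gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum())
    logfact_N = float(gammaln(tbl.sum() + 1.0))
    logp_obs = _log_table_prob(tbl, logfact_margins, logfact_N)
    tol = 1e-7
    all_tables = _enumerate_tables(row_sums, col_sums)
    if all_tables is not None:
        p = 0.0
        for t in all_tables:
            lp = _log_table_prob(t, logfact_margins, logfact_N)
            if lp <= logp_obs + tol:
                p += np.exp(lp)
        return float(min(p, 1.0)), False
    # Monte-Carlo fallback: permute column labels of expanded observations
    if rng is None:
        rng = np.random.default_rng(0)
    rows = np.repeat(np.arange(len(row_sums)), row_sums)
    cols = np.repeat(np.arange(len(col_sums)), col_sums)
    count = 0
    for _ in range(mc_draws):
        perm = rng.permutation(cols)
        sim = np.zeros_like(tbl)
        np.add.at(sim, (rows, perm), 1)
        if _log_table_prob(sim, logfact_margins, logfact_N) <= logp_obs + tol:
            count += 1
    return float((1 + count) / (1 + mc_draws)), True


def test_qualitative(table: TraitTable, trait: str,
                     config: Optional[StudyConfig] = None):
    """Fisher exact test of level distributions between forms.

    Returns (p_value, level-by-form count table).
    """
    df = table.data[["form", trait]].dropna(subset=[trait])
    counts = pd.crosstab(df[trait], df["form"], dropna=True)
    for form in (WILD, DOMESTIC):
        if form not in counts.columns:
            counts[form] = 0
    counts = counts[[WILD, DOMESTIC]]
    observed = counts.loc[counts.sum(axis=1) > 0]
    if len(observed) < 2:
        warnings.warn(f"trait {trait!r} constant across both forms; p = 1")
        return 1.0, counts
    seed = config.rng_seed if config is not None else 0
    p, _ = fisher_exact_rxc(observed.to_numpy(), rng=np.random.default_rng(seed))
    return p, counts


def bh_adjust(p_values: Sequence[float], level: float = 0.05):
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=level, method="fdr_bh")
    return q, q <= level


def call_da_traits(table: TraitTable, meta: Optional[Sequence[TraitMeta]] = None,
                   config: Optional[StudyConfig] = None) -> list[DATraitCall]:
    """Dispatch each trait to its test, then BH-adjust within the species."""
    if config is None:
        config = StudyConfig()
    if meta is None:
        meta = table.traits
    results = []
    for tm in meta:
        trait = tm.trait_name
        try:
            if tm.trait_type.is_quantitative:
                if table.has_replicates:
                    fit = fit_trait_lmm(table, trait)
                else:
                    fit = fit_trait_lm(table, trait)
                direction = HIGHER if fit.estimate > 0 else LOWER
                results.append((trait, fit.p_value, direction, fit.model_used, fit.estimate))
            else:
                p, _ = test_qualitative(table, trait, config)
                results.append((trait, p, SHIFT, "fisher", None))
        except ValueError as exc:
            log.warning("skipping trait %s: %s", trait, exc)
    if not results:
        return []
    q, flags = bh_adjust([r[1] for r in results], level=config.fdr_level)
    return [
        DATraitCall(trait_name=t, p_value=p, q_value=float(qv), direction=d,
                    is_da=bool(f), model_used=m, estimate=e)
        for (t, p, d, m, e), qv, f in zip(results, q, flags)
    ]


def da_calls_frame(calls: Sequence[DATraitCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
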