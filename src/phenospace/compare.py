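"""Cross-species comparative statistics over the per-species indices.

Species-level sample sizes are tiny (a dozen pairs), so rank-based tests are
primary: Spearman and Kendall correlations against domestication timing, and
the Wilcoxon-Mann-Whitney test (exact for combined n <= 12) for mating-system
contrasts, with the Student t reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SpeciesMeta


@dataclass
class CorrelationReport:
    n: int
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float
    underpowered: bool = False


@dataclass
class GroupTestReport:
    n_groups: tuple
    wmw_u: float
    wmw_p: float
    t_stat: float
    t_p: float
    exact: bool


def correlate_with_covariate(values: Sequence[float],
                             covariate: Sequence[float]) -> CorrelationReport:
    """Tie-corrected Spearman and Kendall correlations, two-sided."""
    v = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(v) & np.isfinite(c)
    v, c = v[ok], c[ok]
    if len(v) < 4:
        raise ValueError("need at least 4 paired values")
    if np.ptp(v) == 0 or np.ptp(c) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p_rho = stats.spearmanr(v, c)
    tau, p_tau = stats.kendalltau(v, c)
    return CorrelationReport(n=len(v), spearman_rho=float(rho), spearman_p=float(p_rho),
                             kendall_tau=float(tau), kendall_p=float(p_tau))


def test_group_difference(values: Sequence[float],
                          groups: Sequence[str]) -> GroupTestReport:
    """Wilcoxon-Mann-Whitney (primary) plus Student t for a binary grouping."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    a, b = v[g == labels[0]], v[g == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 species per group")
    exact = (len(a) + len(b)) <= 12 and len(np.unique(v)) == len(v)
    method = "exact" if exact else "asymptotic"
    u, wmw_p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    t, t_p = stats.ttest_ind(a, b, equal_var=True)
    return GroupTestReport(n_groups=(len(a), len(b)), wmw_u=float(u), wmw_p=float(wmw_p),
                           t_stat=float(t), t_p=float(t_p), exact=exact)


def diversity_ratio_check(log_ratios_on_control: Mapping[str, float],
                          species_meta: Sequence[SpeciesMeta]) -> CorrelationReport:
    """Correlate leaf-control space log ratios with genomic diversity ratios.

    The genomic diversity ratio (domestic/wild) proxies drift; a positive
    correlation supports leaf spectra as a drift-driven control trait.
    """
    pairs = []
    for m in species_meta:
        if m.species_id in log_ratios_on_control and m.diversity_ratio is not None:
            pairs.append((log_ratios_on_control[m.species_id], m.diversity_ratio))
    if len(pairs) < 4:
        return CorrelationReport(n=len(pairs), spearman_rho=np.nan, spearman_p=np.nan,
                                 kendall_tau=np.nan, kendall_p=np.nan, underpowered=True)
    v, c = zip(*pairs)
    return correlate_with_covariate(v, c)


def n_species_pairs(species_ids: Sequence[str]) -> int:
    """Number of unordered species pairs entering the pairwise-sharing summary."""
    s = len(set(species_ids))
    return s * (s - 1) // 2


def pairwise_shared_da(da_flags: pd.DataFrame) -> pd.DataFrame:
    """Species x species counts of shared DA trait identities (upper structure)."""
    arr = da_flags.to_numpy().astype(int)
    shared = arr @ arr.T
    out = pd.DataFrame(shared, index=da_flags.index, columns=da_flags.index)
    np.fill_diagonal(out.values, 0)
    return out


def build_report(per_species: pd.DataFrame,
                 species_meta: Sequence[SpeciesMeta],
                 trait_means: Optional[pd.DataFrame] = None) -> dict:
    """Join per-species indices with metadata; run the comparative tests.

    ``per_species`` is indexed by species_id with whatever index columns the
    upstream stages produced (log_ratio, pillai_all, pillai_control, mpdi,
    mpdi_per_baseline, skewers_similarity, mean_abs_corr_wild/dom,
    da_fraction, ...). Missing stages leave explicit gaps.
    """
    meta_df = pd.DataFrame([m.__dict__ for m in species_meta]).set_index("species_id")
    summary = per_species.join(meta_df, how="left")

    tests: dict[str, object] = {}
    timing = summary["timing_generations"]
    for col in ("mpdi", "log_ratio", "skewers_similarity"):
        if col not in summary or summary[col].isna().all():
            tests[f"{col}_vs_timing"] = None
            continue
        try:
            tests[f"{col}_vs_timing"] = correlate_with_covariate(summary[col], timing)
        except ValueError:
            tests[f"{col}_vs_timing"] = None
    for col in ("mpdi", "mpdi_per_baseline", "log_ratio", "skewers_similarity"):
        if col not in summary or summary[col].isna().all():
            tests[f"{col}_vs_mating"] = None
            continue
        sub = summary.dropna(subset=[col, "mating_system"])
        try:
            tests[f"{col}_vs_mating"] = test_group_difference(sub[col], sub["mating_system"])
        except ValueError:
            tests[f"{col}_vs_mating"] = None
    report = {"summary": summary, "tests": tests}
    if trait_means is not None:
        report["trait_means"] = trait_means
    return report


def radar_table(table_data: pd.DataFrame, quant_traits: Sequence[str]) -> pd.DataFrame:
    """Plot-ready per-form trait means with standard errors."""
    rows = []
    for form, sub in table_data.groupby("form", observed=True):
        for trait in quant_traits:
            v = pd.to_numeric(sub[trait], errors="coerce").dropna()
            rows.append({"form": form, "trait": trait, "mean": v.mean(),
                         "se": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                         "n": len(v)})
    return pd.DataFrame(rows)
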