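"""Cross-species comparative statistics over the per-species indices.

Joins every stage's per-species summary with the species metadata and runs
the comparative tests: Spearman/Kendall against domestication timing,
Wilcoxon-Mann-Whitney (and Student t) against mating system, and the
leaf-space vs genomic-diversity drift check. Writes results/study_summary.tsv
and results/comparative_tests.json, plus a radar-plot-ready trait-mean table.
"""

import json

import numpy as np
import pandas as pd

from _study import RESULTS, load_bundle, study_config
import phenospace as ph
from phenospace.compare import radar_table

config = study_config()
bundle = load_bundle()
result = ph.run_study(bundle, config)

summary = result.report["summary"]
summary.to_csv(RESULTS / "study_summary.tsv", sep="\t")
print(f"{len(summary)} species, {ph.n_species_pairs(summary.index)} species pairs")

tests_out = {}
for name, test in result.report["tests"].items():
    if test is None:
        tests_out[name] = None
        continue
    if hasattr(test, "spearman_rho"):
        tests_out[name] = {"spearman_rho": test.spearman_rho, "spearman_p": test.spearman_p,
                           "kendall_tau": test.kendall_tau, "kendall_p": test.kendall_p}
        print(f"{name}: Spearman p = {test.spearman_p:.3f}, Kendall p = {test.kendall_p:.3f}")
    else:
        tests_out[name] = {"wmw_p": test.wmw_p, "t_p": test.t_p, "exact": test.exact}
        print(f"{name}: WMW p = {test.wmw_p:.3f} (t-test p = {test.t_p:.3f})")

drift = result.control_diversity
tests_out["control_space_vs_diversity_ratio"] = (
    None if drift.underpowered else
    {"spearman_rho": drift.spearman_rho, "spearman_p": drift.spearman_p,
     "kendall_tau": drift.kendall_tau, "kendall_p": drift.kendall_p})
if not drift.underpowered:
    print(f"leaf-space log ratio vs genomic diversity ratio: "
          f"Spearman rho = {drift.spearman_rho:.2f}, p = {drift.spearman_p:.3f}")

(RESULTS / "comparative_tests.json").write_text(json.dumps(tests_out, indent=2) + "\n")

radar = []
for sp, table in sorted(bundle.trait_tables.items()):
    t = radar_table(table.data, table.quantitative_traits)
    t.insert(0, "species_id", sp)
    radar.append(t)
pd.concat(radar, ignore_index=True).to_csv(RESULTS / "trait_means_radar.tsv",
                                           sep="\t", index=False)
print(f"wrote {RESULTS / 'study_summary.tsv'}, comparative_tests.json, "
      f"trait_means_radar.tsv")
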