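"""Call domestication-associated traits per species (mixed model / Fisher + BH-FDR).

Reads the trait tables written by 01, fits the form contrast per trait and
writes results/da_calls.tsv with p, q, direction and the DA flag.
"""

import pandas as pd

from _study import RESULTS, study_config
import phenospace as ph
from phenospace.syndrome import da_calls_frame

study_dir = RESULTS / "study"
config = study_config()
ontology = pd.read_csv(study_dir / "trait_ontology.csv")

frames = []
for path in sorted(study_dir.glob("sp[0-9][0-9].csv")):
    sp = path.stem
    meta = [ph.TraitMeta(r.trait_name, r.trait_type,
                         shared_id=(r.shared_id if isinstance(r.shared_id, str)
                                    and r.shared_id else None))
            for r in ontology[ontology["species_id"] == sp].itertuples()]
    table = ph.read_trait_table(path, meta)
    calls = ph.call_da_traits(table, config=config)
    frame = da_calls_frame(calls)
    frame.insert(0, "species_id", sp)
    frames.append(frame)
    frac = frame["is_da"].mean()
    print(f"{sp}: {frame['is_da'].sum()}/{len(frame)} traits DA ({100 * frac:.0f}%)")

all_calls = pd.concat(frames, ignore_index=True)
all_calls.to_csv(RESULTS / "da_calls.tsv", sep="\t", index=False)
print(f"\noverall DA fraction: {100 * all_calls['is_da'].mean():.1f}% "
      f"-> {RESULTS / 'da_calls.tsv'}")
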