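"""Shared setup for the analysis drivers: one deterministic synthetic study.

Every driver rebuilds the same 13-species study from SEED so each stage can
be run (and re-run) independently; all tables land under results/.
"""

from pathlib import Path

import phenospace as ph

SEED = 2024
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_params() -> ph.SimParams:
    return ph.SimParams(rng_seed=SEED)


def study_config() -> ph.StudyConfig:
    return ph.StudyConfig(rng_seed=SEED)


def load_bundle() -> ph.StudyBundle:
    return ph.simulate_multispecies(study_params())
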