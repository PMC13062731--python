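import numpy as np
import pandas as pd
import pytest

import phenospace as ph


@pytest.fixture
def toy_table():
    """Six individuals, two forms, one quantitative + one qualitative trait."""
    df = pd.DataFrame({
        "species_id": ["spX"] * 6,
        "accession_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
        "form": ["wild"] * 3 + ["domestic"] * 3,
        "height": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
        "color": ["red", "red", "blue", "blue", "blue", "blue"],
    })
    meta = [ph.TraitMeta("height", "continuous"), ph.TraitMeta("color", "qualitative")]
    return ph.TraitTable(df, meta)


@pytest.fixture
def small_params():
    """Small but structured study for fast end-to-end tests."""
    return ph.SimParams(
        n_species=3, n_wild_accessions=8, n_dom_accessions=8, n_replicates=3,
        n_quant_traits=8, n_qual_traits=2, n_shared_traits=4,
        n_leaf_wavelengths=300, n_seed_wavelengths=200, rng_seed=42,
    )


@pytest.fixture
def spectra_factory():
    """Build a SpectraSet from a dict individual -> array of replicate spectra."""
    def make(spectra_by_ind, organ="leaf", grid=None):
        rows, index = [], []
        n_wl = len(next(iter(spectra_by_ind.values()))[0])
        if grid is None:
            grid = 350.0 + np.arange(n_wl)
        for ind, reps in spectra_by_ind.items():
            for i, rep in enumerate(reps):
                index.append((ind, f"T{i + 1}"))
                rows.append(np.asarray(rep, dtype=float))
        values = pd.DataFrame(
            np.vstack(rows),
            index=pd.MultiIndex.from_tuples(index, names=["individual_id", "replicate_id"]),
            columns=grid,
        )
        return ph.SpectraSet(values=values, organ=organ)
    return make
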