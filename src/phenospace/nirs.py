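"""Spectra quality control, chemometric preprocessing and PCoA trait construction.

The chain is: (1) discard deviant technical replicates (a replicate whose
leave-one-out deviation from its individual's mean exceeds twice the
leave-one-out SD over at least 30% of the spectrum); (2) standard-normal-
variate normalization per spectrum followed by a Savitzky-Golay first
derivative (window 37, order 2, interior points only); (3) principal
coordinate analysis on Euclidean distances between preprocessed spectra;
(4) per-individual means of the first two axes become two new traits
(LNIRS1/2 for leaves — the domestication-neutral control — and SNIRS1/2 for
seeds). Replicate grouping is validated by Ward hierarchical clustering cut
at one cluster per individual, scored with the Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import savgol_coeffs
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.metrics import rand_score

from .datatypes import SpectraSet, StudyConfig

log = logging.getLogger(__name__)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame     # rows = spectra (individual, replicate), cols = axes
    eigenvalues: np.ndarray       # non-increasing
    variance_explained: np.ndarray


@dataclass
class ClusteringValidation:
    g: int
    rand_index: float


def discard_outlier_replicates(spectra: SpectraSet, sd_mult: float = 2.0,
                               frac: float = 0.30):
    """Drop technical replicates that deviate from their individual's profile.

    A replicate is discarded when its per-wavelength deviation from the
    individual's profile — measured as the distance to its *nearest* sibling
    replicate — exceeds ``sd_mult`` times a robust SD of replicate
    differences over at least ``frac`` of the spectrum. The nearest-sibling
    distance keeps the reference uncontaminated by the candidate outlier
    (with 3-4 technical replicates a per-wavelength SD that includes the
    candidate can mathematically never be exceeded twofold, so the naive
    reading of the rule would be vacuous), and the scale is calibrated from
    the median nearest-sibling distance via the order statistics of
    half-normal differences. Individuals with fewer than 3 replicates are
    retained untouched. Returns (retained SpectraSet, discard log).
    """
    from scipy.special import erfinv

    values = spectra.values
    drop: list[tuple] = []
    discard_log = []
    for ind in spectra.individuals:
        block = values.loc[ind]
        n = len(block)
        if n < 3:
            if n < 2:
                log.warning("individual %s has a single replicate; retained untouched", ind)
            continue
        arr = block.to_numpy()
        # nearest-sibling distance per replicate and wavelength
        diffs = np.abs(arr[:, None, :] - arr[None, :, :])
        diffs[np.arange(n), np.arange(n), :] = np.inf
        nearest = diffs.min(axis=1)
        # scale = robust SD of a replicate difference, from a low quantile of
        # the nearest-sibling distances (quantile q of min-of-(n-1) half-normal
        # sits at sd * sqrt(2) * erfinv(1 - (1-q)^{1/(n-1)}); q = 0.25 tolerates
        # one grossly deviant replicate contaminating 1/n of the entries)
        q = 0.25
        z_n = np.sqrt(2.0) * float(erfinv(1.0 - (1.0 - q) ** (1.0 / (n - 1))))
        scale = float(np.quantile(nearest, q)) / z_n
        if scale == 0.0:
            continue  # replicates identical everywhere
        for i, rep in enumerate(block.index):
            share = float((nearest[i] > sd_mult * scale).mean())
            if share >= frac:
                drop.append((ind, rep))
                discard_log.append({"individual_id": ind, "replicate_id": rep,
                                    "fraction_exceeding": share})
    if drop:
        retained = values.drop(index=drop)
        lost = set(spectra.individuals) - set(retained.index.get_level_values(0))
        for ind in sorted(lost):
            log.warning("individual %s lost all replicates to the outlier rule", ind)
    else:
        retained = values
    return spectra.with_values(retained), discard_log


def preprocess_spectra(spectra: SpectraSet, config: StudyConfig | None = None) -> SpectraSet:
    """SNV-normalize each spectrum, then take its Savitzky-Golay first derivative.

    The derivative uses interior points only, so the wavelength grid shrinks
    by (window - 1) points. A constant (zero-SD) spectrum is fatal.
    """
    if config is None:
        config = StudyConfig()
    window, order = config.sg_window, config.sg_order
    grid = spectra.wavelengths
    if len(grid) < window:
        raise ValueError(f"grid length {len(grid)} shorter than SG window {window}")
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("Savitzky-Golay derivative requires a uniform wavelength grid")
    arr = spectra.values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        first = spectra.values.index[bad[0]]
        raise ValueError(f"zero-SD (constant) spectrum for replicate {first}")
    snv = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    coeffs = savgol_coeffs(window, order, deriv=1, delta=float(steps[0]), use="dot")
    windows = sliding_window_view(snv, window, axis=1)
    deriv = windows @ coeffs
    half = window // 2
    out = pd.DataFrame(deriv, index=spectra.values.index, columns=grid[half:-half])
    return spectra.with_values(out)


def snv_only(spectra: SpectraSet) -> SpectraSet:
    """Standard-normal-variate step alone (mean 0, sample SD 1 per spectrum)."""
    arr = spectra.values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-SD spectrum")
    snv = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return spectra.with_values(pd.DataFrame(snv, index=spectra.values.index,
                                            columns=spectra.values.columns))


def pcoa(spectra: SpectraSet, n_axes: int | None = None,
         tol: float = 1e-8) -> PcoaResult:
    """Classical metric MDS on Euclidean distances between spectra."""
    values = spectra.values
    if len(values) < 3:
        raise ValueError("PCoA requires at least 3 spectra")
    ids = [f"{i}||{r}" for i, r in values.index]
    dm = DistanceMatrix(squareform(pdist(values.to_numpy(), metric="euclidean")), ids=ids)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = np.asarray(res.eigvals, dtype=float)
    keep = eig > tol * max(eig.max(), 1.0)
    if n_axes is not None:
        keep &= np.arange(len(eig)) < n_axes
    coords = res.samples.iloc[:, np.flatnonzero(keep)]
    coords = pd.DataFrame(coords.to_numpy(), index=values.index,
                          columns=[f"PCo{i + 1}" for i in range(coords.shape[1])])
    eig_kept = eig[keep]
    total = eig[eig > 0].sum()
    return PcoaResult(coordinates=coords, eigenvalues=eig_kept,
                      variance_explained=eig_kept / total)


def spectra_to_traits(result: PcoaResult, prefix: str) -> pd.DataFrame:
    """Per-individual means of the first two PCoA axes as two new traits."""
    if result.coordinates.shape[1] < 2:
        raise ValueError("need at least two positive PCoA axes")
    two = result.coordinates.iloc[:, :2]
    means = two.groupby(level=0, sort=False).mean()
    means.columns = [f"{prefix}1", f"{prefix}2"]
    means.index.name = "individual_id"
    return means


def validate_replicate_clustering(spectra: SpectraSet) -> ClusteringValidation:
    """Ward clustering cut at g = number of individuals, scored by Rand index."""
    values = spectra.values
    individuals = values.index.get_level_values(0)
    g = individuals.nunique()
    n = len(values)
    if g >= n:
        raise ValueError("need fewer groups than spectra (>=2 replicates somewhere)")
    if g < 2:
        raise ValueError("need at least 2 individuals")
    Z = linkage(values.to_numpy(), method="ward")
    cut = fcluster(Z, t=g, criterion="maxclust")
    true = pd.factorize(individuals)[0]
    return ClusteringValidation(g=int(g), rand_index=float(rand_score(true, cut)))


@dataclass
class NirsQC:
    n_discarded: int
    discard_log: list
    rand_index: float
    variance_explained: np.ndarray


def nirs_control_traits(spectra: SpectraSet, config: StudyConfig | None = None,
                        prefix: str | None = None):
    """Full pipeline: QC -> preprocess -> PCoA -> per-individual axis traits.

    Returns (traits DataFrame, NirsQC).
    """
    if prefix is None:
        prefix = "LNIRS" if spectra.organ == "leaf" else "SNIRS"
    retained, dlog = discard_outlier_replicates(spectra)
    pre = preprocess_spectra(retained, config)
    validation = validate_replicate_clustering(pre)
    res = pcoa(pre)
    traits = spectra_to_traits(res, prefix)
    qc = NirsQC(n_discarded=len(dlog), discard_log=dlog,
                rand_index=validation.rand_index,
                variance_explained=res.variance_explained[:5])
    return traits, qc
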