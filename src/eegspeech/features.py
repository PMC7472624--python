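"""Relative wavelet energy and filter-bank CSP features.

RWE: a 5-level db4 discrete wavelet decomposition at 128 Hz yields the
detail levels D2 (16-32 Hz), D3 (8-16 Hz), D4 (4-8 Hz), D5 (2-4 Hz) and
approximation A5 (<2 Hz); per channel, the energies of these five levels
are normalized to sum to one (D1 is computed but discarded).  Six
channels give a 30-element vector per trial.

FBCSP: a six-band filter bank (delta through gamma) feeds per-band CSP
spatial filters; log-variance features of the projections are ranked by
quantized mutual information with the labels and the top NoF retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import linalg

from .preprocess import design_bandpass, zero_phase_fir
from .synthetic import CANONICAL_BANDS, TrialSet

__all__ = [
    "DEFAULT_FILTERBANK_EDGES",
    "RWE_LEVEL_BANDS",
    "rwe_extract",
    "FilterBank",
    "build_filterbank",
    "band_covariances",
    "CSPModel",
    "fit_csp",
    "fit_csp_bank",
    "csp_log_variance",
    "FeatureSelection",
    "mutual_information",
    "select_features",
    "fbcsp_features",
]

#: Nominal Hz range of each retained DWT level at fs = 128 Hz.
RWE_LEVEL_BANDS = {
    "D2": (16.0, 32.0),
    "D3": (8.0, 16.0),
    "D4": (4.0, 8.0),
    "D5": (2.0, 4.0),
    "A5": (0.0, 2.0),
}
RWE_LEVEL_ORDER = ("D2", "D3", "D4", "D5", "A5")

DEFAULT_FILTERBANK_EDGES = tuple(CANONICAL_BANDS.values())


def rwe_extract(
    trials: TrialSet | np.ndarray, wavelet: str = "db4", levels: int = 5
) -> np.ndarray:
    """Relative wavelet energy features, (trials, 5 * channels).

    Per channel the DWT coefficient energies of levels D2..D5 and A5 are
    normalized by their sum, so each channel's five values sum to one.
    Ordered channel-major: (ch0 D2, ch0 D3, ..., ch0 A5, ch1 D2, ...).
    """
    data = trials.data if isinstance(trials, TrialSet) else np.asarray(trials)
    if data.ndim == 2:
        data = data[None]
    n_trials, n_ch, n_samples = data.shape
    if n_samples < 2**levels:
        raise ValueError(
            f"trials too short for {levels}-level DWT: {n_samples} samples"
        )
    # coeffs: [A5, D5, D4, D3, D2, D1] for levels=5
    coeffs = pywt.wavedec(data, wavelet, level=levels, mode="symmetric", axis=-1)
    energies = {
        "A5": np.sum(coeffs[0] ** 2, axis=-1),
        "D5": np.sum(coeffs[1] ** 2, axis=-1),
        "D4": np.sum(coeffs[2] ** 2, axis=-1),
        "D3": np.sum(coeffs[3] ** 2, axis=-1),
        "D2": np.sum(coeffs[4] ** 2, axis=-1),
    }
    stacked = np.stack([energies[k] for k in RWE_LEVEL_ORDER], axis=-1)
    total = stacked.sum(axis=-1, keepdims=True)
    total[total == 0] = 1.0
    rwe = stacked / total  # (trials, channels, 5)
    return rwe.reshape(n_trials, n_ch * len(RWE_LEVEL_ORDER))


def wavelet_energies(x: np.ndarray, wavelet: str = "db4", levels: int = 5):
    """Unnormalized per-level coefficient energies (incl. D1), plus the
    total coefficient energy.  Energy across all levels equals the total
    by construction (orthogonal DWT: Parseval)."""
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric", axis=-1)
    per_level = [np.sum(c**2, axis=-1) for c in coeffs]
    return per_level, sum(per_level)


@dataclass
class FilterBank:
    """A set of zero-phase FIR band-pass filters."""

    edges: tuple
    fs: float
    taps: list

    def __len__(self):
        return len(self.taps)

    def apply(self, data: np.ndarray) -> np.ndarray:
        """(..., samples) -> (n_bands, ..., samples)."""
        return np.stack([zero_phase_fir(data, t) for t in self.taps])


def build_filterbank(
    edges=DEFAULT_FILTERBANK_EDGES, fs: float = 128.0, max_taps: int | None = None
) -> FilterBank:
    """One band-pass filter per (lo, hi) pair; same FIR family as the
    preprocessing stage, order scaled per band (3 * fs / lo), capped so
    short trials remain filterable."""
    edges = tuple(tuple(e) for e in edges)
    if len(edges) == 0:
        raise ValueError("edge list is empty")
    taps = []
    for lo, hi in edges:
        if lo >= hi:
            raise ValueError(f"degenerate band ({lo}, {hi})")
        order = int(round(3 * fs / lo))
        if max_taps is not None:
            order = min(order, max_taps)
        taps.append(design_bandpass(lo, hi, fs, order))
    return FilterBank(edges=edges, fs=fs, taps=taps)


def band_covariances(
    trials: TrialSet | np.ndarray, bank: FilterBank
) -> np.ndarray:
    """Per-trial, per-band spatial covariance tensor.

    Returns (n_trials, n_bands, C, C).  Label-free, so it can be
    computed once per dataset without leaking fold information.
    """
    data = trials.data if isinstance(trials, TrialSet) else np.asarray(trials)
    n_trials, n_ch, n_samples = data.shape
    covs = np.empty((n_trials, len(bank), n_ch, n_ch))
    for b, taps in enumerate(bank.taps):
        xb = zero_phase_fir(data, taps)
        covs[:, b] = np.einsum("tcs,tds->tcd", xb, xb) / (n_samples - 1)
    return covs


@dataclass
class CSPModel:
    """Per-band CSP spatial filters.

    filters: list over bands of (2*nSF, C) arrays (rows are filters);
    each row w satisfies w' Sigma_total w = 1 on the training data.
    """

    filters: list
    band_edges: tuple
    nsf: int

    @property
    def n_bands(self) -> int:
        return len(self.filters)


def _class_covs(covs_band: np.ndarray, y: np.ndarray) -> dict:
    return {c: covs_band[y == c].mean(axis=0) for c in np.unique(y)}


def _regularize(mat: np.ndarray, ridge: float) -> np.ndarray:
    return mat + ridge * np.trace(mat) / mat.shape[0] * np.eye(mat.shape[0])


def fit_csp(covs_band: np.ndarray, y: np.ndarray, nsf: int) -> np.ndarray:
    """CSP filters for one band from per-trial covariances, (2*nSF, C).

    Two classes: the classic generalized eigendecomposition of
    (Sigma_1, Sigma_1 + Sigma_2), taking nSF eigenvectors from each end.
    More classes: one-vs-rest per class; each class contributes its nSF
    largest-eigenvalue filters and the pool is capped at 2*nSF by
    eigenvalue extremity |lambda - 0.5|.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes for CSP")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
    cls_covs = _class_covs(covs_band, y)
    total = covs_band.mean(axis=0)

    def geneig(a, b):
        for ridge in (0.0, 1e-10, 1e-6, 1e-3):
            try:
                w, v = linalg.eigh(_regularize(a, ridge), _regularize(b, ridge))
                if ridge > 0:
                    warnings.warn(
                        f"singular covariance: ridge {ridge} applied in CSP"
                    )
                return w, v
            except linalg.LinAlgError:
                continue
        raise linalg.LinAlgError("covariance still singular after ridge")

    if len(classes) == 2:
        s1, s2 = cls_covs[classes[0]], cls_covs[classes[1]]
        w, v = geneig(s1, s1 + s2)
        order = np.argsort(w)
        idx = np.concatenate([order[-nsf:][::-1], order[:nsf]])
        return v[:, idx].T
    # one-vs-rest
    candidates = []  # (extremity, class_rank, filter)
    for ci, c in enumerate(classes):
        w, v = geneig(cls_covs[c], total)
        order = np.argsort(w)[::-1][:nsf]  # largest-variance end for class c
        for rank, j in enumerate(order):
            candidates.append((abs(w[j] - 0.5), (ci, rank), v[:, j]))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    keep = candidates[: 2 * nsf]
    return np.stack([f for _, _, f in keep])


def fit_csp_bank(
    covs: np.ndarray, y: np.ndarray, nsf: int, band_edges=DEFAULT_FILTERBANK_EDGES
) -> CSPModel:
    """Fit CSP independently in every band of a covariance tensor."""
    filters = [fit_csp(covs[:, b], y, nsf) for b in range(covs.shape[1])]
    return CSPModel(filters=filters, band_edges=tuple(band_edges), nsf=nsf)


def csp_log_variance(covs: np.ndarray, model: CSPModel) -> np.ndarray:
    """Log-variance of each CSP projection, (n_trials, n_bands * 2*nSF)."""
    feats = []
    for b, w in enumerate(model.filters):
        var = np.einsum("fc,tcd,fd->tf", w, covs[:, b], w)
        feats.append(np.log(np.maximum(var, 1e-12)))
    return np.concatenate(feats, axis=1)


@dataclass
class FeatureSelection:
    """MI ranking of candidate features at a given quantization level."""

    mi_scores: np.ndarray
    selected: np.ndarray
    miql: int


def _quantize_equal_frequency(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based equal-frequency binning into ``bins`` levels."""
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (ranks * bins // len(x)).astype(np.int64)


def mutual_information(feature: np.ndarray, y: np.ndarray, miql: int) -> float:
    """Plug-in MI (bits) between an equal-frequency-quantized feature
    and the class labels."""
    q = _quantize_equal_frequency(np.asarray(feature, dtype=float), miql)
    y = np.asarray(y)
    classes, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((miql, len(classes)))
    np.add.at(joint, (q, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def select_features(
    features: np.ndarray, y: np.ndarray, miql: int, nof: int
) -> FeatureSelection:
    """Rank candidates by MI with the labels; keep the top ``nof``.

    Ties broken by feature index (stable sort on descending MI).
    """
    n_cand = features.shape[1]
    if nof > n_cand:
        raise ValueError(f"nof {nof} exceeds candidate count {n_cand}")
    mi = np.array(
        [mutual_information(features[:, j], y, miql) for j in range(n_cand)]
    )
    selected = np.argsort(-mi, kind="stable")[:nof]
    return FeatureSelection(mi_scores=mi, selected=selected, miql=miql)


def fbcsp_features(
    covs: np.ndarray,
    model: CSPModel,
    y_train: np.ndarray,
    train_idx: np.ndarray,
    miql: int,
    nof: int,
) -> tuple[np.ndarray, FeatureSelection]:
    """Selected log-variance features for all trials.

    The CSP model and the MI ranking are fitted on training trials only
    (``train_idx`` into ``covs``); the returned matrix covers every
    trial, restricted to the selected columns.
    """
    candidates = csp_log_variance(covs, model)
    selection = select_features(candidates[train_idx], y_train, miql, nof)
    return candidates[:, selection.selected], selection
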