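"""Band-limiting, ICA blink screening, resampling and segmentation.

The pipeline mirrors a standard imagined-speech EEG preprocessing chain:
2-40 Hz zero-phase FIR band-pass, per-subject FastICA with a
template-correlation screen for eye-blink components (|r| >= 0.8),
and polyphase downsampling to 128 Hz (512 samples per 4 s trial).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .synthetic import TrialSet

__all__ = [
    "ComponentSet",
    "ArtifactScreenResult",
    "design_bandpass",
    "zero_phase_fir",
    "bandpass_fir",
    "downsample",
    "fit_ica",
    "screen_blink_components",
    "remove_components",
    "clean_blinks",
]


@dataclass
class ComponentSet:
    """An ICA decomposition of one subject's concatenated trials.

    unmixing: (components, channels); sources: (components, samples) for
    the concatenated full-rate data; topographies (the "component
    maps"): (channels, components) columns of the mixing matrix.
    """

    unmixing: np.ndarray
    sources: np.ndarray
    topographies: np.ndarray
    mean: np.ndarray

    def __post_init__(self):
        if self.unmixing.shape[0] > self.unmixing.shape[1]:
            raise ValueError(
                "more components than channels: "
                f"{self.unmixing.shape[0]} > {self.unmixing.shape[1]}"
            )

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


@dataclass
class ArtifactScreenResult:
    """Template-correlation screen over component topographies."""

    correlations: np.ndarray
    flagged: np.ndarray
    threshold: float

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")


def design_bandpass(lo: float, hi: float, fs: float, order: int | None = None):
    """Windowed-sinc (Hamming) band-pass taps; odd length (linear phase).

    Default order scales with the low edge: 3 * fs / lo taps, which keeps
    the transition band a fixed fraction of the band's lower edge.
    """
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= fs / 2:
        raise ValueError(f"hi={hi} must be below Nyquist {fs / 2}")
    if order is None:
        order = int(round(3 * fs / lo))
    ntaps = order + 1 if order % 2 == 0 else order
    return signal.firwin(ntaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward application of a linear-phase FIR along axis -1.

    Each pass is a 'same'-mode FFT convolution after reflect padding, so
    the net response is |H(f)|^2 with zero phase and no edge blow-up.
    """
    taps = np.asarray(taps)
    n = x.shape[-1]
    pad = min(len(taps), n - 1)
    # odd (anti-symmetric) extension about the endpoints, as in filtfilt:
    # keeps the extended signal continuous so edge transients stay small
    left = 2 * x[..., :1] - x[..., 1 : pad + 1][..., ::-1]
    right = 2 * x[..., -1:] - x[..., -pad - 1 : -1][..., ::-1]
    xp = np.concatenate([left, x, right], axis=-1)
    shape = [1] * xp.ndim
    shape[-1] = len(taps)
    t = taps.reshape(shape)
    y = signal.fftconvolve(xp, t, mode="same", axes=-1)
    y = signal.fftconvolve(y[..., ::-1], t, mode="same", axes=-1)[..., ::-1]
    return y[..., pad : pad + n]


def bandpass_fir(
    trials: TrialSet, lo: float, hi: float, order: int | None = None
) -> TrialSet:
    """Zero-phase FIR band-pass of every trial; shape preserved."""
    taps = design_bandpass(lo, hi, trials.fs, order)
    out = trials.copy()
    out.data = zero_phase_fir(out.data, taps)
    return out


def downsample(trials: TrialSet, target_fs: float) -> TrialSet:
    """Polyphase anti-aliased resampling to ``target_fs``.

    A 4 s trial at 1024 Hz becomes 512 samples at 128 Hz.
    """
    if target_fs > trials.fs:
        raise ValueError(
            f"target_fs {target_fs} exceeds current fs {trials.fs}"
        )
    if target_fs == trials.fs:
        return trials.copy()
    frac = Fraction(target_fs / trials.fs).limit_denominator(1000)
    data = signal.resample_poly(trials.data, frac.numerator, frac.denominator, axis=-1)
    out = trials.copy()
    out.data = data
    out.fs = target_fs
    return out


def fit_ica(
    trials: TrialSet,
    n_components: int | None = None,
    seed: int = 0,
    decimate_factor: int = 3,
) -> ComponentSet:
    """FastICA on the subject's concatenated trials.

    The unmixing matrix is estimated on data decimated by
    ``decimate_factor`` (spatial filters are rate-independent; the
    decimation only speeds up the fit), then applied to the full-rate
    concatenation to produce sources.
    """
    n_ch = trials.n_channels
    if n_components is not None and n_components > n_ch:
        raise ValueError(
            f"n_components {n_components} exceeds channel count {n_ch}"
        )
    # channels x (trials * samples)
    x_full = np.transpose(trials.data, (1, 0, 2)).reshape(n_ch, -1)
    cov = np.cov(x_full)
    rank = int(np.linalg.matrix_rank(cov, tol=1e-10 * np.trace(cov) / n_ch))
    if n_components is None:
        # previously-removed components leave a rank-deficient subspace
        n_components = min(n_ch, rank)
    if rank < n_components:
        raise ValueError(
            f"rank-deficient data: covariance rank {rank} < "
            f"{n_components} requested components"
        )
    x_fit = (
        signal.decimate(x_full, decimate_factor, axis=-1)
        if decimate_factor > 1
        else x_full
    )
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=seed,
        max_iter=500,
        tol=1e-4,
    )
    ica.fit(x_fit.T)
    unmixing = ica.components_  # (components, channels)
    mean = ica.mean_
    sources = unmixing @ (x_full - mean[:, None])
    topographies = ica.mixing_  # (channels, components)
    return ComponentSet(
        unmixing=unmixing, sources=sources, topographies=topographies, mean=mean
    )


def screen_blink_components(
    components: ComponentSet, template: np.ndarray, threshold: float = 0.8
) -> ArtifactScreenResult:
    """Correlate each component map with a blink topography template.

    Components with |Pearson r| >= threshold are flagged (absolute value
    because ICA component signs are arbitrary).
    """
    template = np.asarray(template, dtype=float)
    if len(template) != components.topographies.shape[0]:
        raise ValueError(
            f"template length {len(template)} != channel count "
            f"{components.topographies.shape[0]}"
        )
    if np.std(template) == 0:
        raise ValueError("template has zero variance")
    corrs = np.empty(components.n_components)
    for i in range(components.n_components):
        topo = components.topographies[:, i]
        if np.std(topo) == 0:
            corrs[i] = 0.0
        else:
            corrs[i] = np.corrcoef(topo, template)[0, 1]
    flagged = np.flatnonzero(np.abs(corrs) >= threshold)
    return ArtifactScreenResult(
        correlations=corrs, flagged=flagged, threshold=threshold
    )


def remove_components(
    trials: TrialSet,
    components: ComponentSet,
    flagged: np.ndarray,
    override_keep: np.ndarray | None = None,
) -> TrialSet:
    """Zero flagged sources and remix back to channel space.

    ``override_keep`` lists flagged components to retain anyway (the
    non-interactive stand-in for a visual accept/reject step).
    """
    keep_back = set(np.atleast_1d(override_keep).tolist()) if override_keep is not None else set()
    drop = [i for i in np.atleast_1d(flagged) if i not in keep_back]
    out = trials.copy()
    if not drop:
        return out
    sources = components.sources.copy()
    sources[drop, :] = 0.0
    mixing = components.topographies  # (channels, components)
    x_clean = mixing @ sources + components.mean[:, None]
    out.data = x_clean.reshape(
        trials.n_channels, trials.n_trials, trials.n_samples
    ).transpose(1, 0, 2)
    return out


def clean_blinks(
    trials: TrialSet,
    template: np.ndarray,
    threshold: float = 0.8,
    seed: int = 0,
    override_keep: np.ndarray | None = None,
) -> tuple[TrialSet, ArtifactScreenResult]:
    """Fit ICA, screen topographies against ``template``, remove blinks."""
    comps = fit_ica(trials, seed=seed)
    screen = screen_blink_components(comps, template, threshold)
    cleaned = remove_components(trials, comps, screen.flagged, override_keep)
    return cleaned, screen
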