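"""The six imagined-speech decoders and their loss functions.

CNNs (shallow ConvNet, deep ConvNet, EEGNet) run on raw 6 x 512 trials
through the in-package numpy CNN engine, trained with ADAM at batch
size 64; the hyperparameter grid swaps the principal nonlinearity
(ELU / square / ReLU / leaky ReLU), learning rate, epoch count and loss
(NLL vs summed per-class binary cross-entropy).  Classical baselines:
SVM and random forest on relative wavelet energy vectors, and a
shrinkage-regularized LDA on FBCSP features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nn
from .features import (
    DEFAULT_FILTERBANK_EDGES,
    band_covariances,
    build_filterbank,
    fbcsp_features,
    fit_csp_bank,
)

__all__ = [
    "CNN_FAMILIES",
    "CLASSICAL_FAMILIES",
    "FAMILIES",
    "DEFAULT_GRIDS",
    "ALT_MIQL_GRID",
    "DecoderSpec",
    "TrainedDecoder",
    "PredictionBatch",
    "softmax",
    "nll_loss",
    "ce_loss",
    "build_cnn",
    "fit",
    "predict",
]

CNN_FAMILIES = ("shallow_cnn", "deep_cnn", "eegnet")
CLASSICAL_FAMILIES = ("svm", "rdf", "rlda")
FAMILIES = CNN_FAMILIES + CLASSICAL_FAMILIES

_CNN_GRID = {
    "activation": ["elu", "square", "relu", "leaky_relu"],
    "lr": [0.001, 0.01, 0.1, 1.0],
    "epochs": [20, 40, 60, 80],
    "loss": ["nll", "ce"],
}

#: Hyperparameter spaces searched by the nested cross-validation: 128
#: combinations for each CNN, 64 for each classical baseline.
DEFAULT_GRIDS = {
    "shallow_cnn": dict(_CNN_GRID),
    "deep_cnn": dict(_CNN_GRID),
    "eegnet": dict(_CNN_GRID),
    "svm": {
        "kernel": ["linear", "rbf", "poly", "sigmoid"],
        "C": [0.1, 1.0, 10.0, 100.0],
        "g": [0.01, 0.1, 1.0, 10.0],
    },
    "rdf": {
        "nof": [4, 5, 6, 7],
        "trees": [50, 100, 200, 500],
        "msl": [1, 2, 3, 4],
    },
    "rlda": {
        "nsf": [2, 3, 4, 5],
        "miql": [6, 8, 10, 12],
        "nof": [8, 10, 12, 14],
    },
}

#: Alternative quantization-level grid accepted via config.
ALT_MIQL_GRID = [2, 4, 6, 8]


@dataclass(frozen=True)
class DecoderSpec:
    """A decoder family plus one hyperparameter combination."""

    family: str
    hp: dict = field(default_factory=dict)
    n_classes: int = 6
    input_shape: tuple = (6, 512)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; valid: {list(FAMILIES)}"
            )
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        schema = set(DEFAULT_GRIDS[self.family])
        extra = set(self.hp) - schema
        if extra:
            raise ValueError(
                f"hyperparameters {sorted(extra)} not in the {self.family} "
                f"schema {sorted(schema)}"
            )

    def resolved_hp(self) -> dict:
        """hp with family defaults filled in (first grid value)."""
        out = {k: v[0] for k, v in DEFAULT_GRIDS[self.family].items()}
        out.update(self.hp)
        return out


@dataclass
class TrainedDecoder:
    spec: DecoderSpec
    model: object
    training_log: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def n_parameters(self) -> int | None:
        if hasattr(self.model, "n_parameters"):
            return self.model.n_parameters()
        return None


@dataclass
class PredictionBatch:
    probs: np.ndarray
    labels_hat: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Class probabilities exp(f_k) / sum_m exp(f_m), stabilized by
    max-subtraction; rows are trials."""
    logits = np.asarray(logits, dtype=float)
    if np.isnan(logits).any():
        raise ValueError("NaN in logits")
    squeeze = logits.ndim == 1
    if squeeze:
        logits = logits[None]
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def _true_probs(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12):
    p = probs[np.arange(len(y)), y]
    if np.any(p <= 0):
        warnings.warn(f"zero probability at true class clamped at {eps}")
    return np.maximum(p, eps)


def nll_loss(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean over the batch of -log p(true class)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.asarray(y, dtype=np.int64)
    return float(-np.mean(np.log(_true_probs(probs, y))))


def ce_loss(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean over trials of the summed per-class binary cross-entropy."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.asarray(y, dtype=np.int64)
    n, k = probs.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    if np.any(probs[onehot == 1] <= 0):
        warnings.warn(f"zero probability at true class clamped at {eps}")
    pc = np.clip(probs, eps, 1 - eps)
    return float(
        -np.mean(
            np.sum(onehot * np.log(pc) + (1 - onehot) * np.log(1 - pc), axis=1)
        )
    )


class ShrinkageLDA:
    """Regularized LDA: pooled within-class covariance shrunk toward a
    scaled identity with the analytic (Ledoit-Wolf) intensity.

    Linear scores s_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c
    with the shared shrunk covariance S; probabilities via softmax.
    Lean numpy implementation so thousands of grid-search fits stay
    cheap; agreement with the reference library implementation is
    asserted in the test suite.

    ``shrinkage``: None for the analytic Ledoit-Wolf intensity, or a
    fixed value in [0, 1].
    """

    def __init__(self, shrinkage: float | None = None):
        self.shrinkage = shrinkage

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, p = x.shape
        self.means_ = np.stack([x[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        z = x - self.means_[np.searchsorted(self.classes_, y)]
        s = z.T @ z / n
        mu = np.trace(s) / p
        if self.shrinkage is None:
            d2 = np.sum((s - mu * np.eye(p)) ** 2)
            b2 = np.sum((z**2).sum(axis=1) ** 2) / n**2 - np.sum(s**2) / n
            shrink = 1.0 if d2 == 0 else min(1.0, max(0.0, b2 / d2))
        else:
            shrink = float(self.shrinkage)
        self.shrinkage_ = shrink
        cov = (1 - shrink) * s + shrink * mu * np.eye(p)
        self.coef_ = np.linalg.solve(cov, self.means_.T).T
        self.intercept_ = (
            -0.5 * np.einsum("cp,cp->c", self.means_, self.coef_)
            + np.log(self.priors_)
        )
        return self

    def decision_function(self, x):
        return np.asarray(x, dtype=float) @ self.coef_.T + self.intercept_

    def predict(self, x):
        return self.classes_[self.decision_function(x).argmax(axis=1)]

    def predict_proba(self, x):
        return softmax(self.decision_function(x))

    @property
    def n_features_in_(self):
        return self.coef_.shape[1]


# ---------------------------------------------------------------------------
# CNN architectures.  Kernel sizes and filter counts follow the original
# shallow/deep ConvNet and EEGNet publications, scaled to 6 channels x
# 512 samples; all principal nonlinearities are replaced by the
# activation hyperparameter, and every dropout is 0.5.


def _shallow(n_ch, n_t, n_classes, act, rng):
    layers = [
        nn.Conv2d(1, 40, (1, 25), rng),
        nn.Conv2d(40, 40, (n_ch, 1), rng, bias=False),
        nn.BatchNorm2d(40),
        nn.Activation(act),
        nn.PoolTime(75, 15, "mean"),
        nn.LogAct(),
        nn.Dropout(0.5, rng),
        nn.Flatten(),
    ]
    t = n_t - 24
    t = (t - 75) // 15 + 1
    layers.append(nn.Dense(40 * t, n_classes, rng))
    return nn.Sequential(layers)


def _deep(n_ch, n_t, n_classes, act, rng):
    layers = [
        nn.Conv2d(1, 25, (1, 10), rng),
        nn.Conv2d(25, 25, (n_ch, 1), rng, bias=False),
        nn.BatchNorm2d(25),
        nn.Activation(act),
        nn.PoolTime(3, 3, "max"),
    ]
    t = (n_t - 9 - 3) // 3 + 1
    cin = 25
    for cout in (50, 100, 200):
        layers += [
            nn.Dropout(0.5, rng),
            nn.Conv2d(cin, cout, (1, 10), rng),
            nn.BatchNorm2d(cout),
            nn.Activation(act),
            nn.PoolTime(3, 3, "max"),
        ]
        t = (t - 9 - 3) // 3 + 1
        cin = cout
    layers += [nn.Flatten(), nn.Dense(cin * t, n_classes, rng)]
    return nn.Sequential(layers)


def _eegnet(n_ch, n_t, n_classes, act, rng, f1=8, d=2, f2=16):
    layers = [
        nn.Conv2d(1, f1, (1, 64), rng, bias=False, padding="same"),
        nn.BatchNorm2d(f1),
        nn.Conv2d(f1, f1 * d, (n_ch, 1), rng, groups=f1, bias=False),
        nn.BatchNorm2d(f1 * d),
        nn.Activation(act),
        nn.PoolTime(4, 4, "mean"),
        nn.Dropout(0.5, rng),
        # separable convolution: depthwise temporal then pointwise
        nn.Conv2d(f1 * d, f1 * d, (1, 16), rng, groups=f1 * d, bias=False,
                  padding="same"),
        nn.Conv2d(f1 * d, f2, (1, 1), rng, bias=False),
        nn.BatchNorm2d(f2),
        nn.Activation(act),
        nn.PoolTime(8, 8, "mean"),
        nn.Dropout(0.5, rng),
        nn.Flatten(),
    ]
    t = (n_t // 4) // 8
    layers.append(nn.Dense(f2 * t, n_classes, rng))
    return nn.Sequential(layers)


_BUILDERS = {"shallow_cnn": _shallow, "deep_cnn": _deep, "eegnet": _eegnet}


def build_cnn(spec: DecoderSpec, rng: np.random.Generator | int = 0) -> nn.Sequential:
    """Instantiate an untrained network for a CNN DecoderSpec."""
    if spec.family not in CNN_FAMILIES:
        raise ValueError(f"{spec.family!r} is not a CNN family")
    hp = spec.resolved_hp()
    if hp["activation"] not in nn.Activation.VALID:
        raise ValueError(
            f"unknown activation {hp['activation']!r}; valid: "
            f"{list(nn.Activation.VALID)}"
        )
    if hp["loss"] not in nn.LOSSES:
        raise ValueError(
            f"unknown loss {hp['loss']!r}; valid: {list(nn.LOSSES)}"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_ch, n_t = spec.input_shape
    return _BUILDERS[spec.family](n_ch, n_t, spec.n_classes, hp["activation"], rng)


def zscore_trials(x: np.ndarray) -> np.ndarray:
    """Per-trial, per-channel standardization of raw (N, C, T) trials."""
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _fit_cnn(spec, x, y, seed, batch_size=64):
    rng = np.random.default_rng(seed)
    hp = spec.resolved_hp()
    net = build_cnn(spec, rng)
    x = zscore_trials(np.asarray(x, dtype=np.float64))[:, None, :, :]
    y = np.asarray(y, dtype=np.int64)
    opt = nn.Adam(net.params(), lr=hp["lr"])
    loss_fn = nn.LOSSES[hp["loss"]]
    log = []
    n = len(y)
    for epoch in range(hp["epochs"]):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            net.zero_grad()
            logits = net.forward(x[idx], training=True)
            loss, dlogits = loss_fn(logits, y[idx])
            if not np.isfinite(loss):
                raise nn.DivergenceError(
                    f"non-finite loss at epoch {epoch} ({spec.family}, hp={hp})"
                )
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        log.append({"epoch": epoch, "loss": ep_loss / n, "acc": ep_correct / n})
        if not all(np.isfinite(p).all() for p, _ in net.params()):
            raise nn.DivergenceError(
                f"non-finite parameters at epoch {epoch} ({spec.family})"
            )
    return TrainedDecoder(spec=spec, model=net, training_log=log)


def _fit_classical(spec, x, y, seed):
    hp = spec.resolved_hp()
    if spec.family == "svm":
        model = SVC(
            kernel=hp["kernel"],
            C=hp["C"],
            gamma=hp["g"],
            probability=True,
            random_state=seed,
        )
    elif spec.family == "rdf":
        model = RandomForestClassifier(
            n_estimators=hp["trees"],
            max_features=min(hp["nof"], np.shape(x)[1]),
            min_samples_leaf=hp["msl"],
            random_state=seed,
        )
    else:  # rlda: shrinkage toward scaled identity, analytic intensity
        model = ShrinkageLDA()
    model.fit(np.asarray(x), np.asarray(y, dtype=np.int64))
    return TrainedDecoder(spec=spec, model=model)


class FBCSPRLDA:
    """The rLDA decoder behind the FBCSP feature pipeline.

    Fits the filter bank CSP + MI selection on training trials only,
    then a shrinkage LDA on the selected log-variance features.
    """

    def __init__(self, nsf, miql, nof, edges=DEFAULT_FILTERBANK_EDGES, fs=128.0):
        self.nsf, self.miql, self.nof = nsf, miql, nof
        self.edges, self.fs = edges, fs

    def fit(self, data, y):
        bank = build_filterbank(
            self.edges, self.fs, max_taps=max(8, data.shape[-1] // 3 - 2)
        )
        covs = band_covariances(data, bank)
        return self.fit_covs(covs, y)

    def fit_covs(self, covs, y):
        self.csp = fit_csp_bank(covs, y, self.nsf, self.edges)
        feats, self.selection = fbcsp_features(
            covs, self.csp, y, np.arange(len(y)), self.miql, self.nof
        )
        self.lda = ShrinkageLDA().fit(feats, y)
        self._bank_cache = None
        return self

    def transform_covs(self, covs):
        from .features import csp_log_variance

        return csp_log_variance(covs, self.csp)[:, self.selection.selected]

    def predict_proba(self, data):
        bank = build_filterbank(
            self.edges, self.fs, max_taps=max(8, data.shape[-1] // 3 - 2)
        )
        covs = band_covariances(data, bank)
        return self.lda.predict_proba(self.transform_covs(covs))


def fit(spec: DecoderSpec, x, y, seed: int = 0) -> TrainedDecoder:
    """Train a decoder of any family.

    CNNs receive raw (N, C, T) trials; svm/rdf receive feature matrices
    (RWE vectors); rlda receives raw trials and fits its own FBCSP
    front end.  Deterministic given ``seed``.
    """
    if spec.family in CNN_FAMILIES:
        return _fit_cnn(spec, x, y, seed)
    if spec.family == "rlda":
        hp = spec.resolved_hp()
        model = FBCSPRLDA(hp["nsf"], hp["miql"], hp["nof"]).fit(
            np.asarray(x), np.asarray(y, dtype=np.int64)
        )
        return TrainedDecoder(spec=spec, model=model)
    return _fit_classical(spec, x, y, seed)


def predict(trained: TrainedDecoder, x) -> PredictionBatch:
    """Per-trial class probabilities and argmax labels."""
    x = np.asarray(x)
    spec = trained.spec
    if spec.family in CNN_FAMILIES:
        if x.shape[1:] != tuple(spec.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} != expected {spec.input_shape}"
            )
        xz = zscore_trials(x.astype(np.float64))[:, None, :, :]
        logits = trained.model.forward(xz, training=False)
        probs = softmax(logits)
    elif spec.family == "rlda":
        probs = trained.model.predict_proba(x)
    else:
        if x.ndim != 2 or x.shape[1] != trained.model.n_features_in_:
            raise ValueError(
                f"feature matrix shape {x.shape} does not match fitted model"
            )
        probs = trained.model.predict_proba(x)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PredictionBatch(probs=probs, labels_hat=probs.argmax(axis=1))
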