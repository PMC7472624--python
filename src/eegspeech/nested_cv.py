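"""Nested k-fold cross-validation with exhaustive grid search.

The procedure: split the trials into k stratified outer folds; for each
outer fold, concatenate the remaining k-1 folds and re-partition them
into k stratified inner folds; record a validation accuracy for every
hyperparameter combination on every inner fold; average inner-fold
accuracies (aggregated across all outer folds) per combination and take
the argmax as theta*; finally train on each outer training set with
theta* and report the mean outer test accuracy.

Two selection modes: intra-subject (theta* chosen per subject) and
inter-subject (one theta* from inner-fold accuracies pooled across
subjects).  Failed or diverged fits score 0 so the grid stays total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import decoders
from .decoders import DecoderSpec
from .features import build_filterbank, band_covariances, rwe_extract
from .synthetic import TrialSet

__all__ = [
    "HyperparameterGrid",
    "FoldPlan",
    "CVResult",
    "enumerate_grid",
    "make_folds",
    "inner_search",
    "select_theta_star",
    "run_ncv",
    "run_intra_subject",
    "run_inter_subject",
]


@dataclass(frozen=True)
class HyperparameterGrid:
    """Named dimensions of allowed values for one decoder family."""

    family: str
    dimensions: dict

    def __post_init__(self):
        for name, values in self.dimensions.items():
            if len(values) == 0:
                raise ValueError(f"grid dimension {name!r} is empty")

    @classmethod
    def default(cls, family: str) -> "HyperparameterGrid":
        return cls(family=family, dimensions=decoders.DEFAULT_GRIDS[family])

    @property
    def n_combinations(self) -> int:
        return int(np.prod([len(v) for v in self.dimensions.values()]))


def enumerate_grid(grid: HyperparameterGrid) -> list[dict]:
    """All combinations in lexicographic order over dimensions as
    declared; length equals the product of dimension sizes."""
    names = list(grid.dimensions)
    if not names:
        raise ValueError("grid has no dimensions")
    combos = []
    for values in itertools.product(*(grid.dimensions[n] for n in names)):
        combos.append(dict(zip(names, values)))
    return combos


@dataclass
class FoldPlan:
    """Stratified outer folds plus per-outer-fold inner partitions.

    outer_assignments: (n_trials,) outer fold index of each trial.
    inner_assignments: (k, n_trials); row i gives the inner fold index
    of each trial in outer training set i, and -1 for the held-out
    outer test trials.
    """

    k: int
    outer_assignments: np.ndarray
    inner_assignments: np.ndarray
    seed: int

    def outer_split(self, i: int):
        test = np.flatnonzero(self.outer_assignments == i)
        train = np.flatnonzero(self.outer_assignments != i)
        return train, test

    def inner_split(self, outer: int, inner: int):
        a = self.inner_assignments[outer]
        val = np.flatnonzero(a == inner)
        train = np.flatnonzero((a >= 0) & (a != inner))
        return train, val


def make_folds(trials: TrialSet | np.ndarray, k: int, seed: int = 0) -> FoldPlan:
    """Stratified nested fold plan; with k = 4 each outer fold is 75%
    train / 25% test and each inner split 75% train / 25% validation."""
    y = trials.labels if isinstance(trials, TrialSet) else np.asarray(trials)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < k:
            raise ValueError(f"class {c!r} has {n} trials, fewer than k={k}")
    n = len(y)
    outer = np.empty(n, dtype=np.int64)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for i, (_, test) in enumerate(skf.split(np.zeros(n), y)):
        outer[test] = i
    inner = np.full((k, n), -1, dtype=np.int64)
    for i in range(k):
        train = np.flatnonzero(outer != i)
        y_tr = y[train]
        cls, cnt = np.unique(y_tr, return_counts=True)
        for c, m in zip(cls, cnt):
            if m < k:
                raise ValueError(
                    f"class {c!r} has {m} trials in outer training set {i}, "
                    f"fewer than the {k} inner folds"
                )
        # inner folds re-seeded deterministically from (outer index, seed)
        skf_i = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=(seed * 1000 + i) % (2**31)
        )
        for j, (_, val) in enumerate(skf_i.split(np.zeros(len(train)), y_tr)):
            inner[i, train[val]] = j
    return FoldPlan(k=k, outer_assignments=outer, inner_assignments=inner, seed=seed)


@dataclass
class CVResult:
    """Everything the nested CV produces for one subject/task/family."""

    family: str
    mode: str
    subject_id: str
    inner_table: dict  # (outer, inner, combo_index) -> accuracy
    mean_acc: np.ndarray  # per combo, mean over all inner folds
    theta_star: dict
    theta_star_index: int
    outer_accs: np.ndarray
    mean_test_acc: float
    precision_per_class: np.ndarray
    macro_precision: float
    combos: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Per-family evaluators: prepare trial representations once, then score
# (train, test, theta) splits.  Feature fitting that depends on labels
# (CSP, MI selection) happens inside the training split only.


class _Evaluator:
    def __init__(self, trials: TrialSet, family: str, classes: np.ndarray):
        self.family = family
        self.classes = classes
        self.y = trials.encoded_labels(classes)
        self.n_classes = len(classes)
        if family in ("svm", "rdf"):
            self.x = rwe_extract(trials)
        elif family == "rlda":
            bank = build_filterbank(
                fs=trials.fs, max_taps=max(8, trials.n_samples // 3 - 2)
            )
            self.covs = band_covariances(trials, bank)
        else:
            self.x = trials.data
            self.input_shape = (trials.n_channels, trials.n_samples)

    def _spec(self, theta):
        shape = getattr(self, "input_shape", (6, 512))
        return DecoderSpec(
            family=self.family, hp=theta, n_classes=self.n_classes,
            input_shape=shape,
        )

    def eval_grid(self, combos, train, val, seed):
        """Validation accuracy of every combination on one split."""
        if self.family == "rlda":
            return self._eval_grid_rlda(combos, train, val)
        accs = np.zeros(len(combos))
        for t, theta in enumerate(combos):
            accs[t] = self.evaluate(theta, train, val, seed)[0]
        return accs

    def _eval_grid_rlda(self, combos, train, val):
        from .decoders import ShrinkageLDA
        from .features import csp_log_variance, fit_csp_bank, select_features

        y_tr = self.y[train]
        cand_cache, rank_cache = {}, {}
        accs = np.zeros(len(combos))
        for t, theta in enumerate(combos):
            nsf, miql, nof = theta["nsf"], theta["miql"], theta["nof"]
            try:
                if nsf not in cand_cache:
                    csp = fit_csp_bank(self.covs[train], y_tr, nsf)
                    cand_cache[nsf] = csp_log_variance(self.covs, csp)
                cand = cand_cache[nsf]
                if (nsf, miql) not in rank_cache:
                    rank_cache[(nsf, miql)] = select_features(
                        cand[train], y_tr, miql, cand.shape[1]
                    )
                sel = rank_cache[(nsf, miql)].selected[:nof]
                lda = ShrinkageLDA().fit(cand[np.ix_(train, sel)], y_tr)
                yhat = lda.predict(cand[np.ix_(val, sel)])
                accs[t] = float(np.mean(yhat == self.y[val]))
            except Exception:
                accs[t] = 0.0
        return accs

    def evaluate(self, theta, train, test, seed):
        """(accuracy, predicted labels) of one combination on one split;
        failures score 0."""
        y_te = self.y[test]
        try:
            if self.family == "rlda":
                from .decoders import ShrinkageLDA
                from .features import (
                    csp_log_variance,
                    fit_csp_bank,
                    select_features,
                )

                csp = fit_csp_bank(self.covs[train], self.y[train], theta["nsf"])
                cand = csp_log_variance(self.covs, csp)
                sel = select_features(
                    cand[train], self.y[train], theta["miql"], cand.shape[1]
                ).selected[: theta["nof"]]
                lda = ShrinkageLDA().fit(cand[np.ix_(train, sel)], self.y[train])
                yhat = lda.predict(cand[np.ix_(test, sel)])
            else:
                trained = decoders.fit(
                    self._spec(theta), self.x[train], self.y[train], seed
                )
                yhat = decoders.predict(trained, self.x[test]).labels_hat
            return float(np.mean(yhat == y_te)), yhat
        except Exception:
            return 0.0, np.full(len(test), -1, dtype=np.int64)


def inner_search(
    trials: TrialSet,
    plan: FoldPlan,
    grid: HyperparameterGrid,
    family: str | None = None,
    seed: int = 0,
    classes: np.ndarray | None = None,
    evaluator: "_Evaluator | None" = None,
) -> tuple[dict, np.ndarray]:
    """Inner-fold validation accuracies for every combination.

    Returns (inner_table, mean_acc): the table maps (outer fold, inner
    fold, combo index) to validation accuracy; mean_acc averages over
    all k x k inner evaluations per combination.
    """
    family = family or grid.family
    classes = classes if classes is not None else trials.classes()
    combos = enumerate_grid(grid)
    ev = evaluator if evaluator is not None else _Evaluator(
        trials, family, np.asarray(classes)
    )
    table = {}
    sums = np.zeros(len(combos))
    count = 0
    for i in range(plan.k):
        for j in range(plan.k):
            train, val = plan.inner_split(i, j)
            fold_seed = (seed * 10007 + i * 101 + j) % (2**31)
            accs = ev.eval_grid(combos, train, val, fold_seed)
            for t in range(len(combos)):
                table[(i, j, t)] = accs[t]
            sums += accs
            count += 1
    return table, sums / count


def select_theta_star(mean_acc: np.ndarray) -> int:
    """Index of the highest mean accuracy; ties go to the earliest
    combination in enumeration order."""
    mean_acc = np.asarray(mean_acc)
    if mean_acc.size == 0:
        raise ValueError("empty accuracy table")
    return int(np.argmax(mean_acc))


def _outer_evaluate(ev, plan, theta, seed):
    """Train with theta on each outer training set; test accuracies plus
    pooled per-class precision."""
    n_classes = ev.n_classes
    accs = np.zeros(plan.k)
    tp = np.zeros(n_classes)
    pred_pos = np.zeros(n_classes)
    for i in range(plan.k):
        train, test = plan.outer_split(i)
        fold_seed = (seed * 7919 + i) % (2**31)
        accs[i], yhat = ev.evaluate(theta, train, test, fold_seed)
        for c in range(n_classes):
            pred_pos[c] += np.sum(yhat == c)
            tp[c] += np.sum((yhat == c) & (ev.y[test] == c))
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_pos > 0, tp / pred_pos, np.nan)
    macro = float(np.nanmean(prec)) if np.any(pred_pos > 0) else float("nan")
    return accs, prec, macro


def run_ncv(
    trials: TrialSet,
    grid: HyperparameterGrid,
    family: str | None = None,
    k: int = 4,
    seed: int = 0,
    mode: str = "intra",
    theta_star_index: int | None = None,
    classes: np.ndarray | None = None,
) -> CVResult:
    """Full nested CV for one subject.

    If ``theta_star_index`` is given (inter-subject mode), the inner
    search result is still recorded but the supplied combination is used
    for the outer evaluation.
    """
    family = family or grid.family
    classes = np.asarray(classes if classes is not None else trials.classes())
    plan = make_folds(trials, k, seed)
    combos = enumerate_grid(grid)
    ev = _Evaluator(trials, family, classes)
    table, mean_acc = inner_search(
        trials, plan, grid, family, seed, classes, evaluator=ev
    )
    idx = theta_star_index if theta_star_index is not None else select_theta_star(
        mean_acc
    )
    accs, prec, macro = _outer_evaluate(ev, plan, combos[idx], seed)
    return CVResult(
        family=family,
        mode=mode,
        subject_id=trials.subject_id,
        inner_table=table,
        mean_acc=mean_acc,
        theta_star=combos[idx],
        theta_star_index=idx,
        outer_accs=accs,
        mean_test_acc=float(accs.mean()),
        precision_per_class=prec,
        macro_precision=macro,
        combos=combos,
    )


def _common_classes(dataset: list[TrialSet]) -> np.ndarray:
    classes = dataset[0].classes()
    for t in dataset[1:]:
        if not np.array_equal(t.classes(), classes):
            raise ValueError("subjects have differing class sets")
    return classes


def run_intra_subject(
    dataset: list[TrialSet],
    grid: HyperparameterGrid,
    family: str | None = None,
    k: int = 4,
    seed: int = 0,
) -> dict[str, CVResult]:
    """theta* selected independently per subject from that subject's
    inner folds."""
    classes = _common_classes(dataset)
    return {
        t.subject_id: run_ncv(
            t, grid, family, k, seed=(seed + s) % (2**31), mode="intra",
            classes=classes,
        )
        for s, t in enumerate(dataset)
    }


def run_inter_subject(
    dataset: list[TrialSet],
    grid: HyperparameterGrid,
    family: str | None = None,
    k: int = 4,
    seed: int = 0,
) -> dict[str, CVResult]:
    """One theta* from the across-subject mean of inner-fold validation
    accuracies, then per-subject outer evaluation with that shared
    combination."""
    family = family or grid.family
    classes = _common_classes(dataset)
    combos = enumerate_grid(grid)
    searches = []
    for s, t in enumerate(dataset):
        sub_seed = (seed + s) % (2**31)
        plan = make_folds(t, k, sub_seed)
        ev = _Evaluator(t, family, classes)
        table, mean_acc = inner_search(
            t, plan, grid, family, sub_seed, classes, evaluator=ev
        )
        searches.append((t, sub_seed, plan, ev, table, mean_acc))
    pooled = np.mean([m for *_, m in searches], axis=0)
    idx = select_theta_star(pooled)
    out = {}
    for t, sub_seed, plan, ev, table, mean_acc in searches:
        accs, prec, macro = _outer_evaluate(ev, plan, combos[idx], sub_seed)
        out[t.subject_id] = CVResult(
            family=family,
            mode="inter",
            subject_id=t.subject_id,
            inner_table=table,
            mean_acc=mean_acc,
            theta_star=combos[idx],
            theta_star_index=idx,
            outer_accs=accs,
            mean_test_acc=float(accs.mean()),
            precision_per_class=prec,
            macro_precision=macro,
            combos=combos,
        )
    return out
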