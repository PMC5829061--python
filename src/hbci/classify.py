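"""Shrinkage-LDA classification, modality fusion and cross-validation.

The ternary problem (MA / MI / IS) is decomposed one-versus-one into three
binary problems.  Per binary problem, an EEG base classifier (shrinkage
LDA on filter-bank CSP log-variance features) and a NIRS base classifier
(shrinkage LDA on temporal-mean hemoglobin features) each produce a
continuous decision value; a meta shrinkage-LDA on the stacked
2-dimensional decision vector fuses the modalities.  The final class is
chosen by majority voting over the three binary decisions, with the 1-1-1
cycle broken by the largest absolute decision value.

Shrinkage LDA replaces the empirical covariance S with
``(1 - lambda) S + lambda * nu * I`` where lambda is the analytic
Ledoit-Wolf / Schaefer-Strimmer shrinkage intensity and nu the mean
diagonal of S (the scaled-identity target keeps the regularizer on the
data's own scale; for standardized features it reduces to the plain
identity target, which is also available literally via
``literal_identity=True``).

Evaluation is a label-stratified, repeated k-fold cross-validation
(default 10 x 10-fold).  Nothing computed from a test fold — CSP
covariances, shrinkage intensities, class means, standardization spreads —
ever enters a fitted parameter: meta-classifiers are trained on decision
values produced by an inner cross-validation within the training fold, so
they never see resubstitution-optimistic base outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .data import CLASSES, EpochSet
from .features import (
    FeatureMatrix,
    bandpass_epochs,
    csp_fit_covariances,
    csp_select,
    logvar_features,
    nirs_mean_features,
    task_covariances,
)

__all__ = [
    "BINARY_PROBLEMS",
    "BinaryProblem",
    "ShrinkageLDAModel",
    "MetaModel",
    "CVResult",
    "slda_fit",
    "slda_decision",
    "meta_fit",
    "meta_decision",
    "majority_vote",
    "crossvalidate",
]


@dataclass(frozen=True)
class BinaryProblem:
    """One unordered class pair; decision values > 0 vote ``positive``."""

    positive: str
    negative: str

    @property
    def id(self) -> str:
        return f"{self.positive}-vs-{self.negative}"


#: the three binary problems of the one-versus-one decomposition
BINARY_PROBLEMS = (
    BinaryProblem("MA", "MI"),
    BinaryProblem("MA", "IS"),
    BinaryProblem("MI", "IS"),
)


# ---------------------------------------------------------------------------
# shrinkage LDA
# ---------------------------------------------------------------------------

@dataclass
class ShrinkageLDAModel:
    """Linear discriminant with analytically shrunken covariance."""

    w: np.ndarray
    b: float
    lam: float
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    positive: str
    negative: str

    @property
    def n_features(self) -> int:
        return len(self.w)


def _shrinkage_intensity(Xc: np.ndarray, nu_target: bool) -> tuple[float, np.ndarray, float]:
    """Schaefer-Strimmer analytic shrinkage toward nu*I (or I).

    ``Xc`` holds class-centered observations (rows).  Returns (lambda, S,
    nu) with S the unbiased pooled covariance.
    """
    n, d = Xc.shape
    S = Xc.T @ Xc / (n - 1)
    nu = float(np.trace(S)) / d if nu_target else 1.0
    # variance of the entries of S from the per-observation products
    prods = Xc[:, :, None] * Xc[:, None, :]
    var_S = n / (n - 1) ** 3 * ((prods - prods.mean(axis=0)) ** 2).sum(axis=0)
    target = nu * np.eye(d)
    denom = float(((S - target) ** 2).sum())
    if denom <= 0:
        return 1.0, S, nu
    lam = float(np.clip(var_S.sum() / denom, 0.0, 1.0))
    return lam, S, nu


def slda_fit(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    positive: str | None = None,
    lam: float | None = None,
    literal_identity: bool = False,
) -> ShrinkageLDAModel:
    """Fit a binary shrinkage-LDA.

    ``lam`` forces a shrinkage intensity in [0, 1]; by default it is
    estimated analytically from the training data.  ``positive`` names the
    class mapped to positive decision values (default: first label in
    sorted order).
    """
    if isinstance(X, FeatureMatrix):
        y = X.labels if y is None else y
        X = X.data
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be trials x features with one label per trial")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValueError(f"binary LDA needs exactly 2 classes, got {classes}")
    if positive is None:
        positive = classes[0]
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not in labels")
    negative = classes[0] if classes[1] == positive else classes[1]

    Xp, Xn = X[y == positive], X[y == negative]
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    Xc = np.vstack([Xp - mu_p, Xn - mu_n])

    if lam is None:
        lam_hat, S, nu = _shrinkage_intensity(Xc, nu_target=not literal_identity)
    else:
        if not 0 <= lam <= 1:
            raise ValueError("lam must lie in [0, 1]")
        n = Xc.shape[0]
        S = Xc.T @ Xc / (n - 1)
        nu = 1.0 if literal_identity else float(np.trace(S)) / X.shape[1]
        lam_hat = float(lam)

    sigma = (1.0 - lam_hat) * S + lam_hat * nu * np.eye(X.shape[1])
    w = np.linalg.solve(sigma, mu_p - mu_n)
    b = -0.5 * float(w @ (mu_p + mu_n))
    return ShrinkageLDAModel(
        w=w, b=b, lam=lam_hat, mean_pos=mu_p, mean_neg=mu_n,
        positive=positive, negative=negative,
    )


def slda_decision(model: ShrinkageLDAModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Signed continuous decision values; sign picks the class, magnitude
    carries confidence (the meta-feature)."""
    if isinstance(X, FeatureMatrix):
        X = X.data
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    return X @ model.w + model.b


# ---------------------------------------------------------------------------
# meta-classification (stacking)
# ---------------------------------------------------------------------------

@dataclass
class MetaModel:
    """Fusion sLDA over standardized (EEG, NIRS) base decision values."""

    slda: ShrinkageLDAModel
    eeg_scale: float
    nirs_scale: float


def meta_fit(
    eeg_decisions: np.ndarray,
    nirs_decisions: np.ndarray,
    y: np.ndarray,
    positive: str | None = None,
) -> MetaModel:
    """Fit the meta-classifier on stacked base decision values.

    Each modality's decisions are standardized by their training spread so
    neither modality dominates by raw magnitude.  The inputs must be
    leakage-free (inner-cross-validated) decisions for the training trials.
    """
    eeg_decisions = np.asarray(eeg_decisions, dtype=np.float64)
    nirs_decisions = np.asarray(nirs_decisions, dtype=np.float64)
    if eeg_decisions.shape != nirs_decisions.shape or eeg_decisions.ndim != 1:
        raise ValueError("decision vectors must be 1-D and aligned by trial")
    if len(y) != len(eeg_decisions):
        raise ValueError("labels must align with decisions")
    se = float(eeg_decisions.std()) or 1.0
    sn = float(nirs_decisions.std()) or 1.0
    X = np.column_stack([eeg_decisions / se, nirs_decisions / sn])
    return MetaModel(slda=slda_fit(X, np.asarray(y), positive=positive),
                     eeg_scale=se, nirs_scale=sn)


def meta_decision(model: MetaModel, eeg_decisions: np.ndarray,
                  nirs_decisions: np.ndarray) -> np.ndarray:
    X = np.column_stack([
        np.asarray(eeg_decisions, dtype=np.float64) / model.eeg_scale,
        np.asarray(nirs_decisions, dtype=np.float64) / model.nirs_scale,
    ])
    return slda_decision(model.slda, X)


def majority_vote(votes, confidences) -> str:
    """Final class from the three binary votes.

    A class with at least two votes wins.  In the 1-1-1 cycle (each class
    backed by one vote) the vote with the largest absolute decision value
    wins; remaining ties break on the fixed binary-problem order.
    """
    votes = list(votes)
    confidences = np.abs(np.asarray(confidences, dtype=np.float64))
    if len(votes) != len(confidences):
        raise ValueError("one confidence per vote required")
    labels, counts = np.unique(votes, return_counts=True)
    if counts.max() >= 2:
        return str(labels[np.argmax(counts)])
    return votes[int(np.argmax(confidences))]


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Confusion matrices per repetition and fold, per modality.

    ``confusion[modality]`` has shape (repetitions, folds, 3, 3) with rows
    = true class, columns = predicted, in ``class_order``.
    """

    confusion: dict[str, np.ndarray]
    class_order: tuple[str, ...] = CLASSES

    def accuracies(self, modality: str) -> np.ndarray:
        """Fold-pooled accuracy per repetition."""
        conf = self.confusion[modality]
        pooled = conf.sum(axis=1)  # reps x 3 x 3
        return np.trace(pooled, axis1=1, axis2=2) / pooled.sum(axis=(1, 2))

    def mean_accuracy(self, modality: str) -> float:
        return float(self.accuracies(modality).mean())


def stratified_folds(labels: np.ndarray, k: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Label-stratified fold assignment: per-class seeded shuffle, then
    round-robin so each fold receives an equal share of every class."""
    labels = np.asarray(labels)
    counts = {c: int((labels == c).sum()) for c in set(labels.tolist())}
    smallest = min(counts.values())
    if k > smallest:
        raise ValueError(
            f"k={k} exceeds the smallest class count ({smallest})"
        )
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in sorted(counts):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        for f in range(k):
            folds[f].extend(idx[f::k].tolist())
    return [np.sort(np.array(f)) for f in folds]


class _EEGBase:
    """Per-problem FBCSP + sLDA base classifier over cached covariances."""

    def __init__(self, covs_norm, covs_raw, train_idx, y, problem,
                 cfg: PipelineConfig):
        self.problem = problem
        self.filters = []
        pos_idx = train_idx[y[train_idx] == problem.positive]
        neg_idx = train_idx[y[train_idx] == problem.negative]
        for b in range(len(covs_norm)):
            flt = csp_fit_covariances(
                covs_norm[b][pos_idx].mean(axis=0),
                covs_norm[b][neg_idx].mean(axis=0),
                problem=problem.id,
            )
            self.filters.append(csp_select(flt, cfg.n_csp_first, cfg.n_csp_last))
        X = self.features(covs_raw, np.concatenate([pos_idx, neg_idx]))
        self.slda = slda_fit(
            X, y[np.concatenate([pos_idx, neg_idx])],
            positive=problem.positive,
            literal_identity=cfg.shrinkage_identity_literal,
        )

    def features(self, covs_raw, idx) -> np.ndarray:
        return np.hstack([
            logvar_features(covs_raw[b][idx], self.filters[b].filters)
            for b in range(len(covs_raw))
        ])

    def decisions(self, covs_raw, idx) -> np.ndarray:
        return slda_decision(self.slda, self.features(covs_raw, idx))


class _NIRSBase:
    """Per-problem sLDA on precomputed NIRS temporal-mean features."""

    def __init__(self, F, train_idx, y, problem, cfg: PipelineConfig):
        pair = train_idx[np.isin(y[train_idx], [problem.positive, problem.negative])]
        self.slda = slda_fit(
            F[pair], y[pair], positive=problem.positive,
            literal_identity=cfg.shrinkage_identity_literal,
        )
        self.F = F

    def decisions(self, idx) -> np.ndarray:
        return slda_decision(self.slda, self.F[idx])


def _vote_predictions(decisions_per_problem: list[np.ndarray]) -> list[str]:
    """OVO majority vote per test trial from three decision-value arrays."""
    n = len(decisions_per_problem[0])
    out = []
    for t in range(n):
        votes = [
            (p.positive if decisions_per_problem[j][t] > 0 else p.negative)
            for j, p in enumerate(BINARY_PROBLEMS)
        ]
        confs = [decisions_per_problem[j][t] for j in range(3)]
        out.append(majority_vote(votes, confs))
    return out


def crossvalidate(
    eeg_epochs: EpochSet,
    nirs_epochs: EpochSet,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> CVResult:
    """Repeated stratified k-fold evaluation of EEG-only, NIRS-only and
    hybrid (meta-fused) ternary decoding.

    ``eeg_epochs`` are broadband EEG epochs (band filtering happens inside,
    per bank band); ``nirs_epochs`` are baseline-corrected hemoglobin
    epochs.  Trials must be aligned across modalities.  Deterministic for
    a fixed seed.
    """
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    y = np.asarray(eeg_epochs.labels)
    if eeg_epochs.n_trials != nirs_epochs.n_trials:
        raise ValueError("EEG and NIRS epoch counts differ")
    if not np.array_equal(y, np.asarray(nirs_epochs.labels)):
        raise ValueError("EEG and NIRS trial labels are not aligned")

    # fold-independent per-trial statistics (band-filtered task covariances
    # and NIRS window means are per-trial quantities; training-set averaging
    # happens inside each fold)
    covs_norm, covs_raw = [], []
    for spec in cfg.filter_bank:
        band_ep = bandpass_epochs(eeg_epochs, spec)
        raw = task_covariances(band_ep, cfg.task_window, normalize=False)
        traces = np.trace(raw, axis1=1, axis2=2)
        covs_raw.append(raw)
        covs_norm.append(raw / traces[:, None, None])
    F_nirs = nirs_mean_features(nirs_epochs, cfg.nirs_windows).data

    n_classes = len(CLASSES)
    class_pos = {c: i for i, c in enumerate(CLASSES)}
    shape = (cfg.repetitions, cfg.folds, n_classes, n_classes)
    confusion = {m: np.zeros(shape) for m in ("eeg", "nirs", "hybrid")}

    master = np.random.default_rng(seed)
    for rep in range(cfg.repetitions):
        rep_rng = np.random.default_rng(master.integers(2**31))
        folds = stratified_folds(y, cfg.folds, rep_rng)
        all_idx = np.arange(len(y))
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            dec = {m: [] for m in ("eeg", "nirs", "hybrid")}
            for problem in BINARY_PROBLEMS:
                eeg_base = _EEGBase(covs_norm, covs_raw, train_idx, y,
                                    problem, cfg)
                nirs_base = _NIRSBase(F_nirs, train_idx, y, problem, cfg)
                pair_train = train_idx[
                    np.isin(y[train_idx], [problem.positive, problem.negative])
                ]
                # inner CV: leakage-free base decisions for meta training
                inner_rng = np.random.default_rng(rep_rng.integers(2**31))
                inner = stratified_folds(y[pair_train], cfg.inner_folds,
                                         inner_rng)
                de = np.empty(len(pair_train))
                dn = np.empty(len(pair_train))
                for hold in inner:
                    fit_local = np.setdiff1d(np.arange(len(pair_train)), hold)
                    fit_idx = pair_train[fit_local]
                    hold_idx = pair_train[hold]
                    eb = _EEGBase(covs_norm, covs_raw, fit_idx, y, problem, cfg)
                    nb = _NIRSBase(F_nirs, fit_idx, y, problem, cfg)
                    de[hold] = eb.decisions(covs_raw, hold_idx)
                    dn[hold] = nb.decisions(hold_idx)
                meta = meta_fit(de, dn, y[pair_train],
                                positive=problem.positive)

                d_eeg = eeg_base.decisions(covs_raw, test_idx)
                d_nirs = nirs_base.decisions(test_idx)
                dec["eeg"].append(d_eeg)
                dec["nirs"].append(d_nirs)
                dec["hybrid"].append(meta_decision(meta, d_eeg, d_nirs))

            for modality in ("eeg", "nirs", "hybrid"):
                preds = _vote_predictions(dec[modality])
                for t, pred in zip(test_idx, preds):
                    confusion[modality][rep, f,
                                        class_pos[y[t]], class_pos[pred]] += 1

    return CVResult(confusion=confusion)
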