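"""Aquaphotomics chemometrics: water band, MSC, PCA, PLS-DA.

The pipeline follows the standard NIR workflow for classifying thallus
spectra from the water spectral pattern:

1. restrict to the first overtone of the OH stretching vibrations
   (1300-1600 nm, 301 variables at 1 nm);
2. multiplicative scatter correction (MSC): regress each spectrum on a
   reference (the mean training spectrum), ``x = a + b * ref``, and invert
   the affine distortion, ``x_corrected = (x - a) / b``;
3. mean-centre with the training column means;
4. PCA for display, PLS-DA for classification. PLS-DA regresses a one-hot
   class-membership matrix Y on the spectra via sequentially extracted
   latent variables (NIPALS), assigns each sample to the class with maximal
   predicted score, and selects the number of latent variables by k-fold
   cross-validation minimizing the mean per-class balanced error
   ``Er = 1 - (Sn + Sp) / 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datamodel import ClassMetrics, SpectraMatrix, ValidationError

logger = logging.getLogger(__name__)

WATER_BAND_NM = (1300, 1600)


# Preprocessing ----------------------------------------------------------------

def select_water_band(
    spectra: SpectraMatrix, band: tuple[int, int] = WATER_BAND_NM
) -> SpectraMatrix:
    """Restrict spectra to the OH first-overtone water band (inclusive)."""
    return spectra.select_band(*band)


def absorbance(values: np.ndarray) -> np.ndarray:
    """Optional log10(1/R) transform of reflectance (off by default upstream)."""
    vals = np.asarray(values, dtype=float)
    if np.any(vals <= 0):
        raise ValidationError("absorbance transform requires strictly positive reflectance")
    return -np.log10(vals)


@dataclass(frozen=True)
class PreprocessState:
    """Frozen training-set preprocessing: MSC reference and column means."""

    msc_reference: np.ndarray
    column_means: np.ndarray
    band: tuple[int, int] = WATER_BAND_NM

    def __post_init__(self) -> None:
        if self.msc_reference.shape != self.column_means.shape:
            raise ValidationError("MSC reference and column means must share a grid")


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction.

    Each spectrum is regressed on the reference over wavelengths,
    ``x = a + b * ref`` (ordinary least squares), and corrected as
    ``(x - a) / b``. Default reference: the column mean of ``X`` (so the
    training call both fits and applies; test data must pass the training
    reference). Returns ``(corrected, reference)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("spectra matrix must be 2-D")
    if reference is None:
        if X.shape[0] < 2:
            raise ValidationError("need >= 2 spectra to fit an MSC reference")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (X.shape[1],):
        raise ValidationError(
            f"reference length {reference.shape} does not match {X.shape[1]} wavelengths"
        )
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0:
        raise ValidationError("MSC reference has zero variance")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    small = np.abs(b) < 1e-12
    if small.any():
        raise ValidationError(
            f"MSC slope below 1e-12 for sample index(es) {np.where(small)[0].tolist()}"
        )
    a = X.mean(axis=1) - b * reference.mean()
    corrected = (X - a[:, None]) / b[:, None]
    return corrected, reference


def mean_center(
    X: np.ndarray, column_means: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract (training) column means; returns ``(centered, means)``."""
    X = np.asarray(X, dtype=float)
    if column_means is None:
        column_means = X.mean(axis=0)
    column_means = np.asarray(column_means, dtype=float)
    if column_means.shape != (X.shape[1],):
        raise ValidationError("column-means length does not match the wavelength grid")
    return X - column_means[None, :], column_means


def fit_preprocess(X_train: np.ndarray, band: tuple[int, int] = WATER_BAND_NM) -> tuple[np.ndarray, PreprocessState]:
    """MSC + mean-centring fitted on the training block."""
    corrected, reference = msc(X_train)
    centered, means = mean_center(corrected)
    return centered, PreprocessState(msc_reference=reference, column_means=means, band=band)


def apply_preprocess(X: np.ndarray, state: PreprocessState) -> np.ndarray:
    """Apply a fitted MSC + centring state to new (e.g. test) spectra."""
    corrected, _ = msc(X, reference=state.msc_reference)
    centered, _ = mean_center(corrected, state.column_means)
    return centered


# PCA ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    """SVD principal components of a pretreated spectra matrix."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray


def pca(X: np.ndarray, k: int) -> PCAResult:
    """Principal component analysis of the (already pretreated) matrix by SVD.

    Components are oriented so each loading vector's largest-magnitude entry
    is positive, for reproducible score plots.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ValidationError(f"k must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    scores = U[:, :k] * s[:k]
    return PCAResult(
        scores=scores,
        loadings=Vt[:k].T,
        explained_variance_fraction=s[:k] ** 2 / total if total > 0 else np.zeros(k),
    )


# Train/test split ----------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test index sets drawn under a seed."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        train = set(self.train_indices.tolist())
        test = set(self.test_indices.tolist())
        if train & test:
            raise ValidationError("train and test indices overlap")


def make_split(
    n: int,
    n_test: int,
    seed: int = 0,
    stratify_by: Sequence[str] | None = None,
) -> SplitPlan:
    """Uniform random test subset of size ``n_test`` without replacement.

    With ``stratify_by``, test membership is allocated proportionally within
    each class (largest-remainder rounding).
    """
    if not (0 < n_test < n):
        raise ValidationError(f"n_test must be in (0, n), got {n_test} of {n}")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        test = np.sort(rng.choice(n, size=n_test, replace=False))
    else:
        labels = np.asarray(stratify_by)
        if labels.size != n:
            raise ValidationError("stratify_by length must equal n")
        classes = sorted(pd.unique(labels).tolist())
        quota = {c: n_test * np.sum(labels == c) / n for c in classes}
        take = {c: int(np.floor(quota[c])) for c in classes}
        remainder = sorted(
            classes, key=lambda c: quota[c] - take[c], reverse=True
        )
        short = n_test - sum(take.values())
        for c in remainder[:short]:
            take[c] += 1
        parts = []
        for c in classes:
            idx = np.where(labels == c)[0]
            parts.append(rng.choice(idx, size=take[c], replace=False))
        test = np.sort(np.concatenate(parts))
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    return SplitPlan(train_indices=np.where(mask)[0], test_indices=test, seed=seed)


# PLS-DA ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSDAModel:
    """Fitted latent-variable classifier (NIPALS PLS2 on one-hot Y).

    ``coefficients`` maps centred spectra to centred class scores;
    prediction adds back ``y_mean`` and assigns the argmax class (ties break
    to the lexicographically first label).
    """

    n_latent: int
    class_labels: tuple[str, ...]
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray    # (p, a)
    x_loadings: np.ndarray   # (p, a)
    y_loadings: np.ndarray   # (q, a)
    coefficients: np.ndarray  # (p, q)
    fitted_scores: np.ndarray  # (n_train, q) predicted class scores on train
    msc_reference: np.ndarray | None = None


def _nipals(
    X: np.ndarray,
    Y: np.ndarray,
    n_comp: int,
    tol: float = 1e-12,
    max_iter: int = 1000,
    strict: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sequential NIPALS extraction of up to ``n_comp`` latent variables.

    Returns (T, W, P, C): X-scores, X-weights, X-loadings, Y-loadings. Each
    component maximizes X-Y covariance; X-scores are mutually orthogonal by
    deflation. When the X or Y residual is exhausted before ``n_comp``
    components, ``strict`` raises; otherwise the matrices are truncated to
    the achieved count.
    """
    Xr = X.copy()
    Yr = Y.copy()
    n, p = X.shape
    q = Y.shape[1]
    T = np.zeros((n, n_comp))
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    C = np.zeros((q, n_comp))
    achieved = 0
    scale = max(float(np.abs(X).max()), 1e-300)
    for a in range(n_comp):
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))]
        exhausted = np.allclose(u, 0)
        if not exhausted:
            for _ in range(max_iter):
                w = Xr.T @ u
                norm_w = np.linalg.norm(w)
                if norm_w < 1e-12 * scale:
                    exhausted = True
                    break
                w /= norm_w
                t = Xr @ w
                tt = float(t @ t)
                c = Yr.T @ t / tt
                cc = float(c @ c)
                u_new = Yr @ c / cc
                if np.linalg.norm(u_new - u) <= tol * max(np.linalg.norm(u_new), 1e-300):
                    u = u_new
                    break
                u = u_new
        if exhausted:
            if strict:
                raise ValidationError(
                    f"residual exhausted after {a} latent variables; lower n_latent"
                )
            break
        p_vec = Xr.T @ t / tt
        Xr -= np.outer(t, p_vec)
        Yr -= np.outer(t, c)
        T[:, a], W[:, a], P[:, a], C[:, a] = t, w, p_vec, c
        achieved = a + 1
    return T[:, :achieved], W[:, :achieved], P[:, :achieved], C[:, :achieved]


def _coefficients(W: np.ndarray, P: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Regression coefficients B = W (P'W)^-1 C' for centred X and Y."""
    return W @ np.linalg.solve(P.T @ W, C.T)


def plsda_fit(
    X_train: np.ndarray,
    labels: Sequence[str],
    n_latent: int,
    msc_reference: np.ndarray | None = None,
) -> PLSDAModel:
    """Fit a PLS-DA model on pretreated (MSC'd, centred) training spectra.

    Y is encoded one column per class with 0/1 membership (then centred
    internally); ``n_latent`` components are extracted by NIPALS.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValidationError("X and labels differ in length")
    classes = tuple(sorted(pd.unique(y).tolist()))
    if len(classes) < 2:
        raise ValidationError("PLS-DA needs >= 2 classes")
    counts = {c: int(np.sum(y == c)) for c in classes}
    thin = [c for c, k in counts.items() if k < 2]
    if thin:
        raise ValidationError(f"classes with < 2 training samples: {thin}")
    max_lv = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_latent <= max_lv):
        raise ValidationError(f"n_latent must be in [1, {max_lv}], got {n_latent}")
    Y = np.array([[1.0 if yi == c else 0.0 for c in classes] for yi in y])
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    T, W, P, C = _nipals(Xc, Yc, n_latent)
    B = _coefficients(W, P, C)
    fitted = Xc @ B + y_mean
    return PLSDAModel(
        n_latent=n_latent,
        class_labels=classes,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=C,
        coefficients=B,
        fitted_scores=fitted,
        msc_reference=msc_reference,
    )


def plsda_predict(
    model: PLSDAModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict class labels and continuous class scores for pretreated spectra.

    Assigns the class with maximal predicted score; exact ties go to the
    lexicographically first class label (class columns are kept sorted, so
    the first argmax wins).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.coefficients.shape[0]:
        raise ValidationError(
            f"wavelength grid mismatch: model expects {model.coefficients.shape[0]} "
            f"variables, got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    scores = (X - model.x_mean) @ model.coefficients + model.y_mean
    winners = np.argmax(scores, axis=1)  # first maximum = lexicographic tie-break
    labels = np.array([model.class_labels[i] for i in winners])
    return labels, scores


# Metrics ---------------------------------------------------------------------------

def class_metrics(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_label: str,
    n_latent: int = 0,
    phase: str = "prediction",
) -> ClassMetrics:
    """Per-class sensitivity, specificity, and balanced error.

    Sn = TP/(TP+FN) for the class; Sp = TN/(TN+FP) with every other class
    pooled as negative; Er = 1 - (Sn + Sp)/2.
    """
    yt = np.asarray(true_labels)
    yp = np.asarray(predicted_labels)
    if yt.size == 0 or yt.size != yp.size:
        raise ValidationError("label vectors must be non-empty and equal-length")
    pos = yt == class_label
    if not pos.any():
        raise ValidationError(f"class {class_label!r} absent from true labels")
    pred_pos = yp == class_label
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    sn = tp / (tp + fn)
    sp = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    return ClassMetrics(
        class_label=str(class_label),
        n_latent=n_latent,
        sensitivity=sn,
        specificity=sp,
        error=1.0 - (sn + sp) / 2.0,
        phase=phase,
    )


def balanced_error(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> float:
    """Mean per-class balanced error over the classes present in the truth."""
    classes = sorted(pd.unique(np.asarray(true_labels)).tolist())
    errs = [
        class_metrics(true_labels, predicted_labels, c).error for c in classes
    ]
    return float(np.mean(errs))


# Cross-validated latent-variable selection ---------------------------------------

def _cv_folds(
    labels: np.ndarray, k_folds: int, seed: int, scheme: str
) -> list[tuple[np.ndarray, np.ndarray]]:
    n = labels.size
    if scheme == "stratified":
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(n), labels)]
    if scheme == "venetian":
        folds = []
        for j in range(k_folds):
            te = np.arange(j, n, k_folds)
            tr = np.setdiff1d(np.arange(n), te)
            folds.append((tr, te))
        return folds
    raise ValidationError(f"unknown CV scheme {scheme!r}")


def choose_lv(
    X_train: np.ndarray,
    labels: Sequence[str],
    max_lv: int = 15,
    k_folds: int = 10,
    seed: int = 0,
    scheme: str = "stratified",
) -> tuple[int, np.ndarray]:
    """Select the number of latent variables by k-fold cross-validation.

    ``X_train`` is expected already pretreated (water band, MSC, centring);
    each fold re-centres with its own training means. For each candidate LV
    count the mean (over folds) of the mean per-class balanced error of
    held-out predictions is computed from a single ``max_lv``-component fit
    per fold (truncated coefficient forms). Returns the LV count minimizing
    the curve, smallest count on ties, together with the CV error curve.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    folds = _cv_folds(y, k_folds, seed, scheme)
    feasible = min(max_lv, X.shape[1], min(len(tr) for tr, _ in folds) - 1)
    if feasible < 1:
        raise ValidationError("no feasible latent-variable count for these folds")
    errors = np.zeros((len(folds), feasible))
    for f, (tr, te) in enumerate(folds):
        tr_classes = set(pd.unique(y[tr]).tolist())
        te_classes = set(pd.unique(y[te]).tolist())
        if tr_classes != set(classes) or not te_classes:
            raise ValidationError(
                "a CV fold lost a class; use the stratified scheme or fewer folds"
            )
        Xtr_c, fold_means = mean_center(X[tr])
        Xte_c, _ = mean_center(X[te], fold_means)
        Y = np.array([[1.0 if yi == c else 0.0 for c in classes] for yi in y[tr]])
        y_mean = Y.mean(axis=0)
        T, W, P, C = _nipals(Xtr_c, Y - y_mean, feasible, strict=False)
        achieved = T.shape[1]
        for a in range(1, feasible + 1):
            a_eff = min(a, achieved)  # past the achieved rank nothing changes
            B = _coefficients(W[:, :a_eff], P[:, :a_eff], C[:, :a_eff])
            scores = Xte_c @ B + y_mean
            pred = np.array([classes[i] for i in np.argmax(scores, axis=1)])
            per_class = [
                class_metrics(y[te], pred, c).error
                for c in classes
                if c in te_classes
            ]
            errors[f, a - 1] = float(np.mean(per_class))
    curve = errors.mean(axis=0)
    n_latent = int(np.argmin(curve)) + 1  # argmin takes the first (smallest) on ties
    return n_latent, curve


# End-to-end experiment --------------------------------------------------------------

@dataclass(frozen=True)
class PLSDAExperimentConfig:
    """Knobs of the end-to-end classification experiment."""

    band: tuple[int, int] = WATER_BAND_NM
    n_test: int = 58
    max_lv: int = 15
    k_folds: int = 10
    cv_scheme: str = "stratified"
    stratify_split: bool = False
    use_absorbance: bool = False
    seed: int = 0


@dataclass(frozen=True)
class PLSDAExperimentResult:
    """Everything the experiment computed, for reporting and the run manifest."""

    label_field: str
    n_latent: int
    cv_curve: np.ndarray
    metrics: pd.DataFrame
    split: SplitPlan
    model: PLSDAModel
    pca_scores: pd.DataFrame


def run_plsda_experiment(
    spectra: SpectraMatrix,
    label_field: str,
    config: PLSDAExperimentConfig = PLSDAExperimentConfig(),
) -> PLSDAExperimentResult:
    """Water band -> split -> MSC -> centre -> CV LV choice -> fit -> predict.

    CV-phase metrics pool the held-out predictions of the chosen-LV models
    over the training folds; prediction-phase metrics come from the single
    test-set prediction. Fully reproducible under ``config.seed``.
    """
    if label_field not in spectra.labels.columns:
        raise ValidationError(f"spectra carry no label field {label_field!r}")
    band = select_water_band(spectra, config.band)
    y_all = band.labels[label_field].to_numpy()
    split = make_split(
        band.n_samples,
        config.n_test,
        seed=config.seed,
        stratify_by=y_all if config.stratify_split else None,
    )
    X = band.values
    if config.use_absorbance:
        X = absorbance(X)
    X_train, y_train = X[split.train_indices], y_all[split.train_indices]
    X_test, y_test = X[split.test_indices], y_all[split.test_indices]
    classes = sorted(pd.unique(y_train).tolist())
    if set(pd.unique(y_test)) - set(classes):
        raise ValidationError("test set contains a class unseen in training")

    # Pretreat once on the training block (MSC reference and column means are
    # training-set statistics); the test block is corrected with that state.
    Xtr_c, state = fit_preprocess(X_train, band=config.band)
    Xte_c = apply_preprocess(X_test, state)

    n_latent, curve = choose_lv(
        Xtr_c, y_train, config.max_lv, config.k_folds, config.seed, config.cv_scheme
    )

    # CV-phase predictions at the chosen LV count, pooled over folds
    folds = _cv_folds(y_train, config.k_folds, config.seed, config.cv_scheme)
    cv_pred = np.empty(y_train.size, dtype=object)
    for tr, te in folds:
        model_f = plsda_fit(Xtr_c[tr], y_train[tr], n_latent)
        pred, _ = plsda_predict(model_f, Xtr_c[te])
        cv_pred[te] = pred
    cv_pred = cv_pred.astype(str)

    # Final model on the full training block; external validation on the test set
    model = plsda_fit(Xtr_c, y_train, n_latent, msc_reference=state.msc_reference)
    test_pred, _ = plsda_predict(model, Xte_c)

    rows = []
    for c in classes:
        m_cv = class_metrics(y_train, cv_pred, c, n_latent, phase="cv")
        m_pr = class_metrics(y_test, test_pred, c, n_latent, phase="prediction")
        for m in (m_cv, m_pr):
            rows.append(
                (
                    label_field,
                    m.class_label,
                    m.n_latent,
                    m.phase,
                    round(m.sensitivity, 3),
                    round(m.specificity, 3),
                    round(m.error, 3),
                )
            )
    metrics = pd.DataFrame(
        rows,
        columns=["label_field", "class", "n_latent", "phase", "sensitivity",
                 "specificity", "error"],
    )

    pca_res = pca(Xtr_c, k=3)
    pca_scores = pd.DataFrame(
        pca_res.scores,
        columns=["PC1", "PC2", "PC3"],
        index=[band.sample_ids[i] for i in split.train_indices],
    )
    pca_scores[label_field] = y_train

    return PLSDAExperimentResult(
        label_field=label_field,
        n_latent=n_latent,
        cv_curve=curve,
        metrics=metrics,
        split=split,
        model=model,
        pca_scores=pca_scores,
    )
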