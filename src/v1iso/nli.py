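"""GLM/GQM comparison and nonlinearity indices.

Spiking during hyperpixel white noise is predicted from either the two
projections of each 15-frame stimulus segment onto the halves of the
hyperpixel STA (across-subfield analysis) or from the single-frame
background-subtracted RGB of one hyperpixel at the response latency
(within-subfield analysis).  Each dataset is fit with a logistic
generalized linear model and its full second-order (generalized quadratic)
extension by maximum Bernoulli likelihood.  Performance is one minus the
ROC area on held-out folds, and the nonlinearity index is

    NLI = log10( median over folds of error_GLM / error_GQM ),

positive when the quadratic model predicts held-out spikes better.  The
spread of the per-fold indices is summarized with the standard delete-one
jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .receptive_field import HyperpixelSTA, N_LAGS
from .stimulus import StimulusMovie, hyperpixel_values

__all__ = [
    "ProjectionDataset",
    "SubfieldRGBDataset",
    "ModelFit",
    "NLIResult",
    "build_projection_dataset",
    "firing_rate_map",
    "fit_subfield_model",
    "classification_error",
    "white_noise_nli",
    "within_subfield_nli",
    "jackknife_se",
]


@dataclass(frozen=True)
class ProjectionDataset:
    """Rows of (P1, P2, spike): segment projections and the final-frame label."""

    p1: np.ndarray
    p2: np.ndarray
    spike: np.ndarray  # binary

    def __post_init__(self) -> None:
        if not (self.p1.shape == self.p2.shape == self.spike.shape):
            raise ValueError("P1, P2 and spike must have matching length")
        object.__setattr__(self, "spike", np.asarray(self.spike).astype(np.int8))

    @property
    def features(self) -> np.ndarray:
        return np.column_stack([self.p1, self.p2])


@dataclass(frozen=True)
class SubfieldRGBDataset:
    """Rows of (R, G, B, spike) for one hyperpixel at the response latency."""

    rgb: np.ndarray  # (n, 3) background-subtracted
    spike: np.ndarray

    def __post_init__(self) -> None:
        if self.rgb.shape != (self.spike.shape[0], 3):
            raise ValueError("rgb must be (n, 3) matching spike length")
        object.__setattr__(self, "spike", np.asarray(self.spike).astype(np.int8))

    @property
    def features(self) -> np.ndarray:
        return self.rgb


def _design(X: np.ndarray, kind: str) -> np.ndarray:
    """Linear or full second-order polynomial design matrix (no intercept
    column; the fit adds it)."""
    if kind in ("GLM_across", "GLM_within"):
        return X
    if kind == "GQM_across":
        p1, p2 = X[:, 0], X[:, 1]
        return np.column_stack([p1**2, p2**2, p1 * p2, p1, p2])
    if kind == "GQM_within":
        r, g, b = X[:, 0], X[:, 1], X[:, 2]
        return np.column_stack([r**2, g**2, b**2, r * g, g * b, r * b, r, g, b])
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class ModelFit:
    kind: str
    weights: np.ndarray
    intercept: float
    converged: bool
    ridged: bool = False

    def decision(self, ds) -> np.ndarray:
        return _design(ds.features, self.kind) @ self.weights + self.intercept

    def predict_proba(self, ds) -> np.ndarray:
        from scipy.special import expit

        return expit(self.decision(ds))


@dataclass(frozen=True)
class NLIResult:
    """A nonlinearity index with its per-fold errors and jackknife SE."""

    value: float
    per_fold_errors: list  # [(err_glm, err_gqm), ...]
    jackknife_se: float
    kind: str = "white_noise"

    @property
    def per_fold_log_ratios(self) -> np.ndarray:
        e = np.asarray(self.per_fold_errors, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log10(e[:, 0] / e[:, 1])


def build_projection_dataset(
    movie: StimulusMovie,
    spikes: np.ndarray,
    hsta: HyperpixelSTA,
    background: np.ndarray | None = None,
) -> ProjectionDataset:
    """Project every 15-frame segment onto the two halves of the STA.

    P1 (P2) is the inner product of the background-subtracted hyperpixel
    segment ending at frame t with the temporo-chromatic STA restricted to
    subfield 1 (2); the label is whether a spike occurred at frame t.
    """
    if background is None:
        background = movie.data.mean(axis=(0, 1))
    hp = hyperpixel_values(movie, hsta.hmap) - background  # (n, 2, 3)
    n = hp.shape[0]
    m = n - N_LAGS + 1
    proj = np.zeros((m, 2))
    for k in range(N_LAGS):
        for h in range(2):
            proj[:, h] += hp[k : k + m, h, :] @ hsta.frames[k, h, :]
    labels = (np.asarray(spikes)[N_LAGS - 1 :] >= 1).astype(np.int8)
    return ProjectionDataset(p1=proj[:, 0], p2=proj[:, 1], spike=labels)


def firing_rate_map(
    ds: ProjectionDataset, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike probability binned on the (P1, P2) plane.

    Returns (prob, x_edges, y_edges); bins with no stimuli hold NaN.
    """
    if ds.p1.size == 0:
        raise ValueError("empty dataset")
    counts, xe, ye = np.histogram2d(ds.p1, ds.p2, bins=n_bins)
    spikes, _, _ = np.histogram2d(ds.p1, ds.p2, bins=[xe, ye], weights=ds.spike.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(counts > 0, spikes / counts, np.nan)
    return prob, xe, ye


def fit_subfield_model(ds, kind: str, ridge_on_separation: float = 1e-6) -> ModelFit:
    """Maximum-likelihood logistic fit of the stated GLM or GQM.

    Unregularized by default; on failure to converge (e.g. complete
    separation) the fit is repeated with a tiny L2 penalty and flagged.
    Deterministic given the data.
    """
    X = _design(ds.features, kind)
    y = np.asarray(ds.spike)
    if len(np.unique(y)) < 2:
        raise ValueError("both spike and no-spike classes must be present")

    def _fit(penalty_none: bool) -> tuple[LogisticRegression, bool]:
        # C=inf is an unpenalized ML fit; C=1/ridge applies the tiny fallback ridge
        C = np.inf if penalty_none else 1.0 / ridge_on_separation
        model = LogisticRegression(
            C=C, solver="lbfgs", max_iter=500 if penalty_none else 1000, tol=1e-8
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(X, y)
                return model, True
            except ConvergenceWarning:
                pass
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        return model, False

    def _separated(model) -> bool:
        scores = X @ model.coef_.ravel() + model.intercept_[0]
        return scores[y == 1].min() > scores[y == 0].max()

    model, ok = _fit(penalty_none=True)
    ridged = False
    # complete separation leaves the unpenalized ML unbounded (the solver
    # stalls at arbitrarily steep weights); fall back to a tiny ridge
    if not ok or _separated(model):
        model, ok = _fit(penalty_none=False)
        ridged = True
    return ModelFit(
        kind=kind,
        weights=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
        converged=True,
        ridged=ridged,
    )


def classification_error(fit: ModelFit, ds) -> float:
    """1 - AUC with the fitted probability as ranking score (midrank ties)."""
    y = np.asarray(ds.spike)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the evaluation set")
    return float(1.0 - roc_auc_score(y, fit.decision(ds)))


def jackknife_se(values: np.ndarray) -> float:
    """Standard delete-one jackknife SE treating each value as a pseudo-replicate."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        return float("nan")
    return float(np.sqrt((n - 1) / n * np.sum((v - v.mean()) ** 2)))


def _nli_from_errors(errors: list[tuple[float, float]]) -> tuple[float, float]:
    e = np.asarray(errors, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = e[:, 0] / e[:, 1]
        value = float(np.log10(np.median(ratios)))
        per_fold = np.log10(ratios)
    return value, jackknife_se(per_fold)


def _stratified_folds(y: np.ndarray, k: int, seed: int, max_attempts: int = 5):
    """Stratified k-fold assignments whose test folds contain both classes."""
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + 1000 * attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(len(np.unique(y[te])) == 2 for _, te in folds):
            return folds
    raise ValueError("could not build folds with both classes present")


def white_noise_nli(
    ds: ProjectionDataset, k: int = 10, seed: int = 0
) -> NLIResult:
    """Across-subfield NLI by stratified k-fold cross-validation.

    Per fold the GLM and GQM are trained on the remaining folds and their
    ROC classification errors measured on the held-out fold.
    """
    if ds.spike.sum() < k:
        raise ValueError(f"need at least {k} spikes")
    folds = _stratified_folds(np.asarray(ds.spike), k, seed)
    errors = []
    for tr, te in folds:
        train = ProjectionDataset(ds.p1[tr], ds.p2[tr], ds.spike[tr])
        test = ProjectionDataset(ds.p1[te], ds.p2[te], ds.spike[te])
        glm = fit_subfield_model(train, "GLM_across")
        gqm = fit_subfield_model(train, "GQM_across")
        errors.append(
            (classification_error(glm, test), classification_error(gqm, test))
        )
    value, se = _nli_from_errors(errors)
    return NLIResult(value=value, per_fold_errors=errors, jackknife_se=se,
                     kind="white_noise")


def build_subfield_rgb_datasets(
    movie: StimulusMovie,
    spikes: np.ndarray,
    hsta: HyperpixelSTA,
    latency: int,
    background: np.ndarray | None = None,
) -> tuple[SubfieldRGBDataset, SubfieldRGBDataset]:
    """Single-frame RGB datasets for the two hyperpixels.

    The frame driving the spike bin at time t is taken ``latency`` frames
    earlier (latency = peak lag of the hyperpixel STA).
    """
    if background is None:
        background = movie.data.mean(axis=(0, 1))
    hp = hyperpixel_values(movie, hsta.hmap) - background
    n = hp.shape[0]
    if not 0 <= latency < n:
        raise ValueError("latency out of range")
    labels = (np.asarray(spikes)[latency:] >= 1).astype(np.int8)
    out = []
    for h in range(2):
        feats = hp[: n - latency, h, :]
        out.append(SubfieldRGBDataset(rgb=feats, spike=labels))
    return out[0], out[1]


def within_subfield_nli(
    movie: StimulusMovie,
    spikes: np.ndarray,
    hsta: HyperpixelSTA,
    latency: int | None = None,
    k: int = 10,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> NLIResult:
    """Within-subfield NLI: GLM vs GQM on single-frame RGB per hyperpixel.

    Fold assignments are synchronized across the two hyperpixels (they share
    one spike train); per fold, classification errors are summed across
    subfields before the GLM/GQM ratio is formed.
    """
    if latency is None:
        latency = hsta.peak_latency
    ds1, ds2 = build_subfield_rgb_datasets(movie, spikes, hsta, latency, background)
    y = np.asarray(ds1.spike)
    if y.sum() < k:
        raise ValueError(f"need at least {k} spikes")
    folds = _stratified_folds(y, k, seed)
    errors = []
    for tr, te in folds:
        err_glm = err_gqm = 0.0
        for ds in (ds1, ds2):
            train = SubfieldRGBDataset(ds.rgb[tr], ds.spike[tr])
            test = SubfieldRGBDataset(ds.rgb[te], ds.spike[te])
            err_glm += classification_error(
                fit_subfield_model(train, "GLM_within"), test
            )
            err_gqm += classification_error(
                fit_subfield_model(train, "GQM_within"), test
            )
        errors.append((err_glm, err_gqm))
    value, se = _nli_from_errors(errors)
    return NLIResult(value=value, per_fold_errors=errors, jackknife_se=se,
                     kind="within_subfield")
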