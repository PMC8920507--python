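"""Closed-loop isoresponse contour measurement and robust polar fits.

A multiplicative contrast staircase titrates stimulus contrast along fixed
directions of the neuron-specific stimulus plane until the trial spike
count brackets a target response: contrast rises by a factor of 1.35 when
the count falls short, falls by a factor of 0.65 when it exceeds the
target, and the per-trial change shrinks by 25% after every reversal.  A
run halts at seven reversals (terminated) or on leaving the display gamut.
Termination points (r, theta) are fit, in log(r) with radial error, by a
line ``A r cos(theta) + B r sin(theta) = 1`` and by the general conic
``A (r cos)^2 + B (r sin)^2 + C r^2 cos sin + D r cos + E r sin = 1``
under a Tukey-bisquare objective, and compared by leave-one-out
cross-validation (the isoresponse NLI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .nli import NLIResult, jackknife_se

__all__ = [
    "StaircaseParams",
    "StaircaseRun",
    "Staircase",
    "PolarModelFit",
    "choose_target_rate",
    "run_staircase",
    "measure_contour",
    "fit_contour",
    "isoresponse_nli",
]

#: Tukey bisquare tuning constant (95% Gaussian efficiency)
DEFAULT_TUNING = 4.685
#: floor on the robust residual scale, in log-radius units
MIN_SCALE = 1e-3
#: loss contribution of a direction where a model predicts no positive radius
INVALID_PENALTY = 1e3


@dataclass(frozen=True)
class StaircaseParams:
    up_factor: float = 1.35
    down_factor: float = 0.65
    step_shrink: float = 0.25  # per-reversal reduction of the step magnitude
    max_reversals: int = 7
    initial_radius_fraction: float = 0.25  # of the direction's gamut limit
    max_trials: int = 200  # safety valve; generous vs. the 7-reversal budget

    def __post_init__(self) -> None:
        if not (self.up_factor > 1.0 > self.down_factor > 0.0):
            raise ValueError("need up_factor > 1 > down_factor > 0")
        if not 0.0 < self.step_shrink < 1.0:
            raise ValueError("step_shrink must lie in (0, 1)")


@dataclass
class StaircaseRun:
    theta: float
    trials: list  # [(radius, count), ...]
    reversals: int
    termination_radius: float | None
    status: str  # {"terminated", "out_of_gamut"}


class Staircase:
    """One direction's staircase, stepped trial-by-trial for interleaving.

    Contrast updates are multiplicative, i.e. additive in log radius with
    steps log(1.35) up / log(0.65) down, both scaled by 0.75 per reversal.
    A response equal to the target counts as exceeding it (the contrast is
    not increased), so the procedure always makes progress.
    """

    def __init__(self, theta: float, target_count: float,
                 params: StaircaseParams, gamut_limit: float):
        if not np.isfinite(gamut_limit) or gamut_limit <= 0:
            raise ValueError("gamut_limit must be positive and finite")
        self.theta = float(theta)
        self.target = target_count
        self.params = params
        self.gamut_limit = float(gamut_limit)
        self.radius = params.initial_radius_fraction * gamut_limit
        self.shrink = 1.0
        self.reversals = 0
        self.trials: list[tuple[float, int]] = []
        self.prev_high: bool | None = None
        self.status: str | None = None

    @property
    def active(self) -> bool:
        return self.status is None

    def observe(self, count: int) -> None:
        """Record the response to the current radius and update the state."""
        if not self.active:
            raise RuntimeError("staircase already finished")
        p = self.params
        self.trials.append((self.radius, int(count)))
        high = count >= self.target
        if self.prev_high is not None and high != self.prev_high:
            self.reversals += 1
            self.shrink *= 1.0 - p.step_shrink
            if self.reversals >= p.max_reversals:
                self.status = "terminated"
                return
        self.prev_high = high
        step = np.log(p.down_factor) if high else np.log(p.up_factor)
        new_radius = float(np.exp(np.log(self.radius) + self.shrink * step))
        if new_radius > self.gamut_limit:
            self.status = "out_of_gamut"
            return
        if len(self.trials) >= p.max_trials:
            self.status = "out_of_gamut"
            return
        self.radius = new_radius

    def result(self) -> StaircaseRun:
        if self.active:
            raise RuntimeError("staircase still running")
        term = self.trials[-1][0] if self.status == "terminated" else None
        return StaircaseRun(
            theta=self.theta,
            trials=list(self.trials),
            reversals=self.reversals,
            termination_radius=term,
            status=self.status,
        )


def choose_target_rate(
    baseline_counts: np.ndarray,
    duration_s: float = 0.3,
    percentile: float = 95.0,
    step_ips: float = 5.0,
) -> float:
    """Smallest round target rate strictly above a baseline-rate percentile.

    Targets are multiples of ``step_ips`` (impulses per second), chosen to
    exceed the stated percentile of the baseline firing-rate distribution so
    spontaneous activity rarely triggers spurious staircase reversals.
    """
    counts = np.asarray(baseline_counts, dtype=float)
    if counts.size < 20:
        raise ValueError("need at least 20 baseline trials")
    rates = counts / duration_s
    p = float(np.percentile(rates, percentile))
    return float(step_ips * (np.floor(p / step_ips) + 1.0))


def run_staircase(
    oracle,
    theta: float,
    target_count: float,
    params: StaircaseParams,
    gamut_limit: float,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> StaircaseRun:
    """Drive one staircase to completion.

    ``oracle(radius, theta, rng)`` returns the trial spike count.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sc = Staircase(theta, target_count, params, gamut_limit)
    while sc.active:
        sc.observe(oracle(sc.radius, theta, rng))
    return sc.result()


def measure_contour(
    oracle,
    target_count: float,
    directions: np.ndarray,
    params: StaircaseParams,
    gamut_limit_fn,
    seed: int = 0,
) -> list[StaircaseRun]:
    """Staircases over all directions, interleaved in random pairs.

    Directions are shuffled and taken two at a time; within a pair, trials
    alternate between the two active staircases (mimicking the interleaving
    used to mitigate response non-stationarity).  Raises if every run leaves
    the gamut.
    """
    directions = np.asarray(directions, dtype=float)
    if directions.size < 8:
        raise ValueError("need at least 8 directions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(directions.size)
    runs: dict[int, StaircaseRun] = {}
    for i in range(0, order.size, 2):
        pair = order[i : i + 2]
        stairs = {
            j: Staircase(directions[j], target_count, params,
                         float(gamut_limit_fn(directions[j])))
            for j in pair
        }
        while any(s.active for s in stairs.values()):
            for j in pair:
                s = stairs[j]
                if s.active:
                    s.observe(oracle(s.radius, s.theta, rng))
        for j in pair:
            runs[j] = stairs[j].result()
    out = [runs[j] for j in range(directions.size)]
    if all(r.status == "out_of_gamut" for r in out):
        raise ValueError("all staircases left the gamut; no contour measured")
    return out


# ---------------------------------------------------------------------------
# robust polar fits


def _tukey_rho(u: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare loss; constant c^2/6 beyond |u| = c."""
    u = np.asarray(u, dtype=float)
    inside = np.abs(u) <= c
    out = np.full(u.shape, c**2 / 6.0)
    v = u[inside] / c
    out[inside] = c**2 / 6.0 * (1.0 - (1.0 - v**2) ** 3)
    return out


def _predict_log_r(kind: str, coef: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Model-predicted log radius per direction; NaN when no positive radius."""
    return _predict_log_r_trig(kind, coef, np.cos(theta), np.sin(theta))


def _predict_log_r_trig(
    kind: str, coef: np.ndarray, ct: np.ndarray, st: np.ndarray
) -> np.ndarray:
    if kind == "linear":
        A, B = coef
        denom = A * ct + B * st
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, 1.0 / denom, np.nan)
    elif kind == "quadratic":
        A, B, C, D, E = coef
        a = A * ct**2 + B * st**2 + C * ct * st
        b = D * ct + E * st
        r = np.full(ct.shape, np.nan)
        # a r^2 + b r - 1 = 0; smallest positive real root per direction
        lin = np.abs(a) < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            r_lin = np.where(b > 0, 1.0 / b, np.nan)
        r[lin] = r_lin[lin]
        disc = b**2 + 4.0 * a
        ok = ~lin & (disc >= 0)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = (-b - sq) / (2.0 * a)
            r2 = (-b + sq) / (2.0 * a)
        roots = np.stack([r1, r2])
        roots[:, ~ok] = np.nan
        roots[~(roots > 0)] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r[ok] = np.nanmin(roots, axis=0)[ok]
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.log(r)


@dataclass
class PolarModelFit:
    """Robust fit of a line or conic to (r, theta) termination points."""

    kind: str  # {"linear", "quadratic"}
    coef: np.ndarray  # (A, B) or (A, B, C, D, E)
    robust_loss: float
    scale: float  # robust residual scale used in the objective
    tuning_constant: float = DEFAULT_TUNING

    def predict_r(self, theta) -> np.ndarray:
        return np.exp(_predict_log_r(self.kind, self.coef, np.atleast_1d(np.asarray(theta, float))))

    def heldout_error(self, r: float, theta: float) -> float:
        """Tukey-bisquare error of one point under this fit's scale."""
        logpred = _predict_log_r(self.kind, self.coef, np.atleast_1d(theta))[0]
        if not np.isfinite(logpred):
            return INVALID_PENALTY * self.scale**2
        u = (np.log(r) - logpred) / self.scale
        return float(self.scale**2 * _tukey_rho(np.array([u]), self.tuning_constant)[0])


def _robust_objective(
    coef: np.ndarray, kind: str, logr: np.ndarray, ct: np.ndarray,
    st: np.ndarray, scale: float, c: float
) -> float:
    pred = _predict_log_r_trig(kind, coef, ct, st)
    bad = ~np.isfinite(pred)
    u = (logr - np.where(bad, 0.0, pred)) / scale
    rho = _tukey_rho(u, c)
    rho[bad] = INVALID_PENALTY
    return float(scale**2 * np.sum(rho))


def _linear_init(r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Least-squares seed: regress 1/r on (cos theta, sin theta)."""
    X = np.column_stack([np.cos(theta), np.sin(theta)])
    coef, *_ = np.linalg.lstsq(X, 1.0 / r, rcond=None)
    return coef


def _lms_init(
    kind: str, r: np.ndarray, theta: np.ndarray, logr: np.ndarray,
    rng: np.random.Generator, n_sub: int = 60
) -> np.ndarray | None:
    """High-breakdown seed: exact fits through random minimal subsets,
    keeping the one with the least median squared log-residual.

    Gross outliers can drag both a least-squares seed and the MAD scale
    derived from it; an LMS-style subsample seed stays on the inlier
    structure as long as outliers are a minority.
    """
    ct, st = np.cos(theta), np.sin(theta)
    if kind == "linear":
        X = np.column_stack([ct, st])
    else:
        X = np.column_stack([ct**2, st**2, ct * st, ct, st])
    q = X.shape[1]
    n = r.size
    if n <= q + 1:
        return None
    best, best_med = None, np.inf
    for _ in range(n_sub):
        idx = rng.choice(n, size=q, replace=False)
        try:
            coef = np.linalg.solve(X[idx], 1.0 / r[idx])
        except np.linalg.LinAlgError:
            continue
        res = logr - _predict_log_r_trig(kind, coef, ct, st)
        res = np.where(np.isfinite(res), res, 10.0)  # invalid = very bad
        med = float(np.median(res**2))
        if med < best_med:
            best, best_med = coef, med
    return best


def _mad_scale(res: np.ndarray) -> float:
    res = res[np.isfinite(res)]
    if res.size == 0:
        return 1.0
    return max(1.4826 * float(np.median(np.abs(res - np.median(res)))), MIN_SCALE)


def fit_contour(
    points,
    kind: str = "linear",
    tuning_constant: float = DEFAULT_TUNING,
    n_starts: int = 5,
    seed: int = 0,
    warm_starts: list | None = None,
) -> PolarModelFit:
    """Tukey-bisquare fit of the line (Ax + By = 1) or general conic.

    ``points`` is a sequence of (r, theta) termination points (out-of-gamut
    runs excluded).  Residuals are log(r_obs) - log(r_pred) (radial error in
    log contrast, matching the multiplicative staircase), standardized by a
    MAD scale.  The objective is minimized by Nelder-Mead from a
    least-squares seed plus randomized restarts (and any ``warm_starts``),
    keeping the best; the scale is then re-estimated from the robust
    residuals and the fit repeated once, so gross outliers do not inflate
    the scale through the non-robust seed.
    """
    pts = np.asarray(points, dtype=float)
    r, theta = pts[:, 0], pts[:, 1]
    min_pts = 4 if kind == "linear" else 6
    if r.size < min_pts:
        raise ValueError(f"{kind} fit needs at least {min_pts} points")
    if np.allclose(theta, theta[0]):
        raise ValueError("all directions identical; contour fit is degenerate")
    if not np.all(r > 0):
        raise ValueError("termination radii must be positive")
    logr = np.log(r)
    ct, st = np.cos(theta), np.sin(theta)

    lin0 = _linear_init(r, theta)
    x0 = lin0 if kind == "linear" else np.array([0.0, 0.0, 0.0, lin0[0], lin0[1]])

    rng = np.random.default_rng(seed)
    x_lms = _lms_init(kind, r, theta, logr, rng)
    scale_candidates = [_mad_scale(logr - _predict_log_r(kind, x0, theta))]
    if x_lms is not None:
        scale_candidates.append(
            _mad_scale(logr - _predict_log_r(kind, x_lms, theta))
        )
    # the tighter scale comes from whichever seed tracks the inliers better
    scale = min(scale_candidates)

    spread = np.maximum(np.abs(x0), 0.5)
    starts = [x0] + ([x_lms] if x_lms is not None else []) + list(warm_starts or [])
    starts += [
        x0 + 0.3 * spread * rng.standard_normal(x0.size)
        for _ in range(max(0, n_starts - len(starts)))
    ]

    def _minimize(start, sc):
        return minimize(
            _robust_objective,
            np.asarray(start, dtype=float),
            args=(kind, logr, ct, st, sc, tuning_constant),
            method="Nelder-Mead",
            options={"maxiter": 400 * x0.size, "xatol": 1e-5, "fatol": 1e-9},
        )

    best = None
    for start in starts:
        sol = _minimize(start, scale)
        if best is None or sol.fun < best.fun:
            best = sol
    # re-scale from the robust residuals and polish once
    scale2 = _mad_scale(logr - _predict_log_r(kind, best.x, theta))
    if abs(scale2 - scale) / scale > 0.01:
        sol = _minimize(best.x, scale2)
        best, scale = sol, scale2
    return PolarModelFit(
        kind=kind,
        coef=np.asarray(best.x),
        robust_loss=float(best.fun),
        scale=scale,
        tuning_constant=tuning_constant,
    )


def isoresponse_nli(points, seed: int = 0, min_valid_folds: int = 6) -> NLIResult:
    """Leave-one-out comparison of the linear and quadratic contour models.

    For each left-out termination point both models are fit to the rest and
    their held-out Tukey-bisquare errors recorded; the NLI is the log10 of
    the median linear/quadratic error ratio, with a jackknife SE over the
    per-fold log ratios.  Folds where either fit fails are excluded (at
    least ``min_valid_folds`` must survive).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 8:
        raise ValueError("need at least 8 terminated points")
    # full-data fits seed the leave-one-out refits
    lin_full = fit_contour(pts, "linear", seed=seed)
    quad_full = fit_contour(pts, "quadratic", seed=seed)
    errors = []
    for i in range(n):
        rest = np.delete(pts, i, axis=0)
        r_i, th_i = pts[i]
        try:
            lin = fit_contour(rest, "linear", seed=seed + i, n_starts=3,
                              warm_starts=[lin_full.coef])
            quad = fit_contour(rest, "quadratic", seed=seed + i, n_starts=3,
                               warm_starts=[quad_full.coef])
        except (ValueError, np.linalg.LinAlgError):
            continue
        errors.append((lin.heldout_error(r_i, th_i), quad.heldout_error(r_i, th_i)))
    if len(errors) < min_valid_folds:
        raise ValueError(f"only {len(errors)} valid folds; need {min_valid_folds}")
    e = np.asarray(errors)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = e[:, 0] / e[:, 1]
        value = float(np.log10(np.median(ratios)))
        per_fold = np.log10(ratios)
    return NLIResult(
        value=value,
        per_fold_errors=errors,
        jackknife_se=jackknife_se(per_fold),
        kind="isoresponse",
    )
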