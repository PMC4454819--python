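"""Exponential response-surface model of gold-nanoparticle toxicity.

For a series of gold nanoparticles differing in surface ligand and primary
size, the weighted EZ score is modeled as an exponential response surface
over ligand descriptors, particle size and exposure concentration::

    mod_EZ = exp( b0 + b1*ln(C) + b2*Size + b3*(SASA/Polar) + b4*Refractivity
                  + b5*BandGap + b13*ln(C)*(SASA/Polar) + b25*Size*BandGap
                  + b11*ln(C)^2 + b22*Size^2 )

where ``mod_EZ = 100 * EZ + 0.1`` (the offset avoids ln(0) for clean groups),
``C`` is the exposure concentration in ppm (natural log), ``Size`` the primary
particle diameter in nm, and the three ligand descriptors come from a
:class:`~ezmetric.assay_io.LigandDescriptorSet`.  The coefficient subscripts
are labels only — they carry no combinatorial meaning.

Fitting minimizes the unweighted sum of squares of ``mod_EZ - exp(x @ beta)``
by Levenberg–Marquardt, initialized from the ordinary least-squares fit of
``ln(mod_EZ)`` on the same design matrix (exact for noise-free data, so the
optimizer terminates immediately there).  Standard errors come from
``s^2 (J'J)^-1`` at the optimum, p-values from the t distribution with
``n - 10`` degrees of freedom, and R-squared is reported on the mod scale
(with a log-scale companion).  Outliers are screened by externally
studentized residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .assay_io import LigandDescriptorSet
from .errors import FitError, ValidationError

__all__ = [
    "TERM_NAMES",
    "MOD_OFFSET",
    "GOLD_REFERENCE_COEFFICIENTS",
    "ModelObservation",
    "ModelCoefficients",
    "ResponseModelFit",
    "mod_transform",
    "inverse_mod_transform",
    "design_row",
    "design_matrix",
    "predict_mod_ez",
    "fit_model",
    "detect_outliers",
    "response_surface",
]

#: Names of the ten model terms, in design-matrix column order.
TERM_NAMES: tuple[str, ...] = (
    "intercept",
    "log_conc",
    "size",
    "sasa_over_polar",
    "refractivity",
    "band_gap",
    "log_conc_x_sasa_over_polar",
    "size_x_band_gap",
    "log_conc_sq",
    "size_sq",
)

MOD_OFFSET = 0.1
_LINPRED_BOUND = 700.0  # exp overflow guard on the linear predictor


def mod_transform(ez_score: float) -> float:
    """Map a raw EZ score to the positive mod scale: ``100 * score + 0.1``."""
    return 100.0 * ez_score + MOD_OFFSET


def inverse_mod_transform(mod_ez: float) -> float:
    """Invert :func:`mod_transform`: ``(mod - 0.1) / 100``."""
    return (mod_ez - MOD_OFFSET) / 100.0


@dataclass(frozen=True)
class ModelCoefficients:
    """The ten named coefficients of the exponential response surface."""

    intercept: float
    log_conc: float
    size: float
    sasa_over_polar: float
    refractivity: float
    band_gap: float
    log_conc_x_sasa_over_polar: float
    size_x_band_gap: float
    log_conc_sq: float
    size_sq: float

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValidationError(f"coefficient {f.name} is not finite")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in TERM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, beta: Sequence[float]) -> "ModelCoefficients":
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (10,):
            raise ValidationError(f"expected 10 coefficients, got shape {beta.shape}")
        return cls(**dict(zip(TERM_NAMES, beta.tolist())))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TERM_NAMES}


#: Reference coefficient set estimated from the original four-ligand gold
#: nanoparticle screen (TMAT / MEE / MEEE / MES surface chemistries).  Used as
#: the default generating truth for simulated model observations and as a
#: plausible surface for exploratory prediction.
GOLD_REFERENCE_COEFFICIENTS = ModelCoefficients(
    intercept=67.2828,
    log_conc=0.8128,
    size=14.7335,
    sasa_over_polar=4.1535,
    refractivity=-0.2974,
    band_gap=0.3715,
    log_conc_x_sasa_over_polar=-0.0547,
    size_x_band_gap=0.0682,
    log_conc_sq=-0.0343,
    size_sq=-0.0255,
)


@dataclass(frozen=True)
class ModelObservation:
    """One (ligand, size, concentration) exposure with its measured EZ score.

    ``ez_score`` is nominally in [0, 1] and assay data always satisfy
    ``mod_ez >= 0.1``, but the exponential surface is unbounded above and
    simulated noise studies can push a reading below the mod offset, so any
    finite score is accepted.  ``mod_ez`` is derived:
    ``100 * ez_score + 0.1``.
    """

    ligand: str
    descriptors: LigandDescriptorSet
    size: float
    concentration: float
    ez_score: float
    obs_id: str = ""

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValidationError(
                f"observation {self.obs_id or self.ligand}: concentration must be > 0 ppm"
            )
        if not self.size > 0:
            raise ValidationError(f"observation {self.obs_id or self.ligand}: size must be > 0 nm")
        if not math.isfinite(self.ez_score):
            raise ValidationError(
                f"observation {self.obs_id or self.ligand}: invalid EZ score {self.ez_score}"
            )
        if not self.obs_id:
            object.__setattr__(
                self, "obs_id", f"{self.ligand}:{self.size:g}nm:{self.concentration:g}ppm"
            )

    @property
    def mod_ez(self) -> float:
        return mod_transform(self.ez_score)


def design_row(obs: ModelObservation) -> np.ndarray:
    """The ten-term design row for one observation (natural log concentration)."""
    d = obs.descriptors
    ln_c = math.log(obs.concentration)
    return np.array(
        [
            1.0,
            ln_c,
            obs.size,
            d.sasa_over_polar,
            d.refractivity,
            d.band_gap,
            ln_c * d.sasa_over_polar,
            obs.size * d.band_gap,
            ln_c**2,
            obs.size**2,
        ]
    )


def design_matrix(observations: Sequence[ModelObservation]) -> np.ndarray:
    return np.vstack([design_row(o) for o in observations])


def _linear_predictor(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = X @ beta
    if np.any(eta > _LINPRED_BOUND):
        warnings.warn(
            f"linear predictor exceeds {_LINPRED_BOUND}; clipping to avoid overflow",
            stacklevel=3,
        )
        eta = np.minimum(eta, _LINPRED_BOUND)
    return eta


def predict_mod_ez(
    coefficients: ModelCoefficients, obs: ModelObservation | Sequence[ModelObservation]
) -> float | np.ndarray:
    """Predict mod-scale EZ, ``exp(x @ beta)``; strictly positive."""
    single = isinstance(obs, ModelObservation)
    X = design_matrix([obs] if single else list(obs))
    pred = np.exp(_linear_predictor(coefficients.to_array(), X))
    return float(pred[0]) if single else pred


@dataclass(frozen=True)
class ResponseModelFit:
    """Nonlinear least-squares fit of the exponential response surface."""

    coefficients: ModelCoefficients
    standard_errors: Mapping[str, float]
    p_values: Mapping[str, float]
    r_squared: float
    r_squared_log: float
    n_used: int
    outliers_removed: tuple[str, ...]
    sse: float
    n_iterations: int

    def summary_frame(self):
        """Coefficient table: estimate, standard error, p-value per term."""
        import pandas as pd

        return pd.DataFrame(
            {
                "estimate": self.coefficients.as_dict(),
                "std_error": dict(self.standard_errors),
                "p_value": dict(self.p_values),
            }
        )


def _check_rank(X: np.ndarray) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [TERM_NAMES[k] for k in np.flatnonzero(diag < tol)]
    if bad:
        raise FitError(f"design matrix is rank deficient; collinear column(s): {bad}")


def _nls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """LM minimization of ||y - exp(X beta)||^2 from the log-linear OLS start.

    Non-positive responses (possible in untruncated simulation noise) are
    floored at the mod offset for the log-scale initialization only.
    """
    beta0, *_ = np.linalg.lstsq(X, np.log(np.where(y > 0, y, MOD_OFFSET)), rcond=None)

    def resid(beta):
        return y - np.exp(_linear_predictor(beta, X))

    def jac(beta):
        return -np.exp(_linear_predictor(beta, X))[:, None] * X

    sol = optimize.least_squares(
        resid, beta0, jac=jac, method="lm", ftol=1e-12, xtol=1e-14, gtol=1e-12,
        max_nfev=500 * len(beta0),
    )
    if not sol.success:
        raise FitError(f"nonlinear least squares did not converge: {sol.message}")
    return sol.x, resid(sol.x), 2.0 * sol.cost, sol.nfev


def _fit_once(observations: Sequence[ModelObservation]) -> ResponseModelFit:
    n = len(observations)
    p = len(TERM_NAMES)
    if n < p + 1:
        raise FitError(f"need at least {p + 1} observations, got {n}")
    X = design_matrix(observations)
    _check_rank(X)
    y = np.array([o.mod_ez for o in observations])
    beta, e, sse, nfev = _nls(X, y)
    dof = n - p
    s2 = sse / dof
    yhat = np.exp(_linear_predictor(beta, X))
    J = yhat[:, None] * X
    cov = s2 * np.linalg.inv(J.T @ J)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    sst = float(((y - y.mean()) ** 2).sum())
    pos = y > 0  # log-scale R^2 only over positive responses
    log_y = np.log(y[pos])
    log_resid = log_y - X[pos] @ beta
    log_sst = float(((log_y - log_y.mean()) ** 2).sum())
    return ResponseModelFit(
        coefficients=ModelCoefficients.from_array(beta),
        standard_errors=dict(zip(TERM_NAMES, se.tolist())),
        p_values=dict(zip(TERM_NAMES, pvals.tolist())),
        r_squared=1.0 - sse / sst,
        r_squared_log=1.0 - float((log_resid**2).sum()) / log_sst,
        n_used=n,
        outliers_removed=(),
        sse=float(sse),
        n_iterations=nfev,
    )


def fit_model(
    observations: Iterable[ModelObservation],
    *,
    remove_outliers: bool = False,
    outlier_threshold: float = 3.0,
) -> ResponseModelFit:
    """Fit the exponential response surface by nonlinear least squares.

    With ``remove_outliers=True`` a single screen-and-refit pass is applied:
    observations whose externally studentized residual exceeds the threshold
    in magnitude are dropped and the model refit once.
    """
    observations = list(observations)
    fit = _fit_once(observations)
    if remove_outliers:
        flagged = detect_outliers(fit, observations, threshold=outlier_threshold)
        if flagged:
            kept = [o for o in observations if o.obs_id not in set(flagged)]
            refit = _fit_once(kept)
            fit = ResponseModelFit(
                coefficients=refit.coefficients,
                standard_errors=refit.standard_errors,
                p_values=refit.p_values,
                r_squared=refit.r_squared,
                r_squared_log=refit.r_squared_log,
                n_used=refit.n_used,
                outliers_removed=tuple(flagged),
                sse=refit.sse,
                n_iterations=refit.n_iterations,
            )
    return fit


def detect_outliers(
    fit: ResponseModelFit,
    observations: Sequence[ModelObservation],
    *,
    threshold: float = 3.0,
) -> list[str]:
    """Flag observations with externally studentized residual |t| > threshold.

    Leverages come from the hat matrix of the linearized model (Jacobian at
    the optimum); the residual variance for each point is re-estimated with
    that point deleted.
    """
    observations = list(observations)
    X = design_matrix(observations)
    y = np.array([o.mod_ez for o in observations])
    beta = fit.coefficients.to_array()
    yhat = np.exp(_linear_predictor(beta, X))
    e = y - yhat
    # an (essentially) interpolating fit has no outliers; guards against
    # studentizing pure floating-point noise
    if np.max(np.abs(e) / np.maximum(np.abs(y), 1.0)) < 1e-8:
        return []
    J = yhat[:, None] * X
    H = J @ np.linalg.inv(J.T @ J) @ J.T
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    n, p = X.shape
    sse = float((e**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_del = (sse - e**2 / (1.0 - h)) / (n - p - 1)
        s2_del = np.maximum(s2_del, 0.0)
        t_ext = e / np.sqrt(s2_del * (1.0 - h))
        t_ext = np.where(s2_del == 0.0, np.where(e == 0.0, 0.0, np.inf * np.sign(e)), t_ext)
    return [observations[i].obs_id for i in np.flatnonzero(np.abs(t_ext) > threshold)]


def response_surface(
    coefficients: ModelCoefficients,
    descriptors: LigandDescriptorSet,
    size_grid: Sequence[float],
    conc_grid: Sequence[float],
    *,
    as_ez: bool = False,
) -> np.ndarray:
    """Predictions over a size x concentration grid for one ligand.

    Returns an array of shape ``(len(size_grid), len(conc_grid))`` on the mod
    scale, or inverse-mod-transformed to the EZ scale with ``as_ez=True``.
    """
    size_grid = [float(s) for s in size_grid]
    conc_grid = [float(c) for c in conc_grid]
    if any(s <= 0 for s in size_grid) or any(c <= 0 for c in conc_grid):
        raise ValidationError("size and concentration grids must be positive")
    out = np.empty((len(size_grid), len(conc_grid)))
    for i, size in enumerate(size_grid):
        for j, conc in enumerate(conc_grid):
            obs = ModelObservation(
                ligand=descriptors.ligand,
                descriptors=descriptors,
                size=size,
                concentration=conc,
                ez_score=0.0,
            )
            out[i, j] = predict_mod_ez(coefficients, obs)
    return (out - MOD_OFFSET) / 100.0 if as_ez else out
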