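"""Per-species negative-binomial catch regression with a log-effort offset.

The expected catch of a species in one sample is

    E[y] = days · exp(a₁ + a₂·date + a₃·rain + a₄·deadwood + a_foresttype)

with NB2 errors, Var = μ + μ²/θ. Coefficients are estimated by maximum
likelihood: iteratively reweighted least squares (Fisher scoring) for the
coefficient vector, alternating with a bounded profile maximisation over
log θ. Dummy levels with all-zero catches (complete separation — farmland
in practice) are detected, clamped to −cap on the linear-predictor scale
and flagged rather than left to diverge.

The fitter is written directly in numpy because the resampling tests in
:mod:`trapcatch.inference` refit both nested models per species for every
one of hundreds of resamples; each fit must cost well under a millisecond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from trapcatch.core_io import ForestType, ValidationError
from trapcatch.covariates import DESIGN_COLUMNS, DesignMatrix

logger = logging.getLogger(__name__)

_ETA_MAX = 40.0  # guards exp overflow; exp(40) ≈ 2.4e17 dwarfs any real catch
_MAX_STEP = 3.0  # largest coefficient move per Fisher-scoring step
_PIN_AFTER = 3  # consecutive at-cap iterations before a coefficient is pinned


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the NB2 fitter.

    cap
        Bound on each coefficient's magnitude on the linear-predictor
        scale. A coefficient pushed to the cap with the gradient still
        pointing outward is flagged as separated.
    tol / max_outer
        Outer loop (coefficients ↔ θ alternation) stops when the relative
        log-likelihood change drops below ``tol`` or after ``max_outer``
        alternations.
    theta_min / theta_max
        Profile search bounds for θ; the upper bound is effectively the
        Poisson limit.
    low_n_threshold
        Species with fewer total individuals are fitted and pooled into
        multi-species statistics but marked ``low_n`` in reports.
    """

    cap: float = 15.0
    tol: float = 1e-8
    max_outer: int = 200
    irls_tol: float = 1e-10
    irls_maxit: int = 50
    theta_min: float = 1e-2
    theta_max: float = 1e5
    theta_xatol: float = 1e-6
    low_n_threshold: int = 10


#: Cheap settings for warm-started refits inside resampling loops.
FAST_REFIT = FitConfig(tol=1e-6, max_outer=3, irls_tol=1e-8, irls_maxit=25, theta_xatol=1e-3)


@dataclass
class SpeciesFit:
    """Fitted NB2 model for one species.

    ``coefficients`` is keyed by design column name (the primary-forest
    level is the reference and is identically 0, so it has no entry).
    ``separation_flags`` names coefficients clamped at ±cap.
    """

    species: str
    coefficients: dict[str, float]
    theta: float
    loglik: float
    converged: bool
    separation_flags: set[str] = field(default_factory=set)
    se: dict[str, float] = field(default_factory=dict)
    columns: tuple[str, ...] = DESIGN_COLUMNS
    n_obs: int = 0
    total_count: int = 0
    low_n: bool = False

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.columns])


def nb_loglik(counts: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood Σᵢ log NB(yᵢ | μᵢ, θ) with Var = μ + μ²/θ."""
    y = np.asarray(counts)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(counts, dtype=float)
        if np.any(yf < 0) or np.any(yf != np.floor(yf)):
            raise ValidationError("counts must be non-negative integers")
        y = yf.astype(np.int64)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or theta <= 0:
        raise ValidationError("mu and theta must be positive")
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _loglik_raw(y: np.ndarray, eta: np.ndarray, theta: float) -> float:
    """nb_loglik without validation, for inner loops; eta already clipped."""
    mu = np.exp(eta)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * (eta - np.log(theta + mu))
        )
    )


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    beta: np.ndarray,
    theta: float,
    fixed: np.ndarray,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fisher scoring for β given θ, with coefficient capping.

    ``fixed`` is a boolean mask of clamped columns (their contribution
    moves to the offset). Returns (beta, fixed, converged); newly clamped
    columns are added to ``fixed``.
    """
    cap = config.cap
    n, p = X.shape
    fixed = fixed.copy()
    beta = beta.copy()
    converged = False
    at_cap = np.zeros(p, dtype=int)
    for _ in range(config.irls_maxit):
        free = ~fixed
        if not free.any():
            converged = True
            break
        off_eff = offset + X[:, fixed] @ beta[fixed] if fixed.any() else offset
        Xf = X[:, free]
        eta = np.clip(off_eff + Xf @ beta[free], -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = mu / (1.0 + mu / theta)
        z = (eta - off_eff) + (y - mu) / mu
        Xw = Xf * W[:, None]
        try:
            new = np.linalg.solve(Xw.T @ Xf, Xw.T @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(Xw.T @ Xf, Xw.T @ z, rcond=None)[0]
        # damp Fisher steps: overshoot past the cap must not be mistaken
        # for separation, so clamp first and only pin after the estimate
        # sits at the cap for several consecutive iterations
        step = new - beta[free]
        m = np.max(np.abs(step))
        if m > _MAX_STEP:
            step *= _MAX_STEP / m
        cand = beta[free] + step
        over_free = np.abs(cand) > cap
        beta[free] = np.clip(cand, -cap, cap)
        over = np.zeros(p, dtype=bool)
        over[free] = over_free
        at_cap = np.where(over, at_cap + 1, 0)
        newly_fixed = at_cap >= _PIN_AFTER
        if newly_fixed.any():
            fixed |= newly_fixed
            continue
        if np.max(np.abs(step)) < config.irls_tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    return beta, fixed, converged


def _profile_theta(y: np.ndarray, eta: np.ndarray, config: FitConfig) -> float:
    lo, hi = np.log(config.theta_min), np.log(config.theta_max)
    res = minimize_scalar(
        lambda lt: -_loglik_raw(y, eta, float(np.exp(lt))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": config.theta_xatol},
    )
    return float(np.exp(res.x))


def _gradient(X, y, offset, beta, theta):
    eta = np.clip(offset + X @ beta, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    return X.T @ ((y - mu) * theta / (theta + mu))


def fit_matrix(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    colnames: Sequence[str],
    config: FitConfig | None = None,
    warm_beta: np.ndarray | None = None,
    warm_theta: float | None = None,
    species: str = "",
) -> SpeciesFit:
    """Fit the NB2 regression on raw arrays.

    This is the workhorse behind :func:`fit_species`; the inference module
    calls it directly with reduced or merged design matrices and warm
    starts.
    """
    config = config or FitConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n, p = X.shape
    colnames = tuple(colnames)
    cap = config.cap

    fixed = np.zeros(p, dtype=bool)
    beta = np.zeros(p)
    flags: set[str] = set()

    if y.sum() == 0:
        # Complete separation of the intercept: every observation is a zero.
        beta[colnames.index("intercept")] = -cap
        eta = np.clip(offset + X @ beta, -_ETA_MAX, _ETA_MAX)
        theta = 1.0
        return SpeciesFit(
            species=species,
            coefficients=dict(zip(colnames, beta)),
            theta=theta,
            loglik=_loglik_raw(y, eta, theta),
            converged=True,
            separation_flags={"intercept"},
            columns=colnames,
            n_obs=n,
            total_count=0,
        )

    # Structural zeros: a 0/1 dummy whose "on" rows catch nothing in total
    # drives its coefficient to -inf; clamp it up front.
    for j, name in enumerate(colnames):
        col = X[:, j]
        if name != "intercept" and np.array_equal(col, col.astype(bool)) and col.any():
            if y[col > 0].sum() == 0:
                beta[j] = -cap
                fixed[j] = True
                flags.add(name)

    if warm_beta is not None and len(warm_beta) == p:
        free0 = ~fixed
        beta[free0] = np.clip(np.asarray(warm_beta, dtype=float)[free0], -cap, cap)
    elif "intercept" in colnames:
        rate = max(y.sum() / np.exp(offset).sum(), 1e-8)
        beta[colnames.index("intercept")] = min(max(np.log(rate), -cap), cap)

    theta = warm_theta if warm_theta is not None else 1e4  # ≈ Poisson start
    theta = float(np.clip(theta, config.theta_min, config.theta_max))

    ll = -np.inf
    converged = False
    for _ in range(config.max_outer):
        beta, fixed, irls_ok = _irls(X, y, offset, beta, theta, fixed, config)
        eta = np.clip(offset + X @ beta, -_ETA_MAX, _ETA_MAX)
        theta = _profile_theta(y, eta, config)
        new_ll = _loglik_raw(y, eta, theta)
        if irls_ok and abs(new_ll - ll) < config.tol * (1.0 + abs(new_ll)):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        logger.warning("fit for %s did not converge within %d alternations", species or "<species>", config.max_outer)

    # A coefficient at the cap with the gradient still pushing outward is a
    # separation artefact, not an interior maximum.
    grad = _gradient(X, y, offset, beta, theta)
    for j, name in enumerate(colnames):
        if abs(beta[j]) >= cap - 1e-9 and np.sign(grad[j]) == np.sign(beta[j]) or fixed[j]:
            if abs(beta[j]) >= cap - 1e-9:
                flags.add(name)

    # Standard errors from the expected information of the free columns.
    se: dict[str, float] = {}
    free = np.array([name not in flags for name in colnames])
    if free.any():
        eta = np.clip(offset + X @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = mu / (1.0 + mu / theta)
        Xf = X[:, free]
        info = (Xf * W[:, None]).T @ Xf
        try:
            cov = np.linalg.inv(info)
            for k, name in enumerate(np.array(colnames)[free]):
                if cov[k, k] > 0:
                    se[str(name)] = float(np.sqrt(cov[k, k]))
        except np.linalg.LinAlgError:
            pass

    total = int(y.sum())
    return SpeciesFit(
        species=species,
        coefficients={name: float(b) for name, b in zip(colnames, beta)},
        theta=theta,
        loglik=ll,
        converged=converged,
        separation_flags=flags,
        se=se,
        columns=colnames,
        n_obs=n,
        total_count=total,
        low_n=total < config.low_n_threshold,
    )


def fit_species(
    design: DesignMatrix,
    species: str,
    config: FitConfig | None = None,
    columns: Sequence[str] | None = None,
) -> SpeciesFit:
    """Fit one species' catch model on an assembled design.

    Parameters
    ----------
    design
        The per-sample design (covariates, offset, counts).
    species
        Species name; must be in ``design.species``.
    columns
        Optional subset of :data:`~trapcatch.covariates.DESIGN_COLUMNS`
        (used for null models in likelihood-ratio tests). Defaults to the
        full set.
    """
    if species not in design.species:
        raise ValidationError(f"species {species!r} not in design")
    cols = tuple(columns) if columns is not None else DESIGN_COLUMNS
    unknown = [c for c in cols if c not in DESIGN_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown design column(s) {unknown}")
    Xfull = design.model_matrix()
    idx = [DESIGN_COLUMNS.index(c) for c in cols]
    y = design.counts_matrix()[:, design.species.index(species)]
    return fit_matrix(
        Xfull[:, idx], y, design.offsets(), cols, config=config, species=species
    )


def lr_statistic(fit_alt: SpeciesFit, fit_null: SpeciesFit) -> float:
    """Likelihood ratio 2·(ℓ_alt − ℓ_null) between nested fits.

    The null model's columns must be expressible within the alternative's
    (a subset, or merged dummies); both must be fitted on the same rows.
    Tiny negative values from finite optimisation tolerance are clipped to
    0 (and logged).
    """
    if fit_alt.n_obs != fit_null.n_obs or fit_alt.total_count != fit_null.total_count:
        raise ValidationError("fits compare different observation sets")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < 0:
        if stat < -1e-4:
            logger.warning(
                "negative likelihood ratio %.3g for %s clipped to 0 "
                "(null fit beat the alternative; check convergence)",
                stat, fit_alt.species,
            )
        else:
            logger.debug("clipping tiny negative LR %.3g to 0", stat)
        stat = 0.0
    return stat


def predict_catch(
    fit: SpeciesFit | Mapping[str, float],
    date: float,
    rain: float,
    deadwood: float,
    forest_type: ForestType | str,
    days: float,
) -> float:
    """Expected catch: days · exp(a₁ + a₂·date + a₃·rain + a₄·deadwood + a_ft).

    ``fit`` may be a :class:`SpeciesFit` or a plain coefficient mapping
    keyed like the design columns. Primary forest is the reference level
    (a_primary = 0).
    """
    coefs = fit.coefficients if isinstance(fit, SpeciesFit) else dict(fit)
    ft = ForestType(forest_type)
    if days < 0:
        raise ValidationError("effort days must be non-negative")
    eta = (
        coefs.get("intercept", 0.0)
        + coefs.get("date", 0.0) * date
        + coefs.get("rain", 0.0) * rain
        + coefs.get("deadwood", 0.0) * deadwood
        + (0.0 if ft is ForestType.PRIMARY else coefs[ft.value])
    )
    return days * float(np.exp(eta))


# ---------------------------------------------------------------------------
# Batched fitting across resampled count matrices
#
# The resampling tests refit the same design against hundreds of count
# vectors; doing those fits one at a time in Python is the bottleneck, so
# the whole batch advances together: one einsum builds every weighted
# normal-equation system, one batched solve updates every coefficient
# vector, and the profile-theta Newton step runs on (B, n) arrays.


def _batch_loglik(Y: np.ndarray, eta: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood per batch row; Y, eta (B, n); theta (B, 1) -> (B,)."""
    mu = np.exp(eta)
    return (
        gammaln(Y + theta)
        - gammaln(theta)
        - gammaln(Y + 1)
        + theta * np.log(theta / (theta + mu))
        + Y * (eta - np.log(theta + mu))
    ).sum(axis=1)


def _batch_irls(
    X: np.ndarray,
    Y: np.ndarray,
    offset: np.ndarray,
    beta: np.ndarray,
    theta: np.ndarray,
    pinned: np.ndarray,
    pinval: np.ndarray,
    cap: float,
    n_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher-scoring iterations on a (B, n) batch.

    ``pinned``/``pinval`` (B, p) hold coefficients frozen (structural
    zeros, capped values): their rows and columns of each normal-equation
    system are replaced so the solution passes through the pinned value.
    Coefficients that leave [-cap, cap] are clamped and pinned for the
    remaining iterations. Returns (beta, pinned, pinval).
    """
    B, p = beta.shape
    eye = np.eye(p)
    at_cap = np.zeros((B, p), dtype=np.int8)
    for _ in range(n_iter):
        beta = np.where(pinned, pinval, beta)
        eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = mu / (1.0 + mu / theta)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        A = np.einsum("bn,np,nq->bpq", W, X, X, optimize=True)
        rhs = np.einsum("bn,bn,np->bp", W, z, X, optimize=True)
        A += 1e-9 * eye[None, :, :]
        if pinned.any():
            c = np.where(pinned, pinval, 0.0)
            rhs -= np.einsum("bpq,bq->bp", A, c)
            mask = pinned[:, None, :] | pinned[:, :, None]
            A = np.where(mask, 0.0, A)
            A[np.broadcast_to(eye[None].astype(bool), A.shape) & pinned[:, :, None]] = 1.0
            rhs = np.where(pinned, pinval, rhs)
        new = np.linalg.solve(A, rhs[..., None])[..., 0]
        # damped step, clamp-then-pin as in the scalar fitter
        step = new - beta
        m = np.max(np.abs(step), axis=1, keepdims=True)
        scale = np.where(m > _MAX_STEP, _MAX_STEP / np.where(m > 0, m, 1.0), 1.0)
        cand = beta + step * scale
        over = (~pinned) & (np.abs(cand) > cap)
        beta = np.clip(cand, -cap, cap)
        at_cap = np.where(over, at_cap + 1, 0)
        newly = (~pinned) & (at_cap >= _PIN_AFTER)
        if newly.any():
            pinval = np.where(newly, np.sign(beta) * cap, pinval)
            pinned = pinned | newly
            beta = np.where(pinned, pinval, beta)
    return beta, pinned, pinval


def _batch_theta_newton(
    Y: np.ndarray, eta: np.ndarray, theta: np.ndarray, config: FitConfig, n_iter: int = 4
) -> np.ndarray:
    """Profile-theta secant steps on log theta for a (B, n) batch.

    Finds the zero of g(t) = θ·∂ℓ/∂θ at θ = eᵗ by the secant method; only
    digamma is needed (trigamma through scipy is far more expensive).
    """
    from scipy.special import psi

    mu = np.exp(eta)
    lo, hi = np.log(config.theta_min), np.log(config.theta_max)

    def g(t: np.ndarray) -> np.ndarray:
        th = np.exp(t)
        return th[:, 0] * (
            psi(Y + th) - psi(th) + np.log(th) + 1.0
            - np.log(th + mu) - (Y + th) / (th + mu)
        ).sum(axis=1)

    t0 = np.clip(np.log(theta), lo, hi)
    t1 = np.clip(t0 + 0.25, lo, hi)
    g0, g1 = g(t0), g(t1)
    for _ in range(n_iter):
        denom = g1 - g0
        safe = np.abs(denom) > 1e-12
        step = np.where(safe, -g1 * (t1[:, 0] - t0[:, 0]) / np.where(safe, denom, 1.0), 0.0)
        t2 = np.clip(t1 + np.clip(step, -3.0, 3.0)[:, None], lo, hi)
        t0, g0 = t1, g1
        t1 = t2
        g1 = g(t1)
    # keep whichever endpoint has the smaller score residual
    better0 = np.abs(g0) < np.abs(g1)
    return np.exp(np.where(better0[:, None], t0, t1))


def _batch_pins(X: np.ndarray, Y: np.ndarray, colnames: tuple[str, ...], cap: float):
    """Initial pins: all-zero batches and structurally zero dummy levels."""
    B, n = Y.shape
    p = X.shape[1]
    pinned = np.zeros((B, p), dtype=bool)
    pinval = np.zeros((B, p))
    allzero = Y.sum(axis=1) == 0
    if allzero.any():
        pinned[allzero, :] = True
        if "intercept" in colnames:
            pinval[allzero, colnames.index("intercept")] = -cap
    for j, name in enumerate(colnames):
        col = X[:, j]
        if name != "intercept" and np.array_equal(col, col.astype(bool)) and col.any():
            zero_level = Y[:, col > 0].sum(axis=1) == 0
            mask = zero_level & ~allzero
            pinned[mask, j] = True
            pinval[mask, j] = -cap
    return pinned, pinval


def fit_batch(
    X: np.ndarray,
    Y: np.ndarray,
    offset: np.ndarray,
    colnames: Sequence[str],
    warm_beta: np.ndarray,
    warm_theta: float | np.ndarray,
    config: FitConfig | None = None,
    schedule: tuple[int, int, int] = (6, 3, 4),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one species' model against every count vector of a batch.

    Y is (B, n); all batch members share X and offset. ``warm_beta`` may
    be one vector (p,) or per-batch (B, p); ``warm_theta`` a scalar or
    (B,). The iteration budget is fixed (IRLS, theta-Newton, IRLS again
    per ``schedule``) rather than adaptive, which is what makes the batch
    advance in lock step. Returns (beta (B, p), theta (B,), loglik (B,)).
    """
    config = config or FitConfig()
    colnames = tuple(colnames)
    Y = np.asarray(Y, dtype=np.float64)
    B = Y.shape[0]
    p = X.shape[1]
    beta = np.broadcast_to(
        np.clip(np.asarray(warm_beta, dtype=float), -config.cap, config.cap), (B, p)
    ).copy()
    theta = np.broadcast_to(
        np.clip(np.asarray(warm_theta, dtype=float), config.theta_min, config.theta_max),
        (B,),
    ).reshape(B, 1).copy()
    pinned, pinval = _batch_pins(X, Y, colnames, config.cap)
    beta = np.where(pinned, pinval, beta)

    it1, it_th, it2 = schedule
    beta, pinned, pinval = _batch_irls(X, Y, offset, beta, theta, pinned, pinval, config.cap, it1)
    eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_MAX, _ETA_MAX)
    theta = _batch_theta_newton(Y, eta, theta, config, n_iter=it_th)
    beta, pinned, pinval = _batch_irls(X, Y, offset, beta, theta, pinned, pinval, config.cap, it2)
    eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_MAX, _ETA_MAX)
    ll = _batch_loglik(Y, eta, theta)
    return beta, theta[:, 0], ll
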