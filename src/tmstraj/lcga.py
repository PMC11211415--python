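"""Latent class growth analysis for ordinal session ratings.

Model.  Subject ``i`` belongs to one of ``G`` latent classes.  Class
membership follows a multinomial logit with intercepts ``zeta_g`` (reference
class fixed at 0) and optional subject covariates.  Within class ``g`` the
rating at session ``t`` is driven by a cubic latent process on scaled time
``u = t/20``::

    lambda_g(u) = beta_g0 + beta_g1 u + beta_g2 u^2 + beta_g3 u^3

observed through a cumulative-probit ("thresholds") link with ``M - 1``
strictly increasing cut-points ``tau``::

    P(Y_it = m | g) = Phi(tau_m - lambda_g(u)) - Phi(tau_{m-1} - lambda_g(u))

with ``tau_0 = -inf``, ``tau_M = +inf`` and residual scale fixed at 1.  For
identifiability ``tau_1`` is fixed at 0 and all class intercepts are free;
this is a reparameterisation of the usual ordinal-mixture likelihood and
changes nothing observable.

Estimation is multi-start maximum likelihood: the one-class solution seeds
start 0 (replicated across classes, zero membership logits) and further
starts perturb the class intercepts and membership logits with seeded
Gaussian noise.  The observed-data log-likelihood is maximised by L-BFGS
with analytic gradients; an EM mode is provided as a cross-check.
Convergence is declared only when the parameter-change, likelihood-change
and scaled-gradient criteria (convB / convL / convG) are all met.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_softmax, logsumexp, softmax
from scipy.stats import norm

from .ingest import ratings_to_matrix

__all__ = [
    "LCGAParams",
    "LCGAFit",
    "FitSettings",
    "category_prob",
    "subject_loglik",
    "fit_lcga",
    "fit_lcga_em",
    "posterior_probs",
    "predict_trajectory",
    "wald_test_membership",
    "observed_information",
]

_TIME_SCALE = 20.0
_P_FLOOR = 1e-300
_RATIO_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# parameters


@dataclass
class LCGAParams:
    """Parameters of a fitted (or hypothesised) ordinal trajectory mixture."""

    betas: np.ndarray  # (G, 4) cubic coefficients per class
    tau: np.ndarray  # (M-1,) strictly increasing thresholds, tau[0] == 0
    zeta: np.ndarray | None = None  # (G-1,) membership logits, class 0 = reference
    gamma: np.ndarray | None = None  # (G-1, C) membership covariate effects

    def __post_init__(self):
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        self.tau = np.asarray(self.tau, dtype=float)
        if self.zeta is None:
            self.zeta = np.zeros(self.G - 1)
        self.zeta = np.asarray(self.zeta, dtype=float)
        if self.gamma is not None:
            self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if abs(self.tau[0]) > 1e-12:
            raise ValueError("tau[0] is fixed at 0 for identifiability")

    @property
    def G(self) -> int:
        return self.betas.shape[0]

    @property
    def M(self) -> int:
        return len(self.tau) + 1

    @property
    def pi(self) -> np.ndarray:
        """Marginal class-membership probabilities (covariates at 0)."""
        eta = np.concatenate([[0.0], self.zeta])
        return softmax(eta)

    def latent(self, sessions) -> np.ndarray:
        """lambda_g(u(t)) for each class; returns (G, T)."""
        u = np.asarray(sessions, dtype=float) / _TIME_SCALE
        design = np.vander(u, 4, increasing=True)
        return self.betas @ design.T

    def n_params(self, n_covariates: int | None = None) -> int:
        c = 0 if self.gamma is None else self.gamma.shape[1]
        if n_covariates is not None:
            c = n_covariates
        return (self.G - 1) * (1 + c) + 4 * self.G + (self.M - 2)

    def to_dict(self) -> dict:
        return {
            "betas": self.betas.tolist(),
            "tau": self.tau.tolist(),
            "zeta": self.zeta.tolist(),
            "gamma": None if self.gamma is None else self.gamma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCGAParams":
        gamma = d.get("gamma")
        return cls(
            betas=np.asarray(d["betas"]),
            tau=np.asarray(d["tau"]),
            zeta=np.asarray(d["zeta"]),
            gamma=None if gamma is None else np.asarray(gamma),
        )


@dataclass
class FitSettings:
    n_starts: int = 100
    max_iter: int = 1000
    conv_b: float = 1e-4
    conv_l: float = 1e-4
    conv_g: float = 1e-4
    seed: int = 0
    start_scale: float = 1.0  # SD of intercept/logit perturbations
    shape_scale: float = 4.0  # SD of slope/curvature perturbations


@dataclass
class LCGAFit:
    """A fitted mixture: parameters, likelihood and classification."""

    params: LCGAParams
    loglik: float
    n_params: int
    n_subjects: int
    posteriors: np.ndarray  # (N, G)
    assignments: np.ndarray  # modal class per subject (0-based)
    subject_ids: np.ndarray
    converged: bool
    convergence_flags: dict  # {"conv_b": bool, "conv_l": bool, "conv_g": bool}
    n_iterations: int
    best_start_index: int
    start_logliks: list = field(default_factory=list)
    settings: FitSettings | None = None
    sessions: np.ndarray | None = None

    @property
    def G(self) -> int:
        return self.params.G

    @property
    def class_fractions(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.G) / self.n_subjects

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_subjects": self.n_subjects,
            "converged": bool(self.converged),
            "convergence_flags": {k: bool(v) for k, v in self.convergence_flags.items()},
            "n_iterations": int(self.n_iterations),
            "best_start_index": int(self.best_start_index),
            "start_logliks": [float(v) for v in self.start_logliks],
            "sessions": None if self.sessions is None else list(map(float, self.sessions)),
            "settings": None
            if self.settings is None
            else {
                "n_starts": self.settings.n_starts,
                "max_iter": self.settings.max_iter,
                "conv_b": self.settings.conv_b,
                "conv_l": self.settings.conv_l,
                "conv_g": self.settings.conv_g,
                "seed": self.settings.seed,
                "start_scale": self.settings.start_scale,
                "shape_scale": self.settings.shape_scale,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def posteriors_frame(self) -> pd.DataFrame:
        cols = {f"p_{g + 1}": self.posteriors[:, g] for g in range(self.G)}
        return pd.DataFrame(
            {"subject_id": self.subject_ids, **cols, "assigned_class": self.assignments}
        )


# ---------------------------------------------------------------------------
# probabilities and likelihood


def _cat_prob_table(params: LCGAParams, sessions) -> np.ndarray:
    """P(Y = m | g, t) as an array of shape (G, T, M)."""
    lam = params.latent(sessions)  # (G, T)
    a = params.tau[:, None, None] - lam[None]  # (M-1, G, T)
    cdf = norm.cdf(a)
    G, T = lam.shape
    cum = np.concatenate([np.zeros((1, G, T)), cdf, np.ones((1, G, T))])
    return np.moveaxis(np.diff(cum, axis=0), 0, 2)  # (G, T, M)


def category_prob(params: LCGAParams, g: int, t: float, m: int) -> float:
    """P(Y = m | class g, session t) under the cumulative-probit link.

    ``m`` is 1-based (1..M).
    """
    if not 1 <= m <= params.M:
        raise ValueError(f"category m={m} outside 1..{params.M}")
    table = _cat_prob_table(params, [t])
    return float(table[g, 0, m - 1])


def subject_loglik(params: LCGAParams, sessions, values, covariates=None) -> float:
    """Observed-data log-likelihood contribution of one rating series.

    ``values`` holds 1-based categories aligned with ``sessions``; NaN marks
    a missing session, which contributes nothing.  A series with no observed
    sessions contributes 0 (with a warning).
    """
    sessions = np.asarray(sessions, dtype=float)
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    if not obs.any():
        warnings.warn("rating series with zero observed sessions contributes 0")
        return 0.0
    table = _cat_prob_table(params, sessions[obs])  # (G, n_obs, M)
    idx = values[obs].astype(int) - 1
    logp = np.log(np.clip(table[:, np.arange(obs.sum()), idx], _P_FLOOR, None))
    logpi = _log_prior(params, covariates)
    return float(logsumexp(logpi.ravel() + logp.sum(axis=1)))


def _log_prior(params: LCGAParams, covariates=None) -> np.ndarray:
    """log pi (shape (1, G) or (N, G) with covariates)."""
    eta = np.concatenate([[0.0], params.zeta])[None, :]
    if params.gamma is not None and covariates is not None:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        eta = eta + np.concatenate(
            [np.zeros((X.shape[0], 1)), X @ params.gamma.T], axis=1
        )
    return log_softmax(eta, axis=1)


# ---------------------------------------------------------------------------
# encoded data and the packed objective


class _Encoded:
    """One-hot encoded rating matrix for fast likelihood evaluation."""

    def __init__(self, Y: np.ndarray, sessions: np.ndarray, M: int, covariates=None):
        Y = np.asarray(Y, dtype=float)
        self.N, self.T = Y.shape
        self.M = M
        self.sessions = np.asarray(sessions, dtype=float)
        u = self.sessions / _TIME_SCALE
        self.U = np.vander(u, 4, increasing=True)  # (T, 4)
        X = np.zeros((self.N, self.T * M))
        i, t = np.nonzero(~np.isnan(Y))
        m = Y[i, t].astype(int) - 1
        if np.any((m < 0) | (m >= M)):
            raise ValueError(f"categories outside 1..{M}")
        X[i, t * M + m] = 1.0
        self.X = X
        self.Xcov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
        self.C = 0 if self.Xcov is None else self.Xcov.shape[1]


def _unpack(x: np.ndarray, G: int, M: int, C: int):
    k = G - 1
    zeta = x[:k]
    gamma = x[k : k + k * C].reshape(k, C) if C else None
    betas = x[k + k * C : k + k * C + 4 * G].reshape(G, 4)
    deltas = x[k + k * C + 4 * G :]
    tau = np.concatenate([[0.0], np.cumsum(deltas**2)])
    return zeta, gamma, betas, deltas, tau


def _pack(params: LCGAParams, C: int) -> np.ndarray:
    deltas = np.sqrt(np.diff(params.tau))
    parts = [params.zeta]
    if C:
        gamma = params.gamma if params.gamma is not None else np.zeros((params.G - 1, C))
        parts.append(gamma.ravel())
    parts += [params.betas.ravel(), deltas]
    return np.concatenate(parts)


def _nll_grad(x: np.ndarray, data: _Encoded, G: int):
    """Negative log-likelihood and its analytic gradient."""
    M, T, N = data.M, data.T, data.N
    zeta, gamma, betas, deltas, tau = _unpack(x, G, M, data.C)

    lam = betas @ data.U.T  # (G, T)
    a = tau[:, None, None] - lam[None]  # (M-1, G, T)
    cdf = norm.cdf(a)
    pdf = norm.pdf(a)
    cum = np.concatenate([np.zeros((1, G, T)), cdf, np.ones((1, G, T))])
    P = np.diff(cum, axis=0)  # (M, G, T)
    pdf_full = np.concatenate([np.zeros((1, G, T)), pdf, np.zeros((1, G, T))])  # (M+1, G, T)
    logP = np.log(np.clip(P, _P_FLOOR, None))

    L = np.moveaxis(logP, 0, 2).reshape(G, T * M)  # (G, T*M)
    s = data.X @ L.T  # (N, G)

    eta = np.concatenate([[0.0], zeta])[None, :].repeat(N, axis=0)
    if data.C:
        eta[:, 1:] += data.Xcov @ gamma.T
    logpi = log_softmax(eta, axis=1)
    joint = logpi + s
    ll_i = logsumexp(joint, axis=1)
    nll = -float(ll_i.sum())

    # gradient
    w = np.exp(joint - ll_i[:, None])  # posteriors (N, G)
    W = (w.T @ data.X).reshape(G, T, M)  # soft counts per (g, t, m)
    Pr = np.clip(P, _RATIO_FLOOR, None)  # (M, G, T)
    Wm = np.moveaxis(W, 2, 0)  # (M, G, T)

    # d logP_m / d lambda = (phi_{m-1} - phi_m) / P_m  (phi at tau_{m-1}, tau_m)
    D = (Wm * (pdf_full[:-1] - pdf_full[1:]) / Pr).sum(axis=0)  # (G, T)
    grad_betas = -(D @ data.U)  # (G, 4)

    ratio = Wm / Pr  # (M, G, T)
    # d NLL / d tau_j, finite thresholds j = 1..M-1 (1-based)
    grad_tau = np.array(
        [-np.sum(pdf[j - 1] * (ratio[j - 1] - ratio[j])) for j in range(1, M)]
    )
    # tau_j = sum_{k<j} delta_k^2 (free from j = 2): chain rule
    tail = np.cumsum(grad_tau[::-1])[::-1]  # tail[j-1] = sum_{l>=j} grad_tau_l
    grad_deltas = 2.0 * deltas * tail[1:]

    pi = np.exp(logpi)
    diff = pi - w  # (N, G)
    grad_zeta = diff[:, 1:].sum(axis=0)
    parts = [grad_zeta]
    if data.C:
        parts.append((diff[:, 1:].T @ data.Xcov).ravel())
    parts += [grad_betas.ravel(), grad_deltas]
    return nll, np.concatenate(parts)


# ---------------------------------------------------------------------------
# fitting


def _coerce_data(data):
    if isinstance(data, pd.DataFrame):
        Y, sessions, ids = ratings_to_matrix(data)
    else:
        Y, sessions = data
        Y = np.asarray(Y, dtype=float)
        sessions = np.asarray(sessions, dtype=float)
        ids = np.arange(Y.shape[0])
    return Y, sessions, ids


@dataclass
class _StartResult:
    x: np.ndarray
    fun: float
    nit: int
    conv_b: bool
    conv_l: bool
    hessian: np.ndarray | None = None


class _EarlyStop:
    """Stops L-BFGS once the parameter- and likelihood-change criteria hold."""

    def __init__(self, data, G, conv_b, conv_l):
        self.data, self.G = data, G
        self.conv_b, self.conv_l = conv_b, conv_l
        self.x_prev = None
        self.f_prev = None
        self.met = False
        self.nit = 0

    def __call__(self, xk):
        self.nit += 1
        f = _nll_grad(xk, self.data, self.G)[0]
        if self.x_prev is not None:
            if (
                np.max(np.abs(xk - self.x_prev)) < self.conv_b
                and abs(f - self.f_prev) < self.conv_l
            ):
                self.met = True
                self.x_prev, self.f_prev = np.array(xk), f
                raise StopIteration
        self.x_prev, self.f_prev = np.array(xk), f


def _optimize_one(x0, data, G, settings: FitSettings) -> _StartResult:
    """Quasi-Newton pass with the reference convergence rules.

    L-BFGS runs until convB and convL are jointly met between accepted
    iterates; if it stalls on a flat ridge first (tiny likelihood change,
    parameter steps above convB), a Newton polish with the observed-
    information Hessian finishes the job within the iteration budget.
    """
    stopper = _EarlyStop(data, G, settings.conv_b, settings.conv_l)
    res = optimize.minimize(
        _nll_grad,
        x0,
        args=(data, G),
        jac=True,
        method="L-BFGS-B",
        callback=stopper,
        options={"maxiter": settings.max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    x, f = res.x, float(res.fun)
    nit = stopper.nit
    conv_b = conv_l = stopper.met
    if not stopper.met and res.nit <= 1:
        conv_b = conv_l = True  # converged at (or next to) the starting point
    H = None
    if not (conv_b and conv_l):
        x, f, H, extra, conv_b, conv_l = _newton_polish(
            x, f, data, G, settings, budget=settings.max_iter - nit
        )
        nit += extra
    return _StartResult(x=x, fun=f, nit=nit, conv_b=conv_b, conv_l=conv_l, hessian=H)


def _newton_polish(x, f, data, G, settings: FitSettings, budget: int, max_steps: int = 10):
    """Damped Newton steps on the NLL; returns final Hessian for reuse."""
    conv_b = conv_l = False
    H = None
    steps = 0
    for _ in range(min(max_steps, max(budget, 0))):
        H = _num_hessian(x, data, G)
        g = _nll_grad(x, data, G)[1]
        ridge = 0.0
        for _ in range(8):
            try:
                step = np.linalg.solve(H + ridge * np.eye(len(x)), -g)
                break
            except np.linalg.LinAlgError:
                ridge = max(2 * ridge, 1e-6)
        else:  # pragma: no cover
            break
        alpha = 1.0
        for _ in range(20):
            f_new = _nll_grad(x + alpha * step, data, G)[0]
            if f_new <= f:
                break
            alpha /= 2
        else:
            break
        steps += 1
        dx = np.max(np.abs(alpha * step))
        df = f - f_new
        x = x + alpha * step
        f = f_new
        if dx < settings.conv_b and df < settings.conv_l:
            conv_b = conv_l = True
            break
    return x, f, H, steps, conv_b, conv_l


def _conv_g_criterion(x, data, G, settings: FitSettings, H=None):
    """lcmm-style scaled-gradient criterion g' H^-1 g / n_params."""
    if H is None:
        H = _num_hessian(x, data, G)
    _, g = _nll_grad(x, data, G)
    try:
        hg = np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        hg = np.linalg.lstsq(H, g, rcond=None)[0]
    crit = abs(float(g @ hg)) / len(x)
    return crit < settings.conv_g, H


def _num_hessian(x, data, G, step=1e-5):
    """Hessian of the NLL via central differences of the analytic gradient."""
    n = len(x)
    H = np.zeros((n, n))
    for j in range(n):
        h = step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        gp = _nll_grad(xp, data, G)[1]
        gm = _nll_grad(xm, data, G)[1]
        H[:, j] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def _split_start(warm: "LCGAFit", enc: "_Encoded") -> np.ndarray:
    """Start vector for G classes from a (G-1)-class fit.

    The largest modal class is duplicated with intercepts nudged +/-0.5 and
    its membership mass halved; thresholds carry over unchanged.
    """
    p = warm.params
    c = int(np.argmax(warm.class_fractions))
    betas = np.insert(p.betas, c + 1, p.betas[c], axis=0)
    betas[c, 0] -= 0.5
    betas[c + 1, 0] += 0.5
    eta = np.concatenate([[0.0], p.zeta])
    eta = np.insert(eta, c + 1, eta[c])
    eta[c] -= np.log(2.0)
    eta[c + 1] -= np.log(2.0)
    zeta = eta[1:] - eta[0]
    parts = [zeta]
    if enc.C:
        parts.append(np.zeros((warm.G) * enc.C))
    parts += [betas.ravel(), np.sqrt(np.diff(p.tau))]
    return np.concatenate(parts)


def _fit_one_class(data: _Encoded, settings: FitSettings) -> _StartResult:
    x0 = np.concatenate([[0.5, 0.0, 0.0, 0.0], np.ones(data.M - 2)])
    return _optimize_one(x0, data, 1, settings)


def _canonical_order(params: LCGAParams) -> np.ndarray:
    """Classes sorted by end-of-course latent level, best first."""
    lam_end = params.latent([_TIME_SCALE])[:, 0]
    return np.argsort(-lam_end, kind="stable")


def _permute_params(params: LCGAParams, order: np.ndarray) -> LCGAParams:
    eta = np.concatenate([[0.0], params.zeta])[order]
    zeta = eta[1:] - eta[0]
    gamma = None
    if params.gamma is not None:
        gfull = np.concatenate(
            [np.zeros((1, params.gamma.shape[1])), params.gamma]
        )[order]
        gamma = gfull[1:] - gfull[0]
    return LCGAParams(
        betas=params.betas[order], tau=params.tau.copy(), zeta=zeta, gamma=gamma
    )


def fit_lcga(
    data,
    G: int,
    settings: FitSettings | None = None,
    covariates=None,
    n_categories: int = 4,
    method: str = "qn",
    warm_start: "LCGAFit | None" = None,
    **overrides,
) -> LCGAFit:
    """Fit a G-class ordinal trajectory mixture by multi-start ML.

    Parameters
    ----------
    data
        Recoded long ratings table (``subject_id``/``session``/``rating``)
        or a ``(Y, sessions)`` pair with ``Y`` an N x T category matrix
        (NaN = missing).
    G
        Number of latent classes (>= 1; G = 1 uses a single deterministic
        start).
    settings
        Multi-start and convergence settings; keyword overrides such as
        ``n_starts=20`` or ``seed=3`` are applied on top.
    covariates
        Optional N x C matrix entering the class-membership model.
    method
        ``"qn"`` (quasi-Newton, default) or ``"em"`` (cross-check mode, see
        :func:`fit_lcga_em`).
    warm_start
        Optional fitted (G-1)-class model.  Adds one deterministic start
        that splits the warm fit's largest class in two — random
        perturbations of the one-class solution occasionally miss optima
        whose classes differ mainly in shape, and the split start makes
        class enumeration robust to that.

    Returns the best solution across starts (highest log-likelihood among
    converged starts, falling back to the overall best with its convergence
    state reported honestly).
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    settings = settings or FitSettings()
    if overrides:
        settings = FitSettings(**{**settings.__dict__, **overrides})
    if method == "em":
        return fit_lcga_em(data, G, settings=settings, n_categories=n_categories)
    if method != "qn":
        raise ValueError(f"unknown method {method!r}")

    Y, sessions, ids = _coerce_data(data)
    enc = _Encoded(Y, sessions, n_categories, covariates)
    one = _fit_one_class(_Encoded(Y, sessions, n_categories), settings)
    beta1 = one.x[:4]
    delta1 = one.x[4:]

    if G == 1:
        starts = [np.concatenate([beta1, delta1])]
    else:
        rng = np.random.default_rng(settings.seed)
        base_betas = np.tile(beta1, G)
        starts = []
        for j in range(settings.n_starts):
            zeta0 = np.zeros(G - 1)
            betas0 = base_betas.copy().reshape(G, 4)
            if j > 0:
                zeta0 = rng.normal(0.0, settings.start_scale, G - 1)
                betas0[:, 0] += rng.normal(0.0, settings.start_scale, G)
                # intercept-only perturbations cannot reach optima whose
                # classes differ mainly in shape; spread the curvature too
                betas0[:, 1:] += rng.normal(0.0, settings.shape_scale, (G, 3))
            parts = [zeta0]
            if enc.C:
                parts.append(np.zeros((G - 1) * enc.C))
            parts += [betas0.ravel(), delta1.copy()]
            starts.append(np.concatenate(parts))
        if warm_start is not None and warm_start.G == G - 1:
            starts.append(_split_start(warm_start, enc))

    results = [_optimize_one(x0, enc, G, settings) for x0 in starts]
    logliks = [-r.fun for r in results]
    candidates = [k for k, r in enumerate(results) if r.conv_b and r.conv_l]
    best = max(candidates or range(len(results)), key=lambda k: logliks[k])
    res = results[best]
    conv_b, conv_l = res.conv_b, res.conv_l
    if not (conv_b and conv_l):
        warnings.warn(f"best start ({best}) did not meet convB/convL criteria")
    conv_g, _ = _conv_g_criterion(res.x, enc, G, settings, H=res.hessian)
    if (conv_b and conv_l) and not conv_g and res.nit < settings.max_iter:
        # the early stop can leave the gradient criterion marginally unmet;
        # a Newton polish from the optimum settles all three
        x, f, H, extra, pb, pl = _newton_polish(
            res.x, res.fun, enc, G, settings, budget=settings.max_iter - res.nit
        )
        res = _StartResult(
            x=x, fun=f, nit=res.nit + extra, conv_b=conv_b or pb, conv_l=conv_l or pl,
            hessian=H,
        )
        logliks[best] = -f
        conv_g, _ = _conv_g_criterion(res.x, enc, G, settings, H=res.hessian)

    zeta, gamma, betas, _, tau = _unpack(res.x, G, enc.M, enc.C)
    params = LCGAParams(betas=betas, tau=tau, zeta=zeta, gamma=gamma)
    params = _permute_params(params, _canonical_order(params))
    post = posterior_probs(params, (Y, sessions), covariates=covariates)
    assignments = post.argmax(axis=1)
    converged = bool(conv_b and conv_l and conv_g)
    return LCGAFit(
        params=params,
        loglik=-float(res.fun),
        n_params=len(res.x),
        n_subjects=enc.N,
        posteriors=post,
        assignments=assignments,
        subject_ids=ids,
        converged=converged,
        convergence_flags={"conv_b": conv_b, "conv_l": conv_l, "conv_g": conv_g},
        n_iterations=int(res.nit),
        best_start_index=int(best),
        start_logliks=logliks,
        settings=settings,
        sessions=sessions,
    )


def fit_lcga_em(
    data, G: int, settings: FitSettings | None = None, n_categories: int = 4
) -> LCGAFit:
    """EM cross-check estimator (no membership covariates).

    E-step computes posteriors; the M-step updates class proportions in
    closed form and the trajectory/threshold parameters by an inner
    quasi-Newton pass on the expected complete-data log-likelihood.  The
    observed log-likelihood is monotone up to the inner-solver tolerance;
    the per-iteration trace is kept on the returned fit
    (``fit.start_logliks``).
    """
    settings = settings or FitSettings()
    Y, sessions, ids = _coerce_data(data)
    enc = _Encoded(Y, sessions, n_categories)
    one = _fit_one_class(_Encoded(Y, sessions, n_categories), settings)
    rng = np.random.default_rng(settings.seed)
    betas = np.tile(one.x[:4], (G, 1))
    if G > 1:
        betas[:, 0] += rng.normal(0.0, settings.start_scale, G)
    deltas = one.x[4:].copy()
    logpi = np.full(G, -np.log(G))

    def observed_ll(betas, deltas, logpi):
        tau = np.concatenate([[0.0], np.cumsum(deltas**2)])
        p = LCGAParams(betas=betas, tau=tau, zeta=logpi[1:] - logpi[0])
        table = _cat_prob_table(p, sessions)
        L = np.log(np.clip(table, _P_FLOOR, None)).reshape(G, -1)
        s = enc.X @ L.T
        joint = log_softmax(np.concatenate([[0.0], p.zeta]))[None, :] + s
        return logsumexp(joint, axis=1), joint

    trace = []
    prev_ll = -np.inf
    n_iter = 0
    for it in range(settings.max_iter):
        n_iter = it + 1
        ll_i, joint = observed_ll(betas, deltas, logpi)
        ll = float(ll_i.sum())
        trace.append(ll)
        w = np.exp(joint - ll_i[:, None])
        if abs(ll - prev_ll) < settings.conv_l and it > 0:
            break
        prev_ll = ll
        # M-step: pi closed form; (betas, deltas) by weighted inner pass
        pi = np.clip(w.mean(axis=0), 1e-12, None)
        logpi = np.log(pi / pi.sum())
        W = (w.T @ enc.X).reshape(G, enc.T, enc.M)

        def q_obj(xz):
            b = xz[: 4 * G].reshape(G, 4)
            d = xz[4 * G :]
            tau = np.concatenate([[0.0], np.cumsum(d**2)])
            lam = b @ enc.U.T
            a = tau[:, None, None] - lam[None]
            cum = np.concatenate(
                [np.zeros((1, G, enc.T)), norm.cdf(a), np.ones((1, G, enc.T))]
            )
            P = np.clip(np.diff(cum, axis=0), _P_FLOOR, None)
            return -float(np.sum(np.moveaxis(W, 2, 0) * np.log(P)))

        xz0 = np.concatenate([betas.ravel(), deltas])
        inner = optimize.minimize(q_obj, xz0, method="L-BFGS-B", options={"maxiter": 60})
        betas = inner.x[: 4 * G].reshape(G, 4)
        deltas = inner.x[4 * G :]

    tau = np.concatenate([[0.0], np.cumsum(deltas**2)])
    params = LCGAParams(betas=betas, tau=tau, zeta=logpi[1:] - logpi[0])
    params = _permute_params(params, _canonical_order(params))
    post = posterior_probs(params, (Y, sessions))
    conv = n_iter < settings.max_iter
    return LCGAFit(
        params=params,
        loglik=trace[-1],
        n_params=params.n_params(),
        n_subjects=enc.N,
        posteriors=post,
        assignments=post.argmax(axis=1),
        subject_ids=ids,
        converged=conv,
        convergence_flags={"conv_b": conv, "conv_l": conv, "conv_g": conv},
        n_iterations=n_iter,
        best_start_index=0,
        start_logliks=trace,
        settings=settings,
        sessions=sessions,
    )


# ---------------------------------------------------------------------------
# posteriors and prediction


def posterior_probs(params: LCGAParams, data, covariates=None) -> np.ndarray:
    """Posterior class-membership matrix p_ig; rows sum to 1.

    Computed in the log domain, so per-session probabilities near zero do
    not underflow.
    """
    Y, sessions, _ = _coerce_data(data)
    table = _cat_prob_table(params, sessions)  # (G, T, M)
    L = np.log(np.clip(table, _P_FLOOR, None)).reshape(params.G, -1)
    enc = _Encoded(Y, sessions, params.M)
    s = enc.X @ L.T
    logpi = _log_prior(params, covariates)
    joint = logpi + s
    return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))


def observed_information(fit: LCGAFit, data, covariates=None) -> np.ndarray:
    """Observed information (Hessian of the NLL) at the fitted optimum."""
    Y, sessions, _ = _coerce_data(data)
    enc = _Encoded(Y, sessions, fit.params.M, covariates)
    x = _pack(fit.params, enc.C)
    return _num_hessian(x, enc, fit.G)


def expected_rating(params: LCGAParams, sessions) -> np.ndarray:
    """E[Y | g, t] = sum_m m P(Y = m | g, t); shape (G, T)."""
    table = _cat_prob_table(params, sessions)
    m = np.arange(1, params.M + 1)
    return table @ m


def predict_trajectory(
    fit: LCGAFit,
    vcov: np.ndarray | None = None,
    n_draws: int = 500,
    seed: int = 0,
    sessions=None,
) -> pd.DataFrame:
    """Per-class expected rating curves with 95% bands over t = 0..20.

    Bands are the 2.5/97.5 percentiles of the expected-rating functional
    over ``n_draws`` parameter vectors sampled from the asymptotic normal
    of the estimator (mean = fitted parameters, covariance = ``vcov``,
    typically the inverse observed information).  With ``vcov=None`` the
    bands are flagged unavailable; with a zero matrix they collapse onto
    the point curve.
    """
    if sessions is None:
        sessions = np.arange(0, 21)
    sessions = np.asarray(sessions, dtype=float)
    point = expected_rating(fit.params, sessions)  # (G, T)
    rows = {
        "class": np.repeat(np.arange(fit.G), len(sessions)),
        "session": np.tile(sessions, fit.G),
        "expected_rating": point.ravel(),
    }
    if vcov is None:
        rows["lo95"] = np.nan
        rows["hi95"] = np.nan
        out = pd.DataFrame(rows)
        out.attrs["bands_available"] = False
        return out

    C = 0 if fit.params.gamma is None else fit.params.gamma.shape[1]
    x = _pack(fit.params, C)
    vcov = np.asarray(vcov, dtype=float)
    rng = np.random.default_rng(seed)
    if np.allclose(vcov, 0.0):
        draws = np.tile(x, (n_draws, 1))
    else:
        # symmetrise and clip tiny negative eigenvalues from numeric inversion
        sym = (vcov + vcov.T) / 2
        vals, vecs = np.linalg.eigh(sym)
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        draws = x + rng.standard_normal((n_draws, len(x))) @ root.T
    curves = np.empty((n_draws, fit.G, len(sessions)))
    for k, xd in enumerate(draws):
        zeta, gamma, betas, _, tau = _unpack(xd, fit.G, fit.params.M, C)
        p = LCGAParams(betas=betas, tau=tau, zeta=zeta, gamma=gamma)
        curves[k] = expected_rating(p, sessions)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    rows["lo95"] = lo.ravel()
    rows["hi95"] = hi.ravel()
    out = pd.DataFrame(rows)
    out.attrs["bands_available"] = True
    return out


def wald_test_membership(fit: LCGAFit, data, covariates) -> dict:
    """Wald test that all membership-covariate effects are zero.

    Mirrors the screening step in which a treatment-arm covariate is kept
    in the class-membership model only if significant.
    """
    from scipy.stats import chi2

    if fit.params.gamma is None:
        raise ValueError("fit has no membership covariates")
    H = observed_information(fit, data, covariates)
    vcov = np.linalg.pinv(H)
    G = fit.G
    C = fit.params.gamma.shape[1]
    idx = np.arange(G - 1, G - 1 + (G - 1) * C)  # gamma block in packing order
    g = fit.params.gamma.ravel()
    V = vcov[np.ix_(idx, idx)]
    stat = float(g @ np.linalg.solve(V, g))
    df = len(idx)
    return {"statistic": stat, "df": df, "p_value": float(chi2.sf(stat, df))}
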