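"""Stimulus-coded drift-diffusion modeling of yes/no choice behavior.

The decision variable y evolves as ``dy = (v*s + dc) dt + c dW`` from
``y0 = z*a`` until it is absorbed at 0 ('no') or a ('yes'); the observed
reaction time is the first-passage time plus the non-decision time t0.
``s`` is the stimulus code (+1 signal, -1 noise), ``v`` the stimulus-dependent
drift, and ``dc`` the drift criterion — an evidence-independent drift offset
that biases accumulation toward one bound cumulatively over time (unlike a
starting-point bias ``z != 0.5``, which is a constant head start).

Likelihoods use the exact series expansion of the two-boundary first-passage
density, with the small-time / large-time form chosen per evaluation point by
the standard truncation error bound.  Across-trial drift variability ``sv``
is integrated out by Gauss-Hermite quadrature.

Fitting is per-subject maximum likelihood with multi-start Nelder-Mead; model
comparison uses AIC/BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq, minimize
from sklearn.base import BaseEstimator

__all__ = [
    "DDMParams",
    "DDMFit",
    "simulate",
    "fpt_density",
    "choice_probability",
    "analytic_upper_probability",
    "DriftDiffusionModel",
    "fit",
    "mode_shift_diagnostic",
    "match_z_to_choice_fraction",
    "RegressionDDM",
    "fit_regression_ddm",
]

# absolute truncation tolerance for the density series
_SERIES_ERR = 1e-8
# density floor inside log-likelihoods (guards rt <= t0 and far tails)
_DENSITY_FLOOR = 1e-12


@dataclass
class DDMParams:
    """Diffusion parameters.

    a : boundary separation; z : starting point as a fraction of a;
    v : mean drift rate; dc : drift criterion; t0 : non-decision time (s);
    sv : across-trial drift standard deviation; c : diffusion noise scale
    (fixed at 1 by the usual scaling convention — only ratios to c are
    identifiable).
    """

    a: float = 1.0
    z: float = 0.5
    v: float = 1.0
    dc: float = 0.0
    t0: float = 0.3
    sv: float = 0.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError("boundary separation a must be > 0")
        if not (0.0 < self.z < 1.0):
            raise ValueError("starting point z must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be >= 0")
        if self.sv < 0:
            raise ValueError("drift variability sv must be >= 0")
        if not (self.c > 0):
            raise ValueError("noise scale c must be > 0")


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------


# A discretely monitored path misses boundary crossings between steps, so
# absorption happens too late relative to the continuous process; the
# Broadie-Glasserman-Kou continuity correction narrows each boundary by
# beta*c*sqrt(dt), beta = -zeta(1/2)/sqrt(2*pi), to compensate.
_BGK_BETA = 0.5825971579390107


@njit(cache=True)
def _euler_fpt(mu, a, y0, c, dt, t_max, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = mu.shape[0]
    rt = np.empty(n)
    choice = np.empty(n, np.int64)
    s = c * np.sqrt(dt)
    h = _BGK_BETA * s  # continuity correction
    lo = h
    hi = a - h
    for i in range(n):
        y = y0
        t = 0.0
        drift = mu[i] * dt
        ch = -1
        while t < t_max:
            y += drift + s * np.random.normal()
            t += dt
            if y >= hi:
                ch = 1
                break
            if y <= lo:
                ch = 0
                break
        choice[i] = ch
        rt[i] = t if ch >= 0 else np.nan
    return rt, choice


def simulate(params: DDMParams, stimulus, n=None, dt=1e-4, seed=0, t_max=10.0):
    """Simulate choices and RTs by Euler-Maruyama integration.

    Parameters
    ----------
    stimulus : int or array of +/-1
        Stimulus code per trial (scalar is broadcast to ``n`` trials).
    n : int, optional
        Number of trials (required when stimulus is scalar).

    Returns
    -------
    rt : array — hit time + t0 (NaN for trials not absorbed by t_max)
    choice : array — 1 'yes' (upper bound), 0 'no' (lower), -1 not absorbed
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    stimulus = np.asarray(stimulus, float)
    if stimulus.ndim == 0:
        if n is None:
            raise ValueError("n is required with scalar stimulus")
        stimulus = np.full(n, float(stimulus))
    n = stimulus.size
    rng = np.random.default_rng(seed)
    mu = params.v * stimulus + params.dc
    if params.sv > 0:
        mu = rng.normal(mu, params.sv)
    sim_seed = int(rng.integers(0, 2**31 - 1))
    rt, choice = _euler_fpt(
        np.ascontiguousarray(mu), params.a, params.z * params.a, params.c, dt, t_max, sim_seed
    )
    n_lost = int(np.sum(choice < 0))
    if n_lost:
        warnings.warn(f"{n_lost} of {n} trials not absorbed by t_max={t_max}")
    rt = rt + params.t0
    return rt, choice


# ---------------------------------------------------------------------------
# analytic first-passage density
# ---------------------------------------------------------------------------


def _f_lower_standard(tau, w, err=_SERIES_ERR):
    """Density at the lower bound for a=1, v=0, start w, as a function of
    normalized time tau; small-/large-time series selected element-wise."""
    tau = np.asarray(tau, float)
    w = np.broadcast_to(np.asarray(w, float), tau.shape)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not np.any(pos):
        return out
    t = tau[pos]
    ww = w[pos]

    # required number of terms (Navarro-Fuss style bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * t) * err
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(arg_s), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * err
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
    use_small = ks < kl

    val = np.empty_like(t)
    if np.any(use_small):
        ts = t[use_small]
        ws = ww[use_small]
        K = int(min(np.ceil(np.max(ks[use_small])), 50))
        acc = np.zeros_like(ts)
        for k in range(-K, K + 1):
            wk = ws + 2.0 * k
            acc += wk * np.exp(-(wk**2) / (2.0 * ts))
        val[use_small] = acc / np.sqrt(2.0 * np.pi * ts**3)
    if np.any(~use_small):
        tl = t[~use_small]
        wl = ww[~use_small]
        K = int(min(np.ceil(np.max(kl[~use_small])), 500))
        acc = np.zeros_like(tl)
        for k in range(1, K + 1):
            acc += k * np.exp(-(k**2) * np.pi**2 * tl / 2.0) * np.sin(k * np.pi * wl)
        val[~use_small] = np.pi * acc
    out[pos] = np.maximum(val, 0.0)
    return out


def _density_constant_drift(t_dec, mu, a, z, c, choice_upper):
    """Two-boundary FPT density at decision time t_dec for drift mu."""
    A = a / c
    M = np.asarray(mu, float) / c
    if choice_upper:
        M = -M
        w = 1.0 - z
    else:
        w = z
    tau = np.asarray(t_dec, float) / A**2
    M, tau = np.broadcast_arrays(M, tau)
    f = _f_lower_standard(tau, w) / A**2
    return f * np.exp(-M * A * w - (M**2) * np.asarray(t_dec, float) / 2.0)


_GH_NODES = 20
_gh_cache: dict = {}


def _hermegauss(n):
    if n not in _gh_cache:
        _gh_cache[n] = np.polynomial.hermite_e.hermegauss(n)
    return _gh_cache[n]


def fpt_density(params: DDMParams, stimulus, choice, t, n_quad=_GH_NODES):
    """First-passage-time density of the observed RT for one bound.

    ``choice`` is 1 for 'yes' (upper bound) or 0 for 'no' (lower).  Values at
    ``t <= t0`` are 0.  With ``sv > 0`` the density is marginalized over the
    Gaussian drift distribution by Gauss-Hermite quadrature.
    """
    t = np.asarray(t, float)
    td = t - params.t0
    mu = params.v * np.asarray(stimulus, float) + params.dc
    upper = bool(np.asarray(choice).item() == 1) if np.asarray(choice).ndim == 0 else None
    if upper is None:
        raise ValueError("choice must be scalar here; use _loglik for vectors")
    if params.sv == 0:
        out = _density_constant_drift(np.maximum(td, 0.0), mu, params.a, params.z, params.c, upper)
    else:
        x, wts = _hermegauss(n_quad)
        # mu_j ~ N(mu, sv): probabilists' Hermite nodes
        out = np.zeros(np.broadcast(td, mu).shape, float)
        for xj, wj in zip(x, wts):
            out += wj * _density_constant_drift(
                np.maximum(td, 0.0), mu + params.sv * xj, params.a, params.z, params.c, upper
            )
        out /= np.sqrt(2.0 * np.pi)
    return np.where(td > 0, out, 0.0)


def analytic_upper_probability(mu, a, z, c=1.0):
    """Closed-form P(absorb at the upper bound) for constant drift mu:
    (exp(-2 mu z a / c^2) - 1) / (exp(-2 mu a / c^2) - 1), with the drift-free
    limit z."""
    k = 2.0 * mu * a / c**2
    if abs(k) < 1e-9:
        return float(z)
    return float(np.expm1(-k * z) / np.expm1(-k))


def choice_probability(params: DDMParams, stimulus, n_quad=_GH_NODES):
    """P('yes') under the model, marginal over drift variability."""
    mu = params.v * float(stimulus) + params.dc
    if params.sv == 0:
        return analytic_upper_probability(mu, params.a, params.z, params.c)
    x, wts = _hermegauss(n_quad)
    p = sum(
        wj * analytic_upper_probability(mu + params.sv * xj, params.a, params.z, params.c)
        for xj, wj in zip(x, wts)
    )
    return float(p / np.sqrt(2.0 * np.pi))


def _loglik(rt, choice, mu, a, z, t0, sv, c, n_quad=_GH_NODES):
    """Vectorized log-likelihood; mu is the per-trial mean drift.

    The drift-free series factor depends only on the normalized time and the
    (choice-side) starting point, so it is computed once and reused across
    the drift-variability quadrature nodes; only the exponential drift
    factor is re-evaluated per node.
    """
    td = rt - t0
    valid = td > 0
    tdv = np.maximum(td, 1e-12)
    up = choice == 1
    A = a / c
    tau = tdv / A**2
    w_eff = np.where(up, 1.0 - z, z)
    sgn = np.where(up, -1.0, 1.0)  # upper bound = lower bound of mirrored process
    series = _f_lower_standard(tau, w_eff) / A**2

    def drift_factor(m):
        M = sgn * m / c
        return np.exp(-M * A * w_eff - (M**2) * tdv / 2.0)

    if sv > 0:
        x, wts = _hermegauss(n_quad)
        fac = np.zeros_like(rt)
        for xj, wj in zip(x, wts):
            fac += wj * drift_factor(mu + sv * xj)
        fac /= np.sqrt(2.0 * np.pi)
    else:
        fac = drift_factor(mu)
    dens = np.where(valid, np.maximum(series * fac, _DENSITY_FLOOR),
                    _DENSITY_FLOOR)
    return float(np.sum(np.log(dens)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_FREE_DEFAULT = ("a", "t0", "v", "z", "dc")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass
class DDMFit:
    """Per-condition ML fit with shared drift variability."""

    params: dict = field(default_factory=dict)  # bin label -> DDMParams
    loglik: float = np.nan
    aic: float = np.nan
    bic: float = np.nan
    n_params: int = 0
    n_trials: int = 0
    n_starts: int = 0
    converged: bool = False


class DriftDiffusionModel(BaseEstimator):
    """Maximum-likelihood stimulus-coded DDM, optionally per condition.

    Parameters listed in ``free_per_bin`` take independent values in each
    condition (TPR bin); ``shared`` parameters take a single value across
    conditions.  The reduced model of interest fixes ``dc`` across bins by
    moving it from ``free_per_bin`` to ``shared``.

    Fitted attributes: ``params_`` (dict bin label -> DDMParams), ``loglik_``,
    ``aic_``, ``bic_``, ``fit_`` (DDMFit), ``converged_``.
    """

    def __init__(
        self,
        free_per_bin=_FREE_DEFAULT,
        shared=("sv",),
        n_starts=5,
        seed=0,
        fixed=None,
        n_quad=_GH_NODES,
        maxiter=4000,
    ):
        self.free_per_bin = free_per_bin
        self.shared = shared
        self.n_starts = n_starts
        self.seed = seed
        self.fixed = fixed
        self.n_quad = n_quad
        self.maxiter = maxiter

    # -- parameter packing ---------------------------------------------------

    def _names(self, n_bins):
        per_bin = [(p, b) for b in range(n_bins) for p in self.free_per_bin]
        shared = [(p, None) for p in self.shared]
        return per_bin + shared

    def _to_theta(self, values, rt_min):
        out = []
        for (p, _), v in zip(self._theta_names, values):
            if p == "a":
                out.append(np.log(v))
            elif p == "z":
                out.append(_logit(v))
            elif p == "t0":
                out.append(_logit(np.clip(v / rt_min, 1e-4, 1 - 1e-4)))
            elif p == "sv":
                out.append(np.log(max(v, 1e-4)))
            else:
                out.append(v)
        return np.array(out)

    def _from_theta(self, theta, rt_min, n_bins):
        fixed = dict(self.fixed or {})
        vals = {b: dict(fixed) for b in range(n_bins)}
        shared_vals = {}
        for (p, b), x in zip(self._theta_names, theta):
            if p == "a":
                v = np.exp(np.clip(x, -10, 10))
            elif p == "z":
                v = _sigmoid(np.clip(x, -30, 30))
            elif p == "t0":
                v = _sigmoid(np.clip(x, -30, 30)) * rt_min
            elif p == "sv":
                v = np.exp(np.clip(x, -10, 4))
            else:
                v = x
            if b is None:
                shared_vals[p] = v
            else:
                vals[b][p] = v
        for b in vals:
            vals[b].update(shared_vals)
        return vals

    def _nll(self, theta, data, rt_min, n_bins):
        vals = self._from_theta(theta, rt_min, n_bins)
        total = 0.0
        for b, (rt, choice, stim) in data.items():
            p = vals[b]
            mu = p.get("v", 1.0) * stim + p.get("dc", 0.0)
            total -= _loglik(
                rt, choice, mu, p.get("a", 1.0), p.get("z", 0.5), p.get("t0", 0.3),
                p.get("sv", 0.0), p.get("c", 1.0), self.n_quad,
            )
        if not np.isfinite(total):
            return 1e12
        return total

    # -- API -----------------------------------------------------------------

    def fit(self, rt, choice, stimulus, bins=None):
        """Fit by multi-start ML.

        rt, choice (1 yes / 0 no), stimulus (+1/-1) are per-trial arrays;
        ``bins`` labels the condition of each trial (None = one condition).
        """
        rt = np.asarray(rt, float)
        choice = np.asarray(choice, int)
        stimulus = np.asarray(stimulus, float)
        ok = np.isfinite(rt) & (choice >= 0)
        rt, choice, stimulus = rt[ok], choice[ok], stimulus[ok]
        if bins is None:
            bins = np.zeros(rt.size, int)
        else:
            bins = np.asarray(bins)[ok]
        labels = [lbl for lbl in np.unique(bins)]
        n_bins = len(labels)
        data = {}
        for i, lbl in enumerate(labels):
            m = bins == lbl
            if len(np.unique(choice[m])) < 2:
                raise ValueError(f"bin {lbl!r} lacks one of the choice types")
            data[i] = (rt[m], choice[m], stimulus[m])
        rt_min = float(rt.min())
        self._theta_names = self._names(n_bins)

        # moment-based base start: overall yes-rate informs dc sign
        p_yes = float(np.mean(choice))
        base = {
            "a": 1.2, "z": 0.5, "v": 1.0,
            "dc": 0.5 * (p_yes - 0.5), "t0": 0.5 * rt_min, "sv": 0.2,
        }
        base_vec = [base[p] for p, _ in self._theta_names]
        theta0 = self._to_theta(base_vec, rt_min)

        rng = np.random.default_rng(self.seed)
        best = None
        for start in range(self.n_starts):
            th = theta0 if start == 0 else theta0 + rng.normal(0, 0.4, theta0.size)
            res = minimize(
                self._nll, th, args=(data, rt_min, n_bins), method="Nelder-Mead",
                options={"maxiter": self.maxiter, "xatol": 1e-4, "fatol": 1e-4,
                         "adaptive": True},
            )
            if best is None or res.fun < best.fun:
                best = res
        # polish from the best start
        res = minimize(
            self._nll, best.x, args=(data, rt_min, n_bins), method="Nelder-Mead",
            options={"maxiter": self.maxiter, "xatol": 1e-5, "fatol": 1e-5,
                     "adaptive": True},
        )
        if res.fun <= best.fun:
            best = res
        if not best.success:
            warnings.warn("DDM fit: optimizer did not report convergence; "
                          "returning best parameters found")

        vals = self._from_theta(best.x, rt_min, n_bins)
        self.params_ = {
            lbl: DDMParams(**{k: v for k, v in vals[i].items()
                              if k in DDMParams.__dataclass_fields__})
            for i, lbl in enumerate(labels)
        }
        k = len(self._theta_names)
        n = rt.size
        self.loglik_ = -float(best.fun)
        self.aic_ = 2 * k - 2 * self.loglik_
        self.bic_ = k * np.log(n) - 2 * self.loglik_
        self.converged_ = bool(best.success)
        self.fit_ = DDMFit(
            params=self.params_, loglik=self.loglik_, aic=self.aic_, bic=self.bic_,
            n_params=k, n_trials=n, n_starts=self.n_starts, converged=self.converged_,
        )
        return self

    def predict_choice_probability(self, stimulus, bin_label=None):
        lbl = bin_label if bin_label is not None else next(iter(self.params_))
        return choice_probability(self.params_[lbl], stimulus, self.n_quad)


def fit(rt, choice, stimulus, bins=None, free_per_bin=_FREE_DEFAULT, shared=("sv",),
        n_starts=5, seed=0, **kw) -> DDMFit:
    """Functional wrapper over DriftDiffusionModel."""
    model = DriftDiffusionModel(free_per_bin=free_per_bin, shared=shared,
                                n_starts=n_starts, seed=seed, **kw)
    model.fit(rt, choice, stimulus, bins=bins)
    return model.fit_


# ---------------------------------------------------------------------------
# drift-criterion vs starting-point dissociation
# ---------------------------------------------------------------------------


def match_z_to_choice_fraction(params_dc: DDMParams, stimulus_mix=(1.0, -1.0), tol=1e-10):
    """Return a starting-point-biased parameter set (dc=0) whose overall
    P('yes') over the stimulus mixture matches that of ``params_dc``."""
    target = np.mean([choice_probability(params_dc, s) for s in stimulus_mix])

    def gap(z):
        p = replace(params_dc, z=z, dc=0.0)
        return np.mean([choice_probability(p, s) for s in stimulus_mix]) - target

    z = brentq(gap, 1e-6, 1 - 1e-6, xtol=tol)
    return replace(params_dc, z=z, dc=0.0)


def _rt_mode(params: DDMParams, stimulus, choice, t_max=6.0, n_grid=6000):
    t = np.linspace(params.t0 + 1e-4, params.t0 + t_max, n_grid)
    d = fpt_density(params, stimulus, choice, t)
    return float(t[np.argmax(d)])


def mode_shift_diagnostic(params_biased_z: DDMParams, params_biased_dc: DDMParams,
                          params_unbiased: DDMParams | None = None,
                          stimulus_mix=(1.0, -1.0)):
    """Compare how a starting-point bias and a matched drift-criterion bias
    displace the modes of the choice-conditional RT distributions.

    A drift-criterion bias accumulates over time and barely moves the RT
    mode; an equivalent (choice-fraction-matched) starting-point bias shifts
    it substantially.  Returns a dict with per-choice mode shifts relative to
    the unbiased model and the matched choice fractions.
    """
    if params_unbiased is None:
        params_unbiased = replace(params_biased_dc, dc=0.0, z=0.5)

    def modes(p):
        return {
            ch: np.mean([_rt_mode(p, s, ch) for s in stimulus_mix]) for ch in (1, 0)
        }

    m0 = modes(params_unbiased)
    mz = modes(params_biased_z)
    mdc = modes(params_biased_dc)
    p_yes = {
        "z": np.mean([choice_probability(params_biased_z, s) for s in stimulus_mix]),
        "dc": np.mean([choice_probability(params_biased_dc, s) for s in stimulus_mix]),
    }
    shifts = {
        "z": {ch: mz[ch] - m0[ch] for ch in (1, 0)},
        "dc": {ch: mdc[ch] - m0[ch] for ch in (1, 0)},
    }
    return {"mode_shifts": shifts, "choice_fractions": p_yes, "modes_unbiased": m0}


# ---------------------------------------------------------------------------
# trial-level regression DDM:  v_i = b0 + b1*S_i + b2*M_i + b3*C_i
# ---------------------------------------------------------------------------


@dataclass
class RegressionDDMSpec:
    """Trial-level drift regression fit: b0 overall drift bias, b1 stimulus
    drift, b2/b3 coefficients on the combined neuromodulatory (M) and
    colliculi (C) responses; a, z, t0 shared across trials."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    a: float
    z: float
    t0: float
    loglik: float
    converged: bool


class RegressionDDM(BaseEstimator):
    """ML fit of the trial-level drift regression.

    The per-trial drift is composed inside the first-passage likelihood;
    boundary separation, starting point and non-decision time are fitted but
    do not depend on the trial-wise brainstem regressors.
    """

    def __init__(self, n_starts=3, seed=0, maxiter=4000, zscore_inputs=True):
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter
        self.zscore_inputs = zscore_inputs

    @staticmethod
    def _zscore(x):
        sd = np.std(x)
        return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)

    def fit(self, rt, choice, stimulus, M, C):
        rt = np.asarray(rt, float)
        choice = np.asarray(choice, int)
        stimulus = np.asarray(stimulus, float)
        M = np.asarray(M, float)
        C = np.asarray(C, float)
        ok = np.isfinite(rt) & (choice >= 0)
        rt, choice, stimulus, M, C = rt[ok], choice[ok], stimulus[ok], M[ok], C[ok]
        if self.zscore_inputs:
            M = self._zscore(M)
            C = self._zscore(C)
        rt_min = float(rt.min())

        def unpack(th):
            b0, b1, b2, b3 = th[:4]
            a = np.exp(np.clip(th[4], -10, 10))
            z = _sigmoid(np.clip(th[5], -30, 30))
            t0 = _sigmoid(np.clip(th[6], -30, 30)) * rt_min
            return b0, b1, b2, b3, a, z, t0

        def nll(th):
            b0, b1, b2, b3, a, z, t0 = unpack(th)
            mu = b0 + b1 * stimulus + b2 * M + b3 * C
            val = -_loglik(rt, choice, mu, a, z, t0, 0.0, 1.0)
            return val if np.isfinite(val) else 1e12

        p_yes = float(np.mean(choice))
        th0 = np.array([0.5 * (p_yes - 0.5), 1.0, 0.0, 0.0,
                        np.log(1.2), 0.0, _logit(0.5)])
        rng = np.random.default_rng(self.seed)
        best = None
        for start in range(self.n_starts):
            th = th0 if start == 0 else th0 + rng.normal(0, 0.3, th0.size)
            res = minimize(nll, th, method="Nelder-Mead",
                           options={"maxiter": self.maxiter, "xatol": 1e-4,
                                    "fatol": 1e-4, "adaptive": True})
            if best is None or res.fun < best.fun:
                best = res
        b0, b1, b2, b3, a, z, t0 = unpack(best.x)
        self.spec_ = RegressionDDMSpec(b0, b1, b2, b3, a, z, t0,
                                       -float(best.fun), bool(best.success))
        self.coef_ = np.array([b0, b1, b2, b3])
        self.loglik_ = -float(best.fun)
        return self


def fit_regression_ddm(rt, choice, stimulus, M, C, **kw) -> RegressionDDMSpec:
    """Functional wrapper over RegressionDDM."""
    return RegressionDDM(**kw).fit(rt, choice, stimulus, M, C).spec_
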