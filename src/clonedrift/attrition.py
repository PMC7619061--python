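"""Subcritical birth-death attrition model for the blood-forming-ancestor (BFA) pool.

A pool of ``N0`` independent ancestors at birth, each dividing at rate
``lambda = xi * delta`` and lost (death or differentiation) at rate ``delta``
with ``delta > lambda`` (subcritical, ``xi = lambda/delta < 1``), goes extinct
in finite time.  The pool-survival probability has the closed form

    p_S(t) = 1 - [ (e^{(1-xi) delta t} - 1) / (e^{(1-xi) delta t} - xi) ]^{N0}

which is the N0-th power of the standard linear birth-death extinction
probability.  Equating pool extinction with bone-marrow failure lets the model
be fitted to a Kaplan-Meier survival curve by Bayesian posterior sampling with
uniform priors and a Gaussian observation-noise model on the survival steps.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AttritionParams",
    "AttritionPriors",
    "KaplanMeierCurve",
    "PosteriorSample",
    "AttritionFitter",
    "survival_probability",
    "extinction_time_quantile",
    "km_estimator",
    "log_posterior",
    "fit_attrition",
]


class InvalidParameterError(ValueError):
    """Raised for parameter values outside the model's domain."""


@dataclass(frozen=True)
class AttritionParams:
    """Parameter set (N0, delta, xi, sigma) of the attrition model.

    Attributes
    ----------
    n0 : float
        Initial post-natal BFA count (> 0; continuous in the likelihood).
    delta : float
        Per-cell loss rate, 1/week (> 0).
    xi : float
        Subcriticality ratio lambda/delta, in [0, 1).
    sigma : float
        Observation-noise standard deviation on survival probabilities,
        in (0, 1).
    """

    n0: float
    delta: float
    xi: float
    sigma: float = 0.05

    def __post_init__(self):
        if not (self.n0 > 0):
            raise InvalidParameterError(f"n0 must be > 0, got {self.n0}")
        if not (self.delta > 0):
            raise InvalidParameterError(f"delta must be > 0, got {self.delta}")
        if not (0 <= self.xi < 1):
            raise InvalidParameterError(f"xi must be in [0, 1), got {self.xi}")
        if not (0 < self.sigma < 1):
            raise InvalidParameterError(f"sigma must be in (0, 1), got {self.sigma}")

    @property
    def lam(self) -> float:
        """Division rate lambda = xi * delta (< delta)."""
        return self.xi * self.delta

    @property
    def mean_lifetime(self) -> float:
        """Mean waiting time to the loss event, 1/delta (weeks)."""
        return 1.0 / self.delta

    @property
    def division_before_loss(self) -> float:
        """Probability a BFA divides into two before being lost, xi/(1+xi)."""
        return self.xi / (1.0 + self.xi)


@dataclass(frozen=True)
class AttritionPriors:
    """Uniform prior bounds; defaults are the published fitting box."""

    log10_n0: tuple[float, float] = (0.0, 3.0)
    delta: tuple[float, float] = (0.01, 10.0)  # 1/week
    xi: tuple[float, float] = (0.0, 1.0)
    sigma: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        for name in ("log10_n0", "delta", "xi", "sigma"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidParameterError(f"prior {name}: lower must be < upper")

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit survival estimate.

    ``times`` holds the distinct observation times (weeks, sorted);
    ``survival`` the estimate just after each time; ``n_events`` and
    ``n_at_risk`` the per-time death count and risk set.
    """

    times: np.ndarray
    survival: np.ndarray
    n_events: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.size == 0:
            raise ValueError("Kaplan-Meier curve must contain at least one time")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s < 0) or np.any(s > 1) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be nonincreasing and within [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        object.__setattr__(self, "n_events", np.asarray(self.n_events, dtype=int))
        object.__setattr__(self, "n_at_risk", np.asarray(self.n_at_risk, dtype=int))

    @property
    def step_times(self) -> np.ndarray:
        """Times at which at least one event (death) occurred."""
        return self.times[self.n_events > 0]

    @property
    def step_survival(self) -> np.ndarray:
        return self.survival[self.n_events > 0]


@dataclass(frozen=True)
class PosteriorSample:
    """Posterior draws plus sampler diagnostics."""

    draws: pd.DataFrame  # columns n0, delta, xi, sigma + derived
    diagnostics: dict
    seed: int | None


def survival_probability(params: AttritionParams, t) -> np.ndarray | float:
    """Pool survival probability p_S(t) of the attrition model.

    Evaluated in log space so large exponents (1-xi)*delta*t >= 700 do not
    overflow: with a = (1-xi) delta t the ratio equals
    (1 - e^{-a}) / (1 - xi e^{-a}).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    a = (1.0 - params.xi) * params.delta * t_arr
    with np.errstate(divide="ignore"):
        log_ratio = np.log1p(-np.exp(-a)) - np.log1p(-params.xi * np.exp(-a))
    p = -np.expm1(params.n0 * log_ratio)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(p)
    return p


def extinction_time_quantile(params: AttritionParams, q: float) -> float:
    """Time t at which a fraction q of pools has gone extinct: p_S(t) = 1 - q.

    Bracketed root finding (Brent) to 1e-10 relative tolerance; the upper
    bracket doubles until the survival probability falls below 1 - q.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0, 1), got {q}")
    target = 1.0 - q
    t_hi = 1.0
    while survival_probability(params, t_hi) > target:
        t_hi *= 2.0
        if t_hi > 1e12:  # pragma: no cover - subcritical guarantees termination
            raise RuntimeError("failed to bracket extinction quantile")
    return float(
        optimize.brentq(
            lambda t: survival_probability(params, t) - target,
            0.0,
            t_hi,
            rtol=1e-10,
        )
    )


def km_estimator(times: Sequence[float], event_flags: Sequence[bool]) -> KaplanMeierCurve:
    """Product-limit estimate from per-animal times and death flags.

    Censored observations (flag false) reduce the risk set without a step.
    Backed by lifelines' KaplanMeierFitter.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and event_flags must have the same length")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table.copy()
    if 0.0 in table.index and table.loc[0.0, "observed"] == 0 and 0.0 not in t:
        table = table.drop(index=0.0)
    # drop the synthetic t=0 row lifelines prepends unless a real observation sits there
    table = table[(table.index > 0) | (table["observed"] > 0) | (table["censored"] > 0)]
    sf = kmf.survival_function_["KM_estimate"]
    times_out = table.index.to_numpy(dtype=float)
    surv = sf.reindex(table.index).to_numpy(dtype=float)
    return KaplanMeierCurve(
        times=times_out,
        survival=surv,
        n_events=table["observed"].to_numpy(),
        n_at_risk=table["at_risk"].to_numpy(),
    )


_PARAM_NAMES = ("log10_n0", "delta", "xi", "sigma")


def _theta_to_params(theta: Mapping[str, float]) -> AttritionParams:
    return AttritionParams(
        n0=10.0 ** theta["log10_n0"],
        delta=theta["delta"],
        xi=theta["xi"],
        sigma=theta["sigma"],
    )


def log_posterior(
    params: AttritionParams, km: KaplanMeierCurve, priors: AttritionPriors
) -> float:
    """Log posterior of the attrition model given a Kaplan-Meier curve.

    Gaussian log-density of the residuals (KM survival minus model survival)
    at the KM step times, with standard deviation sigma, plus the flat
    log-prior (a constant inside the bounds, -inf outside).
    """
    if km.step_times.size == 0:
        raise ValueError("Kaplan-Meier curve has no event times")
    theta = {
        "log10_n0": np.log10(params.n0),
        "delta": params.delta,
        "xi": params.xi,
        "sigma": params.sigma,
    }
    for name, (lo, hi) in priors.bounds().items():
        if not (lo < theta[name] < hi):
            return -np.inf
    model = survival_probability(params, km.step_times)
    resid = km.step_survival - model
    return float(np.sum(stats.norm.logpdf(resid, scale=params.sigma)))


def _log_post_theta(
    theta_free: np.ndarray,
    free_names: Sequence[str],
    fixed: Mapping[str, float],
    km: KaplanMeierCurve,
    priors: AttritionPriors,
) -> float:
    theta = dict(fixed)
    theta.update(zip(free_names, theta_free))
    bounds = priors.bounds()
    for name in free_names:
        lo, hi = bounds[name]
        if not (lo < theta[name] < hi):
            return -np.inf
    # inline survival for speed (no dataclass validation per call)
    n0 = 10.0 ** theta["log10_n0"]
    delta, xi, sigma = theta["delta"], theta["xi"], theta["sigma"]
    a = (1.0 - xi) * delta * km.step_times
    with np.errstate(divide="ignore"):
        log_ratio = np.log1p(-np.exp(-a)) - np.log1p(-xi * np.exp(-a))
    model = -np.expm1(n0 * log_ratio)
    resid = km.step_survival - model
    return float(
        -0.5 * np.sum(resid**2) / sigma**2
        - resid.size * (np.log(sigma) + 0.5 * np.log(2 * np.pi))
    )


def _theta_to_walker(theta: Mapping[str, float]) -> dict[str, float]:
    """Map natural parameters to the decorrelated sampling coordinates.

    The posterior has a curved ridge in (delta, xi): the survival shape is
    controlled mainly by the net decay rate a = (1 - xi) * delta.  Sampling
    in (log10 n0, ln a, xi, ln sigma) removes most of the curvature; the
    Jacobian of (delta, sigma) with respect to (ln a, ln sigma),
    a / (1 - xi) * sigma, is added to the log-density so the uniform priors
    on the natural scale are preserved.
    """
    return {
        "log10_n0": theta["log10_n0"],
        "ln_a": np.log((1.0 - theta["xi"]) * theta["delta"]),
        "xi": theta["xi"],
        "ln_sigma": np.log(theta["sigma"]),
    }


_WALKER_NAMES = ("log10_n0", "ln_a", "xi", "ln_sigma")


def _walker_to_theta(walker: Mapping[str, float]) -> dict[str, float]:
    xi = walker["xi"]
    return {
        "log10_n0": walker["log10_n0"],
        "delta": np.exp(walker["ln_a"]) / (1.0 - xi) if xi < 1 else np.inf,
        "xi": xi,
        "sigma": np.exp(walker["ln_sigma"]),
    }


def _log_post_walker(
    coords: np.ndarray,
    free_names: Sequence[str],
    fixed_walker: Mapping[str, float],
    km: KaplanMeierCurve,
    priors: AttritionPriors,
) -> float:
    walker = dict(fixed_walker)
    walker.update(zip(free_names, coords))
    if not (0.0 < walker["xi"] < 1.0):
        return -np.inf
    theta = _walker_to_theta(walker)
    lp = _log_post_theta(
        np.array([theta["log10_n0"], theta["delta"], theta["xi"], theta["sigma"]]),
        _PARAM_NAMES,
        {},
        km,
        priors,
    )
    if not np.isfinite(lp):
        return lp
    # Jacobian terms keep the priors uniform on the natural scale
    jac = 0.0
    if "ln_a" in free_names:
        jac += walker["ln_a"] - np.log1p(-walker["xi"])
    if "ln_sigma" in free_names:
        jac += walker["ln_sigma"]
    return lp + jac


class AttritionFitter:
    """Bayesian fit of the attrition model to right-censored survival data.

    scikit-learn style estimator: ``fit(durations, event_observed)`` samples
    the posterior of (log10 N0, delta, xi, sigma) under the uniform priors
    with an affine-invariant ensemble sampler (emcee), walkers initialised in
    a ball around the MAP found by differential evolution.

    Parameters
    ----------
    priors : AttritionPriors
    n_samples : int
        Number of posterior draws retained (default 1000).
    n_walkers, n_steps, n_burn : int
        Ensemble geometry and chain lengths.
    fix : dict or None
        Map parameter name -> value to hold fixed (e.g. reduced 2-parameter
        problems fix ``log10_n0`` and ``sigma``).
    random_state : int or None

    Attributes
    ----------
    km_ : KaplanMeierCurve fitted to.
    posterior_ : pd.DataFrame of draws with derived columns
        (``lambda``, ``mean_lifetime``, ``division_before_loss``).
    summary_ : pd.DataFrame of mean/sd/percentiles per column.
    ess_ : float, smallest effective sample size across free parameters.
    map_params_ : AttritionParams at the MAP used for initialisation.
    """

    def __init__(
        self,
        priors: AttritionPriors | None = None,
        n_samples: int = 1000,
        n_walkers: int = 48,
        n_steps: int = 6000,
        n_burn: int = 2000,
        fix: Mapping[str, float] | None = None,
        random_state: int | None = None,
    ):
        self.priors = priors
        self.n_samples = n_samples
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.fix = fix
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "priors": self.priors,
            "n_samples": self.n_samples,
            "n_walkers": self.n_walkers,
            "n_steps": self.n_steps,
            "n_burn": self.n_burn,
            "fix": self.fix,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "AttritionFitter":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, durations, event_observed=None) -> "AttritionFitter":
        if isinstance(durations, KaplanMeierCurve):
            km = durations
        else:
            if event_observed is None:
                event_observed = np.ones(len(durations), dtype=bool)
            km = km_estimator(durations, event_observed)
        if km.step_times.size < 3:
            raise ValueError("need at least 3 event times to fit")
        self.km_ = km
        self._sample()
        return self

    def _sample(self) -> None:
        import emcee

        priors = self.priors or AttritionPriors()
        fixed = dict(self.fix or {})
        if "delta" in fixed:
            raise ValueError(
                "delta cannot be fixed on its own (the sampler works in the "
                "decorrelated (ln a, xi) coordinates); fix xi instead"
            )
        free_theta = [n for n in _PARAM_NAMES if n not in fixed]
        bounds = priors.bounds()
        rng = np.random.default_rng(self.random_state)

        def neg_lp(x):
            return -_log_post_theta(x, free_theta, fixed, self.km_, priors)

        de = optimize.differential_evolution(
            neg_lp,
            bounds=[bounds[n] for n in free_theta],
            seed=int(rng.integers(2**31)),
            maxiter=120,
            tol=1e-8,
            polish=True,
        )
        theta_map = {**fixed, **dict(zip(free_theta, de.x))}
        self.map_params_ = _theta_to_params(theta_map)

        walker_map = _theta_to_walker(theta_map)
        name_map = {"log10_n0": "log10_n0", "xi": "xi", "sigma": "ln_sigma"}
        fixed_walker = {
            name_map[k]: walker_map[name_map[k]] for k in fixed
        }
        free_names = [n for n in _WALKER_NAMES if n not in fixed_walker]
        ndim = len(free_names)
        center = np.array([walker_map[n] for n in free_names])
        scale = {"log10_n0": 0.3, "ln_a": 0.4, "xi": 0.15, "ln_sigma": 0.4}
        p0 = center + np.array([scale[n] for n in free_names]) * rng.standard_normal(
            (self.n_walkers, ndim)
        )
        if "xi" in free_names:
            j = free_names.index("xi")
            p0[:, j] = np.clip(p0[:, j], 1e-4, 1 - 1e-4)
        if "log10_n0" in free_names:
            j = free_names.index("log10_n0")
            lo, hi = bounds["log10_n0"]
            p0[:, j] = np.clip(p0[:, j], lo + 1e-6, hi - 1e-6)

        sampler = emcee.EnsembleSampler(
            self.n_walkers,
            ndim,
            _log_post_walker,
            args=(free_names, fixed_walker, self.km_, priors),
        )
        init = emcee.State(
            p0,
            random_state=np.random.RandomState(int(rng.integers(2**31))).get_state(),
        )
        state = sampler.run_mcmc(init, self.n_burn, skip_initial_state_check=True)
        sampler.reset()
        sampler.run_mcmc(state, self.n_steps)

        chain = sampler.get_chain(flat=True)  # (n_steps*n_walkers, ndim)
        try:
            import logging

            logging.getLogger("emcee.autocorr").setLevel(logging.ERROR)
            tau = sampler.get_autocorr_time(quiet=True)
            ess = float(np.min(chain.shape[0] / np.maximum(tau, 1.0)))
        except Exception:  # pragma: no cover - emcee internals
            ess = float("nan")
        self.ess_ = ess
        self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))
        if not np.isnan(ess) and ess < 100:
            warnings.warn(
                f"posterior sampler effective sample size {ess:.0f} < 100 "
                f"(acceptance {self.acceptance_fraction_:.2f}); "
                "draws may be poorly mixed",
                RuntimeWarning,
            )

        idx = np.linspace(0, chain.shape[0] - 1, self.n_samples).astype(int)
        walkers = {n: chain[idx, j] for j, n in enumerate(free_names)}
        for n, v in fixed_walker.items():
            walkers[n] = np.full(self.n_samples, v)
        xi = walkers["xi"]
        draws = {
            "log10_n0": walkers["log10_n0"],
            "delta": np.exp(walkers["ln_a"]) / (1.0 - xi),
            "xi": xi,
            "sigma": np.exp(walkers["ln_sigma"]),
        }
        df = pd.DataFrame(draws)
        df["n0"] = 10.0 ** df.pop("log10_n0")
        df["lambda"] = df["xi"] * df["delta"]
        df["mean_lifetime"] = 1.0 / df["delta"]
        df["division_before_loss"] = df["xi"] / (1.0 + df["xi"])
        df = df[
            ["n0", "delta", "xi", "sigma", "lambda", "mean_lifetime", "division_before_loss"]
        ]
        self.posterior_ = df
        self.summary_ = df.describe(percentiles=[0.025, 0.5, 0.975]).T
        self.free_names_ = free_names

    def posterior_sample(self) -> PosteriorSample:
        return PosteriorSample(
            draws=self.posterior_,
            diagnostics={
                "ess": self.ess_,
                "acceptance_fraction": self.acceptance_fraction_,
                "map": dataclasses.asdict(self.map_params_),
            },
            seed=self.random_state,
        )

    def to_json_dict(self) -> dict:
        """Posterior summaries as a JSON-serialisable dict."""
        summ = {
            col: {
                "mean": float(self.posterior_[col].mean()),
                "sd": float(self.posterior_[col].std()),
                "q2.5": float(self.posterior_[col].quantile(0.025)),
                "q50": float(self.posterior_[col].quantile(0.5)),
                "q97.5": float(self.posterior_[col].quantile(0.975)),
            }
            for col in self.posterior_.columns
        }
        return {
            "posterior": summ,
            "seed": self.random_state,
            "diagnostics": {
                "ess": self.ess_,
                "acceptance_fraction": self.acceptance_fraction_,
            },
        }


def fit_attrition(
    km: KaplanMeierCurve,
    priors: AttritionPriors | None = None,
    n_samples: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> PosteriorSample:
    """Convenience wrapper: fit the attrition model to a KM curve."""
    fitter = AttritionFitter(
        priors=priors, n_samples=n_samples, random_state=seed, **kwargs
    )
    fitter.fit(km)
    return fitter.posterior_sample()
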