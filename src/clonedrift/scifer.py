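"""Site-frequency-spectrum model of clonal hematopoiesis and ABC inference.

The stem-cell population expands exponentially at division rate
``lambda_exp`` from a single cell to its homeostatic size ``N_ss`` (reached
at ``t_B = ln(N_ss)/lambda_exp``) and thereafter stays constant on average,
dividing at rate ``lambda_ss`` with balanced loss (critical birth-death).
Each division endows a daughter with ``mu`` novel somatic variants
(infinite sites).  The expected site frequency spectrum at sampling age t is

    S_n(t) = integral_0^t  mu * lambda(tau) * N(tau) * p_n(tau, t)  d tau

where ``p_n(tau, t)`` is the probability that a clone founded by one cell at
tau has exactly n cells at t.  Because the probability generating function
of any linear birth-death phase is a Moebius (linear-fractional) map, the
clone-size law after any sequence of phases (Yule expansion, critical
homeostasis, supercritical selected growth) stays in the two-parameter
family

    p_0 = alpha,   p_n = (1 - alpha)(1 - beta) beta^{n-1}   (n >= 1),

with closed-form tails P(n >= m) = (1 - alpha) beta^{m-1}.  Kendall's
critical formula p_n = (lam*dt)^{n-1} / (1 + lam*dt)^{n+1} is the
single-phase special case.  This keeps the expected spectrum, the expected
cumulative variant-count curve, and hence rejection ABC over 10^4+ particles
cheap, with no per-particle stochastic simulation.

Sequencing noise: an observed VAF is beta-distributed around the true VAF
``v = n/(2 N_ss)`` with mean v and concentration equal to the read depth;
variants with fewer than ``min_variant_reads`` variant reads fall below the
detection limit.

The neutral-drift fixation timescale — the expected time for one clone to
take over the homeostatic pool by drift alone — is ``T_fix = N_ss /
lambda_ss``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "SciferParams",
    "SciferPriors",
    "CloneSizeDistribution",
    "AbcResult",
    "SciferABC",
    "clone_size_pmf",
    "expected_sfs",
    "expected_size_tail",
    "selected_clone_size",
    "selected_clone_model",
    "observed_model",
    "abc_fit",
    "fixation_time",
    "classify_clonality",
    "clonal_snv_age_estimate",
]

_EXP_CAP = 700.0  # exponent clamp; e^700 is near the float64 ceiling


class UnitMismatchError(ValueError):
    """Raised when data and priors disagree on the time unit."""


@dataclass(frozen=True)
class SciferParams:
    """Model parameters (mu, lambda_exp, lambda_ss, N_ss[, t_s, r]).

    ``unit`` ("week" for mouse, "year" for human data) is carried explicitly;
    all rates are per that unit.  ``t_s`` and ``r`` are present only for the
    selected-clone model: a clone founded at ``t_s`` with selective advantage
    ``r`` grows supercritically at net rate ``r * lambda_ss``.
    """

    mu: float
    lambda_ss: float
    n_ss: float
    lambda_exp: float = 1.0
    t_s: float | None = None
    r: float | None = None
    unit: str = "week"

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.lambda_ss <= 0 or self.lambda_exp <= 0:
            raise ValueError("division rates must be > 0")
        if self.n_ss <= 1:
            raise ValueError("n_ss must be > 1")
        if (self.t_s is None) != (self.r is None):
            raise ValueError("t_s and r must be given together")
        if self.r is not None and not (0 < self.r < 1):
            raise ValueError("r must be in (0, 1)")
        if self.unit not in ("week", "year"):
            raise ValueError("unit must be 'week' or 'year'")

    @property
    def t_b(self) -> float:
        """Time (from the founder cell) at which expansion reaches N_ss.

        The end of expansion is identified with birth; sampling ages counted
        from birth convert to the model's absolute clock via
        :func:`total_time`.
        """
        return np.log(self.n_ss) / self.lambda_exp

    @property
    def fixation_timescale(self) -> float:
        """Neutral-drift time to clonal dominance, N_ss / lambda_ss."""
        return self.n_ss / self.lambda_ss


@dataclass(frozen=True)
class SciferPriors:
    """Uniform prior box; defaults follow the published mouse/human tables."""

    log10_mu: tuple[float, float] = (-2.0, 3.0)
    log10_lambda_ss: tuple[float, float] = (-2.0, 1.5)
    log10_n_ss: tuple[float, float] = (1.0, 6.0)
    t_s: tuple[float, float] | None = None  # defaults to (0, sampling age)
    r: tuple[float, float] = (0.0, 1.0)
    unit: str = "week"

    @classmethod
    def mouse(cls) -> "SciferPriors":
        return cls(unit="week")

    @classmethod
    def human(cls) -> "SciferPriors":
        return cls(unit="year")


@dataclass(frozen=True)
class CloneSizeDistribution:
    """Clone-size law p_n in the linear-fractional (geometric-tail) family."""

    alpha: float  # extinction probability p_0
    beta: float  # geometric ratio of the tail
    mean: float  # unconditional mean, product of per-phase means

    def pmf(self, n) -> np.ndarray | float:
        n = np.asarray(n)
        out = np.where(
            n == 0,
            self.alpha,
            (1 - self.alpha) * (1 - self.beta) * np.power(self.beta, np.maximum(n - 1, 0)),
        )
        return float(out) if out.ndim == 0 else out

    def sf(self, m) -> np.ndarray | float:
        """P(n >= m) for m >= 1."""
        m = np.asarray(m)
        out = (1 - self.alpha) * np.power(self.beta, np.maximum(m - 1, 0))
        return float(out) if out.ndim == 0 else out

    @property
    def mean_given_alive(self) -> float:
        return self.mean / (1.0 - self.alpha) if self.alpha < 1 else np.inf


def _bd_phase(birth: float, death: float, dt) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alpha, beta, mean) of a linear birth-death phase of length dt.

    General rates: alpha = d(E-1)/(bE-d), beta = b(E-1)/(bE-d) with
    E = e^{(b-d)dt}; the critical limit b = d gives Kendall's
    alpha = beta = b*dt/(1 + b*dt); death = 0 is the Yule case.
    Vectorized over dt.
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("phase duration must be >= 0")
    if abs(birth - death) < 1e-12 * max(birth, death, 1.0):
        x = birth * dt
        a = x / (1.0 + x)
        return a, a.copy(), np.ones_like(dt)
    g = birth - death
    E = np.exp(np.clip(g * dt, -_EXP_CAP, _EXP_CAP))
    denom = birth * E - death
    alpha = death * (E - 1.0) / denom
    beta = birth * (E - 1.0) / denom
    return alpha, beta, E


def _compose(a1, b1, m1, a2, b2, m2):
    """Law of phase 1 followed by phase 2 (each survivor evolves iid).

    The composed pgf is G1(G2(s)); alpha = G1(alpha2), the mean multiplies,
    and beta follows from mean = (1-alpha)/(1-beta).
    """
    alpha = a1 + (1 - a1) * (1 - b1) * a2 / (1 - b1 * a2)
    mean = m1 * m2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = 1.0 - (1.0 - alpha) / mean
    beta = np.where(mean > 0, beta, 0.0)
    return alpha, np.clip(beta, 0.0, 1.0 - 1e-300), mean


def _clone_law(tau, t: float, params: SciferParams):
    """(alpha, beta) arrays for neutral clones founded at tau, observed at t."""
    tau = np.asarray(tau, dtype=float)
    t_b = min(params.t_b, t)
    lam = params.lambda_ss
    alpha = np.empty_like(tau)
    beta = np.empty_like(tau)
    in_exp = tau < t_b
    if np.any(in_exp):
        a1, b1, m1 = _bd_phase(params.lambda_exp, 0.0, t_b - tau[in_exp])
        a2, b2, m2 = _bd_phase(lam, lam, t - t_b)
        a, b, _ = _compose(a1, b1, m1, a2, b2, m2)
        alpha[in_exp] = a
        beta[in_exp] = b
    if np.any(~in_exp):
        a, b, _ = _bd_phase(lam, lam, t - tau[~in_exp])
        alpha[~in_exp] = a
        beta[~in_exp] = b
    return alpha, beta


def clone_size_pmf(tau: float, t: float, params: SciferParams) -> CloneSizeDistribution:
    """Size law of a clone founded by one cell at tau, observed at t.

    During homeostasis this is Kendall's critical birth-death law; clones
    founded during expansion first grow as a Yule process to the phase
    boundary and then drift critically, composed exactly in the
    linear-fractional family.
    """
    if tau > t:
        raise ValueError("tau must be <= t")
    t_b = min(params.t_b, t)
    lam = params.lambda_ss
    if tau >= t_b:
        a, b, m = _bd_phase(lam, lam, t - tau)
        return CloneSizeDistribution(float(a), float(b), float(m))
    a1, b1, m1 = _bd_phase(params.lambda_exp, 0.0, t_b - tau)
    a2, b2, m2 = _bd_phase(lam, lam, t - t_b)
    a, b, m = _compose(a1, b1, m1, a2, b2, m2)
    return CloneSizeDistribution(float(a), float(b), float(m))


def _gauss_nodes(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (b - a)
    return a + half * (x + 1.0), half * w


def _sfs_integral(params: SciferParams, t: float, weight_fn, n_nodes: int):
    """mu * integral of lambda(tau) N(tau) * weight_fn(alpha, beta) d tau."""
    t_b = min(params.t_b, t)
    total = 0.0
    if t_b > 0:
        tau, w = _gauss_nodes(0.0, t_b, n_nodes)
        alpha, beta = _clone_law(tau, t, params)
        rate = params.lambda_exp * np.exp(params.lambda_exp * tau)
        total = total + (w * rate) @ weight_fn(alpha, beta)
    if t > t_b:
        n_t = params.n_ss if params.t_b <= t else np.exp(params.lambda_exp * t)
        tau, w = _gauss_nodes(t_b, t, n_nodes)
        alpha, beta = _clone_law(tau, t, params)
        rate = params.lambda_ss * n_t
        total = total + rate * ((w) @ weight_fn(alpha, beta))
    return params.mu * total


def expected_sfs(
    params: SciferParams, t: float, n_max: int, rtol: float = 1e-6
) -> np.ndarray:
    """Expected S_n for n = 1..n_max (index 0 of the result is S_1).

    Quadrature splits at the expansion/homeostasis boundary; the node count
    doubles until the spectrum changes by less than ``rtol`` in L1.
    """
    if n_max > params.n_ss:
        raise ValueError("n_max must be <= n_ss")
    ns = np.arange(1, n_max + 1)

    def weights(alpha, beta):
        return (1 - alpha)[:, None] * (1 - beta)[:, None] * beta[:, None] ** (ns - 1)

    prev = None
    for n_nodes in (64, 128, 256, 512):
        cur = _sfs_integral(params, t, weights, n_nodes)
        if prev is not None and np.sum(np.abs(cur - prev)) <= rtol * np.sum(np.abs(cur)):
            return cur
        prev = cur
    return prev


def expected_size_tail(
    params: SciferParams, t: float, m_values, n_nodes: int = 128
) -> np.ndarray:
    """Expected number of variants with clone size >= m, for each m.

    Uses the closed-form geometric tail, so it is fast for arbitrarily large
    homeostatic population sizes.
    """
    m = np.asarray(m_values, dtype=float)

    def weights(alpha, beta):
        return (1 - alpha)[:, None] * beta[:, None] ** np.maximum(m - 1.0, 0.0)

    return _sfs_integral(params, t, weights, n_nodes)


def total_time(params: SciferParams, age: float) -> float:
    """Absolute model time for a sampling age counted from birth.

    The founder cell starts at time 0 and the population reaches N_ss at
    t_b = ln(N_ss)/lambda_exp, identified with birth; an animal sampled at
    ``age`` weeks/years after birth sits at absolute time t_b + age.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    return params.t_b + age


def fixation_time(params: SciferParams) -> float:
    """Neutral-drift fixation timescale N_ss / lambda_ss (declared unit)."""
    if params.lambda_ss <= 0:
        raise ValueError("lambda_ss must be > 0")
    return params.n_ss / params.lambda_ss


def selected_clone_size(params: SciferParams, t: float) -> float:
    """Expected size at t of the selected clone founded at t_s.

    Supercritical birth-death (division lambda_ss, loss lambda_ss(1-r))
    conditioned on survival to t — mean e^{r lambda_ss dt}/(1 - alpha(dt)) —
    capped at the homeostatic size N_ss.  Isolated here so an alternative
    growth law can be swapped in.
    """
    if params.t_s is None:
        raise ValueError("selected clone requires t_s and r")
    if params.t_s >= t:
        raise ValueError("t_s must be < t")
    dt = t - params.t_s
    lam = params.lambda_ss
    alpha, _, E = _bd_phase(lam, lam * (1.0 - params.r), dt)
    mean_alive = float(E) / max(1.0 - float(alpha), 1e-300)
    return min(mean_alive, params.n_ss)


def selected_clone_model(
    params: SciferParams, t: float, n_clonal: float | None = None
) -> dict:
    """Expected VAF composition under the selected-clone model.

    Components:

    - ``clone_vaf``: the selected clone's cell fraction over 2 (a clone at
      fixation sits at VAF 0.5 — every cell carries one copy);
    - ``n_clonal``: expected number of variants carried by the clone founder
      (mu times the founder lineage's expected division count up to t_s),
      all at ``clone_vaf``;
    - background: residual-population variants from the neutral machinery,
      scaled to the residual fraction;
    - subclonal: variants acquired inside the growing clone.

    Returns a dict with the atom and two (vaf_grid, tail_counts) component
    callables consumed by :func:`observed_model`.
    """
    if params.t_s is None or params.r is None:
        raise ValueError("selected clone model requires t_s and r")
    if params.t_s >= t:
        raise ValueError("t_s must be < t")
    m = selected_clone_size(params, t)
    f_clone = m / params.n_ss
    clone_vaf = 0.5 * f_clone
    t_b = min(params.t_b, t)
    if n_clonal is None:
        founder_divisions = params.lambda_exp * min(params.t_s, t_b) + (
            params.lambda_ss * max(0.0, params.t_s - t_b)
        )
        n_clonal = params.mu * founder_divisions
    return {
        "clone_size": m,
        "clone_vaf": clone_vaf,
        "n_clonal": n_clonal,
        "residual_fraction": 1.0 - f_clone,
        "params": params,
        "t": t,
    }


def _beta_tail(v: np.ndarray, depth: float, g: np.ndarray) -> np.ndarray:
    """P(observed VAF >= g) for true VAF v at the given depth (outer in g)."""
    a = np.clip(v, 1e-12, 1.0)[:, None] * depth
    b = np.clip(1.0 - v, 1e-12, 1.0)[:, None] * depth
    return special.betainc(a, b, np.clip(g, 0.0, 1.0)[None, :], out=None) * -1 + 1.0


def _size_bins(n_cap: float, n_bins: int) -> np.ndarray:
    """Log-spaced integer clone-size bin edges 1..n_cap (strictly increasing)."""
    edges = np.unique(np.rint(np.geomspace(1.0, max(n_cap, 2.0), n_bins)).astype(np.int64))
    return edges


def observed_model(
    params: SciferParams,
    t: float,
    depth: int,
    min_variant_reads: int = 3,
    grid: np.ndarray | None = None,
    n_bins: int = 48,
    n_nodes: int = 96,
    model: str = "neutral",
) -> tuple[np.ndarray, np.ndarray]:
    """Expected cumulative variant count over an observed-VAF grid.

    The expected spectrum is binned over log-spaced clone sizes, each bin
    convolved with the beta sequencing-noise kernel and truncated below the
    detection limit ``(min_variant_reads - 0.5)/depth``.  Returns
    ``(grid, expected_counts)`` where ``expected_counts[j]`` is the expected
    number of detected variants with observed VAF >= grid[j].
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    thr = (min_variant_reads - 0.5) / depth
    if grid is None:
        grid = default_vaf_grid(depth, min_variant_reads)
    if model not in ("neutral", "selected"):
        raise ValueError(f"unknown model {model!r}")

    n_eff = params.n_ss if params.t_b <= t else float(np.exp(params.lambda_exp * t))
    sel = None
    neutral_params = params
    scale_c = 1.0
    if model == "selected":
        sel = selected_clone_model(params, t)
        neutral_params = replace(params, t_s=None, r=None)
        # the residual population holds a fraction of the pool: its variant
        # production scales with that share (lineage drift is unregulated in
        # a linear birth-death model, so sizes/VAFs are left unscaled)
        scale_c = sel["residual_fraction"]

    # align bin edges with the grid's clone-size thresholds so binning is
    # exact where the cumulative curve is read off
    grid_m = np.ceil(np.clip(grid, 0.0, 0.5) * 2.0 * n_eff).astype(np.int64)
    edges = np.unique(np.concatenate([_size_bins(n_eff, n_bins), grid_m[grid_m >= 1]]))
    tails = expected_size_tail(neutral_params, t, edges, n_nodes=n_nodes)
    # counts[k] = C(m_k) - C(m_{k+1}); the last bin keeps the whole tail
    counts = np.concatenate([tails[:-1] - tails[1:], tails[-1:]])
    mids = np.sqrt(edges * np.append(edges[1:], n_eff).clip(min=edges))
    v_mid = np.clip(mids / (2.0 * n_eff), 0.0, 0.5)
    counts = counts * scale_c

    vs = [v_mid]
    cs = [counts]
    if sel is not None:
        # founder atom
        vs.append(np.array([sel["clone_vaf"]]))
        cs.append(np.array([sel["n_clonal"]]))
        # subclonal variants inside the clone: supercritical growth while the
        # clone expands, then size-regulated (critical) drift once the clone
        # has swept the pool
        p = params
        ts, r, lam = p.t_s, p.r, p.lambda_ss

        def m_raw(d):
            a, _, E = _bd_phase(lam, lam * (1.0 - r), d)
            return E / np.maximum(1.0 - a, 1e-300)

        dt_total = t - ts
        if m_raw(dt_total) >= p.n_ss:
            from scipy.optimize import brentq

            d_cap = brentq(lambda d: m_raw(d) - p.n_ss, 1e-12, dt_total)
        else:
            d_cap = dt_total
        t_cap = ts + d_cap
        tau, w = _gauss_nodes(ts, t, max(n_nodes // 2, 16))
        a1, b1, m1 = _bd_phase(
            lam, lam * (1.0 - r), np.maximum(np.minimum(t_cap, t) - tau, 0.0)
        )
        a2, b2, m2 = _bd_phase(lam, lam, np.maximum(t - np.maximum(tau, t_cap), 0.0))
        alpha, beta, _ = _compose(a1, b1, m1, a2, b2, m2)
        sizes = np.minimum(m_raw(np.maximum(tau - ts, 0.0)), p.n_ss)
        sub_edges = _size_bins(sel["clone_size"], max(n_bins // 2, 8))
        sub_edges = np.unique(np.concatenate([sub_edges, grid_m[grid_m >= 1]]))
        sub_tail = p.mu * (w * lam * sizes) @ (
            (1 - alpha)[:, None] * beta[:, None] ** np.maximum(sub_edges - 1.0, 0.0)
        )
        sub_counts = np.concatenate([sub_tail[:-1] - sub_tail[1:], sub_tail[-1:]])
        sub_mids = np.sqrt(sub_edges * np.append(sub_edges[1:], sel["clone_size"]).clip(min=sub_edges))
        vs.append(np.clip(sub_mids / (2.0 * p.n_ss), 0.0, sel["clone_vaf"]))
        cs.append(sub_counts)

    v_all = np.concatenate(vs)
    c_all = np.concatenate(cs)
    keep = c_all > 0
    v_all, c_all = v_all[keep], c_all[keep]
    if v_all.size == 0:
        return grid, np.zeros_like(grid)
    # read-count discretization: an observed VAF clears grid point g iff the
    # rounded variant-read count reaches ceil(g*depth), i.e. the underlying
    # beta draw exceeds (ceil(g*depth) - 0.5)/depth; detection limit likewise
    g_eff = np.maximum((np.ceil(grid * depth - 1e-9) - 0.5) / depth, thr)
    tail_probs = _beta_tail(v_all, float(depth), g_eff)
    curve = c_all @ tail_probs
    return grid, curve


def default_vaf_grid(depth: int, min_variant_reads: int = 3, n: int = 40) -> np.ndarray:
    """Log-spaced observed-VAF grid from the detection limit up to 0.5."""
    v_det = min_variant_reads / depth
    inv = np.geomspace(2.0, 1.0 / v_det, n)  # 1/VAF from 2 (clonal) to 1/detection
    return np.sort(1.0 / inv)  # ascending observed-VAF grid


def observed_cumulative_counts(observed_vafs, grid: np.ndarray) -> np.ndarray:
    """Empirical cumulative count of variants with observed VAF >= grid[j]."""
    v = np.sort(np.asarray(observed_vafs, dtype=float))
    return len(v) - np.searchsorted(v, grid, side="left")


@dataclass
class AbcResult:
    """Accepted ABC particles with distances and posterior summaries."""

    particles: pd.DataFrame  # accepted, sorted by distance (ascending)
    distances: np.ndarray
    model: str  # "neutral" or "selected"
    summary: dict
    seed: int | None
    n_particles: int
    accept_fraction: float

    @property
    def median_distance(self) -> float:
        return float(np.median(self.distances))

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "summary": self.summary,
            "median_distance": self.median_distance,
            "best_distance": float(self.distances[0]),
            "n_particles": self.n_particles,
            "accept_fraction": self.accept_fraction,
            "seed": self.seed,
        }


def _check_units(priors: SciferPriors, unit: str):
    if priors.unit != unit:
        raise UnitMismatchError(
            f"priors are per-{priors.unit} but data are tagged per-{unit}; "
            "pass matching priors (SciferPriors.mouse() for weeks, "
            "SciferPriors.human() for years)"
        )


class SciferABC:
    """Rejection-ABC fit of the SFS model to an observed VAF sample.

    ``t`` is the sampling age counted from birth (end of expansion); each
    particle's absolute model time is t_b + t, with t_b = ln(N_ss)/lambda_exp
    varying across particles.  Reported ``t_s`` values are likewise ages
    after birth.

    Particles are drawn from the uniform priors (log10 mu, log10 lambda_ss,
    log10 N_ss, and for the selected model t_s and r); for each particle the
    expected observed cumulative variant-count curve is evaluated on a
    log-spaced 1/VAF grid covering [detection limit, 0.5] and compared with
    the data's empirical curve.  The default ``distance="rms_log"`` is the
    root-mean-square difference of log1p(counts) — variance-stabilizing for
    count data, so the high-VAF tail (which carries the population-size and
    drift-timescale signal) is not drowned by Poisson noise in the large
    counts at the detection limit; ``distance="rms"`` compares raw counts.
    The top ``accept_fraction`` of particles by distance is kept.

    Attributes after ``fit(observed_vafs)``: ``result_`` (AbcResult),
    ``particles_``, ``posterior_summary_``, ``fixation_time_`` (posterior
    median of N_ss/lambda_ss).
    """

    def __init__(
        self,
        priors: SciferPriors | None = None,
        t: float = 35.0,
        unit: str = "week",
        model: str = "neutral",
        n_particles: int = 20000,
        accept_fraction: float = 0.01,
        depth: int = 90,
        min_variant_reads: int = 3,
        lambda_exp: float = 1.0,
        distance: str = "rms_log",
        random_state: int | None = None,
    ):
        self.priors = priors
        self.t = t
        self.unit = unit
        self.model = model
        self.n_particles = n_particles
        self.accept_fraction = accept_fraction
        self.depth = depth
        self.min_variant_reads = min_variant_reads
        self.lambda_exp = lambda_exp
        self.distance = distance
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "priors",
                "t",
                "unit",
                "model",
                "n_particles",
                "accept_fraction",
                "depth",
                "min_variant_reads",
                "lambda_exp",
                "distance",
                "random_state",
            )
        }

    def set_params(self, **params) -> "SciferABC":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, observed_vafs) -> "SciferABC":
        v = np.asarray(observed_vafs, dtype=float)
        if v.size == 0:
            raise ValueError("empty VAF data")
        if v.size < 5:
            warnings.warn("fewer than 5 variants: ABC posterior will be weak")
        priors = self.priors or (
            SciferPriors.mouse() if self.unit == "week" else SciferPriors.human()
        )
        _check_units(priors, self.unit)
        if self.model not in ("neutral", "selected"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.distance not in ("rms_log", "rms"):
            raise ValueError(f"unknown distance {self.distance!r}")
        rng = np.random.default_rng(self.random_state)
        t = float(self.t)
        grid = default_vaf_grid(self.depth, self.min_variant_reads)
        data_curve = observed_cumulative_counts(v, grid)
        data_ref = np.log1p(data_curve) if self.distance == "rms_log" else data_curve

        n = self.n_particles
        log10_mu = rng.uniform(*priors.log10_mu, n)
        log10_lss = rng.uniform(*priors.log10_lambda_ss, n)
        log10_nss = rng.uniform(*priors.log10_n_ss, n)
        cols = {
            "mu": 10.0**log10_mu,
            "lambda_ss": 10.0**log10_lss,
            "n_ss": 10.0**log10_nss,
        }
        if self.model == "selected":
            ts_bounds = priors.t_s or (0.0, t)
            cols["t_s"] = rng.uniform(ts_bounds[0], min(ts_bounds[1], t), n)
            cols["r"] = rng.uniform(*priors.r, n)

        dist = np.empty(n)
        for i in range(n):
            kwargs = dict(
                mu=cols["mu"][i],
                lambda_ss=cols["lambda_ss"][i],
                n_ss=max(cols["n_ss"][i], 1.0 + 1e-9),
                lambda_exp=self.lambda_exp,
                unit=self.unit,
            )
            p = SciferParams(**kwargs)
            t_abs = total_time(p, t)  # t is the sampling age after birth
            if self.model == "selected":
                # t_s is sampled as an age after birth; model clock is absolute
                t_s_abs = p.t_b + min(cols["t_s"][i], t * (1 - 1e-9))
                kwargs["t_s"] = t_s_abs
                kwargs["r"] = min(max(cols["r"][i], 1e-9), 1 - 1e-9)
                p = SciferParams(**kwargs)
            _, curve = observed_model(
                p,
                t_abs,
                self.depth,
                self.min_variant_reads,
                grid=grid,
                model=self.model,
            )
            if self.distance == "rms_log":
                dist[i] = np.sqrt(np.mean((np.log1p(curve) - data_ref) ** 2))
            else:
                dist[i] = np.sqrt(np.mean((curve - data_ref) ** 2))

        n_keep = max(int(np.ceil(self.accept_fraction * n)), 1)
        order = np.argsort(dist, kind="stable")[:n_keep]
        if not np.isfinite(dist[order]).any():
            raise RuntimeError("no finite-distance particles accepted")
        particles = pd.DataFrame({k: np.asarray(c)[order] for k, c in cols.items()})
        particles["distance"] = dist[order]
        particles["t_fix"] = particles["n_ss"] / particles["lambda_ss"]

        qs = [0.025, 0.5, 0.975]
        summary = {
            col: {f"q{100 * q:g}": float(particles[col].quantile(q)) for q in qs}
            for col in particles.columns
            if col != "distance"
        }
        self.result_ = AbcResult(
            particles=particles,
            distances=particles["distance"].to_numpy(),
            model=self.model,
            summary=summary,
            seed=self.random_state,
            n_particles=n,
            accept_fraction=self.accept_fraction,
        )
        self.particles_ = particles
        self.posterior_summary_ = summary
        self.fixation_time_ = summary["t_fix"]["q50"]
        self.grid_ = grid
        self.data_curve_ = data_curve
        return self


def abc_fit(
    observed_vafs,
    priors: SciferPriors | None = None,
    t: float = 35.0,
    model: str = "neutral",
    n_particles: int = 20000,
    accept_fraction: float = 0.01,
    depth: int = 90,
    min_variant_reads: int = 3,
    unit: str = "week",
    distance: str = "rms_log",
    seed: int | None = None,
) -> AbcResult:
    """Functional wrapper around :class:`SciferABC`."""
    est = SciferABC(
        priors=priors,
        t=t,
        unit=unit,
        model=model,
        n_particles=n_particles,
        accept_fraction=accept_fraction,
        depth=depth,
        min_variant_reads=min_variant_reads,
        distance=distance,
        random_state=seed,
    )
    est.fit(observed_vafs)
    return est.result_


def classify_clonality(
    neutral_fit: AbcResult,
    selected_fit: AbcResult,
    threshold: float = 0.2,
    n_best: int = 5,
) -> dict:
    """Neutral drift vs clonal expansion by relative ABC fit improvement.

    Each model is scored by the median distance of its ``n_best`` best
    accepted particles (the full accepted set dilutes the
    higher-dimensional selected model with mediocre particles, biasing a
    whole-set median toward neutral).  The clonal model wins when its score
    improves on the neutral model's by more than ``threshold`` (relative);
    ties and small improvements go to neutral drift (parsimony).
    """

    def score(fit: AbcResult) -> float:
        k = min(n_best, len(fit.distances))
        return float(np.median(np.sort(fit.distances)[:k]))

    d_n = score(neutral_fit)
    d_s = score(selected_fit)
    improvement = (d_n - d_s) / d_n if d_n > 0 else 0.0
    verdict = "clonal_expansion" if improvement > threshold else "neutral_drift"
    return {
        "verdict": verdict,
        "neutral_distance": d_n,
        "selected_distance": d_s,
        "relative_improvement": improvement,
        "threshold": threshold,
    }


def clonal_snv_age_estimate(n_clonal: int, mu: float, lambda_ss: float) -> float:
    """Descriptive clone-age proxy: clonal sSNV count / (mu * lambda_ss).

    Non-canonical convenience — the ratio of accrued clonal variants to the
    variant accrual rate per lineage; not a formal estimator.
    """
    if mu <= 0 or lambda_ss <= 0:
        raise ValueError("mu and lambda_ss must be > 0")
    return n_clonal / (mu * lambda_ss)
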