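"""Single-cell-resolution stochastic simulator with infinite-sites mutations.

A population starts from one somatically unmutated founder, expands by a
pure-birth (Yule) process at rate ``lambda_e`` to a target size, then follows
a linear birth-death process (subcritical attrition ``delta > lambda`` or
critical homeostasis ``delta = lambda``) simulated exactly with the Gillespie
algorithm.  Every division copies the mother's mutations to both daughters
and appends one novel integer index per daughter (infinite-sites), so the
full site frequency spectrum (SFS) and true variant allele frequencies
(VAF = n / 2N) can be read out at any checkpoint.

Internally the population is a persistent lineage tree: each cell is a node
carrying exactly one minted mutation (the founder none); a mutation's carrier
count is the number of living cells in that node's subtree, recovered by
walking each living cell's ancestry.  Per-cell mutation vectors are a view
(`Population.mutations_of`), not stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "Population",
    "SiteFrequencySpectrum",
    "VafDataset",
    "MouseResult",
    "expand_population",
    "evolve",
    "sfs",
    "to_vafs",
    "apply_sequencing_noise",
    "thin_sfs",
    "simulate_cohort",
    "simulate_pool_size",
    "sample_extinction_time",
    "cumulative_vaf_curve",
]


@dataclass
class SimConfig:
    """Simulation scenario.

    ``regime`` is ``"attrition"`` (subcritical: ``delta > lam``) or
    ``"homeostasis"`` (critical: loss rate equals ``lam``, expected size
    constant).  ``checkpoints`` are measured in weeks after birth, i.e. after
    the expansion phase reaches ``n_target``.
    """

    n_target: int
    regime: str = "attrition"
    lam: float = 0.538 / 3.0  # division rate after birth (1/week)
    delta: float = 1.0 / 3.0  # loss rate after birth (1/week)
    lambda_e: float = 1.0  # expansion division rate (1/week)
    checkpoints: tuple[float, ...] = (5.0, 25.0, 30.0, 35.0)
    seed: int | None = None

    def __post_init__(self):
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        if self.regime == "attrition":
            if not self.delta > self.lam:
                raise ValueError("attrition regime requires delta > lam")
        elif self.regime == "homeostasis":
            self.delta = self.lam
        else:
            raise ValueError(f"unknown regime {self.regime!r}")
        if list(self.checkpoints) != sorted(self.checkpoints):
            raise ValueError("checkpoints must be sorted ascending")


@dataclass
class Population:
    """Lineage-tree population state.

    ``parent[i]`` is the parent node of node ``i`` (founder has -1); node
    ``i > 0`` carries the unique mutation with index ``i`` minted at its
    creation.  ``alive`` lists the node ids of living cells.
    """

    parent: list = field(default_factory=lambda: [-1])
    birth_time: list = field(default_factory=lambda: [0.0])
    alive: list = field(default_factory=lambda: [0])
    time: float = 0.0
    t_birth: float | None = None  # time expansion reached the target size
    n_divisions: int = 0
    extinction_time: float | None = None

    @property
    def size(self) -> int:
        return len(self.alive)

    @property
    def extinct(self) -> bool:
        return not self.alive

    @property
    def n_mutations_minted(self) -> int:
        """Total distinct mutation indices ever created (2 per division)."""
        return len(self.parent) - 1

    def mutations_of(self, cell: int) -> frozenset[int]:
        """Mutation set of one cell: the indices on its ancestry path."""
        out = []
        node = cell
        parent = self.parent
        while node > 0:
            out.append(node)
            node = parent[node]
        return frozenset(out)


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """S_n: number of mutations carried by exactly n of the N living cells."""

    counts: dict[int, int]
    population_size: int
    extinct: bool = False

    def __post_init__(self):
        for n in self.counts:
            if not (1 <= n <= max(self.population_size, 1)):
                raise ValueError(f"frequency {n} outside [1, N={self.population_size}]")

    @property
    def n_segregating(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class VafDataset:
    """Per-variant read counts after sequencing noise; pandas-friendly."""

    true_vaf: np.ndarray
    observed_vaf: np.ndarray
    depth: np.ndarray
    variant_reads: np.ndarray
    reference_reads: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "true_vaf": self.true_vaf,
                "observed_vaf": self.observed_vaf,
                "depth": self.depth,
                "variant_reads": self.variant_reads,
                "reference_reads": self.reference_reads,
            }
        )


def expand_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Yule expansion from one unmutated founder to exactly ``n_target`` cells."""
    pop = Population()
    parent, birth_time, alive = pop.parent, pop.birth_time, pop.alive
    lam_e = config.lambda_e
    t = 0.0
    while len(alive) < config.n_target:
        n = len(alive)
        t += rng.exponential(1.0 / (lam_e * n))
        i = int(rng.integers(n))
        mother = alive[i]
        c1 = len(parent)
        parent.append(mother)
        parent.append(mother)
        birth_time.append(t)
        birth_time.append(t)
        alive[i] = c1
        alive.append(c1 + 1)
        pop.n_divisions += 1
    pop.time = t
    pop.t_birth = t
    return pop


def evolve(
    pop: Population,
    lam: float,
    delta: float,
    duration: float,
    rng: np.random.Generator,
    max_size: int | None = None,
) -> Population:
    """Exact Gillespie birth-death for ``duration`` time units (in place).

    Per-cell division rate ``lam`` (two daughters, one novel mutation each),
    per-cell loss rate ``delta``.  An extinct population stays extinct.
    With ``max_size`` the run stops early once the population reaches that
    size (supercritical runs would otherwise grow without bound);
    ``pop.time`` then sits at the stopping point.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    t_end = pop.time + duration
    parent, birth_time, alive = pop.parent, pop.birth_time, pop.alive
    total = lam + delta
    p_div = lam / total if total > 0 else 0.0
    t = pop.time
    while alive:
        n = len(alive)
        if total == 0:
            break
        if max_size is not None and n >= max_size:
            pop.time = t
            return pop
        t_next = t + rng.exponential(1.0 / (total * n))
        if t_next > t_end:
            break
        t = t_next
        i = int(rng.integers(n))
        if rng.random() < p_div:
            mother = alive[i]
            c1 = len(parent)
            parent.append(mother)
            parent.append(mother)
            birth_time.append(t)
            birth_time.append(t)
            alive[i] = c1
            alive.append(c1 + 1)
            pop.n_divisions += 1
        else:
            alive[i] = alive[-1]
            alive.pop()
            if not alive:
                pop.extinction_time = t
    pop.time = t_end if alive else (pop.extinction_time or t_end)
    return pop


def sfs(pop: Population, cells: Sequence[int] | None = None) -> SiteFrequencySpectrum:
    """Site frequency spectrum of the living population.

    ``cells`` restricts the spectrum to a subset of the living cells
    (e.g. a subsampled residual population).
    """
    members = pop.alive if cells is None else list(cells)
    if not members:
        return SiteFrequencySpectrum(counts={}, population_size=0, extinct=True)
    carriers = np.zeros(len(pop.parent), dtype=np.int64)
    parent = pop.parent
    for cell in members:
        node = cell
        while node != -1:
            carriers[node] += 1
            node = parent[node]
    freq = carriers[1:]  # node 0 (founder) carries no mutation
    freq = freq[freq > 0]
    values, counts = np.unique(freq, return_counts=True)
    return SiteFrequencySpectrum(
        counts={int(v): int(c) for v, c in zip(values, counts)},
        population_size=len(members),
    )


def to_vafs(spectrum: SiteFrequencySpectrum) -> np.ndarray:
    """Map the SFS to true VAFs n/(2N), one entry per mutation (max 0.5)."""
    N = spectrum.population_size
    if N < 1:
        raise ValueError("population_size must be >= 1")
    out = []
    for n, s in sorted(spectrum.counts.items()):
        if n > N:
            raise ValueError(f"corrupted spectrum: frequency {n} > N = {N}")
        out.extend([n / (2.0 * N)] * s)
    return np.asarray(out, dtype=float)


def thin_sfs(
    spectrum: SiteFrequencySpectrum, mu: float, rng: np.random.Generator
) -> SiteFrequencySpectrum:
    """Thin mutations binomially to an effective rate of ``mu`` per division.

    The simulator mints exactly one mutation per daughter per division
    (mu = 2); datasets requiring mu != 2 keep each minted mutation
    independently with probability mu/2.
    """
    if not (0 < mu <= 2):
        raise ValueError("mu must be in (0, 2] for thinning")
    keep = mu / 2.0
    counts = {
        n: int(rng.binomial(s, keep)) for n, s in spectrum.counts.items()
    }
    counts = {n: s for n, s in counts.items() if s > 0}
    return SiteFrequencySpectrum(
        counts=counts,
        population_size=spectrum.population_size,
        extinct=spectrum.extinct,
    )


def apply_sequencing_noise(
    true_vafs: Iterable[float],
    depth: int,
    min_variant_reads: int = 3,
    rng: np.random.Generator | None = None,
) -> VafDataset:
    """Beta sequencing noise around the true VAFs at a given depth.

    Observed VAF ~ Beta(v*D, (1-v)*D) (mean v, concentration D); variant
    reads = round(observed VAF * D); variants with fewer than
    ``min_variant_reads`` variant reads are below the detection limit and
    dropped.  Degenerate v = 0 or 1 pass through without sampling.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = rng or np.random.default_rng()
    v = np.asarray(list(true_vafs), dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("true VAFs must lie in [0, 1]")
    obs = np.empty_like(v)
    interior = (v > 0) & (v < 1)
    obs[~interior] = v[~interior]
    if interior.any():
        obs[interior] = rng.beta(v[interior] * depth, (1 - v[interior]) * depth)
    reads = np.rint(obs * depth).astype(int)
    keep = reads >= min_variant_reads
    reads = reads[keep]
    return VafDataset(
        true_vaf=v[keep],
        observed_vaf=reads / depth,
        depth=np.full(reads.shape, depth, dtype=int),
        variant_reads=reads,
        reference_reads=depth - reads,
    )


@dataclass
class MouseResult:
    """Per-mouse output of a cohort simulation."""

    mouse: int
    spectra: dict[float, SiteFrequencySpectrum | None]  # checkpoint -> SFS
    extinction_time: float | None  # weeks after birth; None if censored
    censored_at: float | None = None


def _mouse_rng(master_seed: int | None, mouse_index: int) -> np.random.Generator:
    """Independent, reproducible substream keyed (master_seed, mouse_index)."""
    if master_seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), mouse_index]))


def simulate_cohort(
    config: SimConfig, n_mice: int = 100, max_weeks: float = 500.0
) -> list[MouseResult]:
    """Simulate a cohort; record the SFS at each checkpoint reached alive.

    Checkpoints count weeks after birth (end of expansion).  For the
    attrition regime the simulation continues past the last checkpoint until
    extinction (capped at ``max_weeks``, then censored) so Kaplan-Meier
    cohorts can be synthesised from the extinction times.
    """
    results = []
    for m in range(n_mice):
        rng = _mouse_rng(config.seed, m)
        pop = expand_population(config, rng)
        t0 = pop.t_birth
        spectra: dict[float, SiteFrequencySpectrum | None] = {}
        for ck in config.checkpoints:
            if not pop.extinct:
                evolve(pop, config.lam, config.delta, t0 + ck - pop.time, rng)
            spectra[ck] = sfs(pop) if not pop.extinct else None
        ext = None
        censored_at = None
        if config.regime == "attrition":
            if not pop.extinct:
                evolve(pop, config.lam, config.delta, t0 + max_weeks - pop.time, rng)
            if pop.extinct:
                ext = pop.extinction_time - t0
            else:
                censored_at = max_weeks
        results.append(
            MouseResult(
                mouse=m, spectra=spectra, extinction_time=ext, censored_at=censored_at
            )
        )
    return results


def simulate_pool_size(
    n0: int,
    lam: float,
    delta: float,
    checkpoints: Sequence[float],
    rng: np.random.Generator,
    max_time: float = 1e6,
) -> tuple[np.ndarray, float | None]:
    """Size-only Gillespie run (no mutation tracking) from ``n0`` cells.

    Returns the population size at each checkpoint and the extinction time
    (None if still alive at ``max(checkpoints)`` and ``max_time``).
    """
    checkpoints = np.asarray(checkpoints, dtype=float)
    sizes = np.zeros(checkpoints.shape, dtype=int)
    n = int(n0)
    t = 0.0
    total = lam + delta
    p_div = lam / total if total > 0 else 0.0
    subcritical = delta > lam
    ext: float | None = None
    next_idx = 0
    while n > 0 and total > 0:
        t_next = t + rng.exponential(1.0 / (total * n))
        while next_idx < len(checkpoints) and checkpoints[next_idx] < t_next:
            sizes[next_idx] = n
            next_idx += 1
        if next_idx >= len(checkpoints):
            # past all checkpoints: continue only to observe extinction,
            # which is certain (and worth waiting for) only when subcritical
            if not subcritical or t_next > max_time:
                break
        t = t_next
        if rng.random() < p_div:
            n += 1
        else:
            n -= 1
        if n == 0:
            ext = t
    while next_idx < len(checkpoints):
        sizes[next_idx] = n
        next_idx += 1
    return sizes, ext


def sample_extinction_time(
    n0: int, lam: float, delta: float, rng: np.random.Generator, max_time: float = 1e4
) -> float | None:
    """Extinction time of a subcritical pool (None if beyond ``max_time``)."""
    if delta <= lam:
        raise ValueError("extinction sampling requires delta > lam")
    _, ext = simulate_pool_size(n0, lam, delta, [], rng, max_time=max_time)
    return ext


def cumulative_vaf_curve(vafs: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative variant count against 1/VAF.

    Variants are sorted by decreasing VAF (ties keep input order); point k is
    (1/VAF_(k), k).  Under neutral homeostasis the curve is approximately
    linear in 1/VAF, the classic neutral scaling.
    """
    v = np.asarray(list(vafs), dtype=float)
    if np.any(v <= 0):
        raise ValueError("VAFs must be > 0")
    order = np.argsort(-v, kind="stable")
    inv = 1.0 / v[order]
    return inv, np.arange(1, len(inv) + 1)
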