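"""Synthetic-data generators for every input the pipeline consumes.

Each generator returns plain pandas/numpy objects plus a machine-readable
``truth`` dict holding every generating parameter, so downstream recovery
tests read truth only from there.  Defaults mirror the fitted operating
regime of the attrition study system: about 100 blood-forming ancestors at
birth, a mean ancestor lifetime of 3 weeks (delta = 1/3 per week) and a
division-before-loss probability around 35-40% (xi ~ 0.54-0.6); VAF
datasets emulate 90x granulocyte and 30x germline sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from clonedrift import clonesim
from clonedrift.attrition import AttritionParams
from clonedrift.varfilter import CONTEXT_CLASSES

__all__ = [
    "SynthScenario",
    "gen_km_cohort",
    "gen_vaf_dataset",
    "gen_filter_fixture",
]


@dataclass
class SynthScenario:
    """A named generating scenario with its parameters and depths."""

    tag: str  # neutral_drift | selected_clone | attrition_cohort | filter_fixture
    params: dict[str, Any] = field(default_factory=dict)
    depth: int = 90  # granulocyte sequencing depth
    germline_depth: int = 30
    seed: int | None = None

    _TAGS = ("neutral_drift", "selected_clone", "attrition_cohort", "filter_fixture")

    def __post_init__(self):
        if self.tag not in self._TAGS:
            raise ValueError(f"unknown scenario tag {self.tag!r}")
        if self.depth <= 0 or self.germline_depth <= 0:
            raise ValueError("depths must be > 0")


def gen_km_cohort(
    params: AttritionParams,
    n_mice: int,
    censor_fraction: float = 0.0,
    seed: int | None = None,
    max_weeks: float = 500.0,
) -> pd.DataFrame:
    """Survival table ``animal_id, time_weeks, event`` from the attrition model.

    Extinction times are drawn by exact pool simulation; a ``censor_fraction``
    of the animals is right-censored uniformly before its extinction time
    (event 0), emulating deaths unrelated to marrow failure.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    if not (0.0 <= censor_fraction < 1.0):
        raise ValueError("censor_fraction must be in [0, 1)")
    rows = []
    n0 = int(round(params.n0))
    for m in range(n_mice):
        rng = clonesim._mouse_rng(seed, m)
        ext = clonesim.sample_extinction_time(
            n0, params.lam, params.delta, rng, max_time=max_weeks
        )
        if ext is None:
            rows.append((f"M{m:03d}", max_weeks, 0))
            continue
        if rng.random() < censor_fraction:
            rows.append((f"M{m:03d}", float(rng.uniform(0.0, ext)), 0))
        else:
            rows.append((f"M{m:03d}", float(ext), 1))
    return pd.DataFrame(rows, columns=["animal_id", "time_weeks", "event"])


def _simulate_neutral(n_ss, lambda_ss, mu, age, rng):
    cfg = clonesim.SimConfig(
        n_target=int(n_ss), regime="homeostasis", lam=lambda_ss, checkpoints=(age,)
    )
    pop = clonesim.expand_population(cfg, rng)
    clonesim.evolve(pop, lambda_ss, lambda_ss, pop.t_birth + age - pop.time, rng)
    if pop.extinct:
        return None
    spectrum = clonesim.sfs(pop)
    if mu != 2.0:
        spectrum = clonesim.thin_sfs(spectrum, mu, rng)
    return pop, spectrum


def gen_vaf_dataset(scenario: SynthScenario) -> tuple[pd.DataFrame, dict]:
    """Single-timepoint VAF table plus truth for neutral/selected scenarios.

    Neutral: Yule expansion to N_ss then critical homeostasis to the
    sampling age, mutation thinning to the requested per-division rate mu,
    beta sequencing noise at the granulocyte depth with the 3-variant-read
    detection limit.

    Selected: a neutral residual population combined with a clone founded at
    age ``t_s`` growing supercritically (division lambda_ss, loss
    lambda_ss*(1-r), conditioned on survival); the clone founder carries its
    lineage's accrued variants, which become clonal (VAF 0.5 at fixation).

    Returns ``(vaf_table, truth)``; the table has synthetic chrom/pos
    placeholders and columns true_vaf, observed_vaf, depth, variant_reads,
    reference_reads.
    """
    rng = np.random.default_rng(scenario.seed)
    p = dict(scenario.params)
    if scenario.tag == "neutral_drift":
        n_ss = p.get("n_ss", 1500)
        lambda_ss = p.get("lambda_ss", 1.5)
        mu = p.get("mu", 1.0)
        age = p.get("age", 35.0)
        sim = _simulate_neutral(n_ss, lambda_ss, mu, age, rng)
        if sim is None:
            raise RuntimeError("population went extinct before the sampling age")
        _, spectrum = sim
        true_vafs = clonesim.to_vafs(spectrum)
        truth = {
            "scenario": "neutral_drift",
            "n_ss": n_ss,
            "lambda_ss": lambda_ss,
            "mu": mu,
            "age": age,
            "fixation_time": n_ss / lambda_ss,
            "clone_vaf": None,
            "depth": scenario.depth,
            "seed": scenario.seed,
        }
    elif scenario.tag == "selected_clone":
        n_ss = p.get("n_ss", 1500)
        lambda_ss = p.get("lambda_ss", 1.5)
        mu = p.get("mu", 1.0)
        age = p.get("age", 35.0)
        t_s = p.get("t_s", 5.0)  # clone emergence, weeks after birth
        r = p.get("r", 0.8)
        if not (0 <= t_s < age):
            raise ValueError("t_s must lie in [0, age)")
        sim = _simulate_neutral(n_ss, lambda_ss, mu, age, rng)
        if sim is None:
            raise RuntimeError("residual population went extinct")
        res_pop, _ = sim
        # clone: supercritical birth-death from one cell, conditioned alive;
        # once it reaches the homeostatic pool size it is size-regulated and
        # drifts critically for the remaining time (fixation)
        cap = int(n_ss)
        for _ in range(1000):
            clone = clonesim.Population()
            clonesim.evolve(
                clone, lambda_ss, lambda_ss * (1 - r), age - t_s, rng, max_size=cap
            )
            if not clone.extinct:
                break
        else:  # pragma: no cover - p(survival) >> 1e-3 for sensible r
            raise RuntimeError("clone went extinct in 1000 attempts")
        swept = clone.size >= cap
        if swept and clone.time < age - t_s:
            # sweep complete: the clone IS the pool, drifting critically
            clonesim.evolve(clone, lambda_ss, lambda_ss, age - t_s - clone.time, rng)
        clone_spec = clonesim.sfs(clone)
        if mu != 2.0:
            clone_spec = clonesim.thin_sfs(clone_spec, mu, rng)
        n_clone = clone.size
        # an incomplete sweep leaves residual ancestors; a completed sweep
        # displaced them all
        n_res = 0 if swept else max(int(n_ss) - n_clone, 0)
        if n_res > 0 and res_pop.size > 0:
            idx = rng.choice(res_pop.size, size=min(n_res, res_pop.size), replace=False)
            res_cells = [res_pop.alive[i] for i in idx]
        else:
            res_cells = []
        res_spec = clonesim.sfs(res_pop, cells=res_cells)
        if mu != 2.0 and not res_spec.extinct:
            res_spec = clonesim.thin_sfs(res_spec, mu, rng)
        n_total = len(res_cells) + n_clone
        # founder lineage variants accrued up to t_s become clonal
        t_b = np.log(n_ss)  # lambda_exp = 1
        n_clonal = rng.poisson(mu * (t_b + lambda_ss * t_s))
        vaf_parts = [np.full(n_clonal, n_clone / (2.0 * n_total))]
        if len(res_cells):
            # rescale subset VAFs n/(2 n_sub) to the combined pool n/(2 n_total)
            vaf_parts.append(
                clonesim.to_vafs(res_spec) * len(res_cells) / n_total
            )
        vaf_parts.append(clonesim.to_vafs(clone_spec) * n_clone / n_total)
        true_vafs = np.concatenate(vaf_parts)
        truth = {
            "scenario": "selected_clone",
            "n_ss": n_ss,
            "lambda_ss": lambda_ss,
            "mu": mu,
            "age": age,
            "t_s": t_s,
            "r": r,
            "clone_cells": int(n_clone),
            "residual_cells": int(len(res_cells)),
            "clone_vaf": n_clone / (2.0 * n_total),
            "n_clonal_variants": int(n_clonal),
            "depth": scenario.depth,
            "seed": scenario.seed,
        }
    else:
        raise ValueError(
            "gen_vaf_dataset handles neutral_drift/selected_clone; "
            "use simulate_cohort for attrition checkpoints"
        )

    ds = clonesim.apply_sequencing_noise(true_vafs, scenario.depth, 3, rng)
    table = ds.to_frame()
    table.insert(0, "chrom", "syn1")
    table.insert(1, "pos", np.arange(1, len(table) + 1) * 1000)
    return table, truth


def gen_filter_fixture(
    n_samples: int = 6,
    n_true: int = 40,
    n_artifacts: int = 10,
    n_panel_samples: int = 55,
    n_sites_per_class: int = 100,
    background_scale: float = 0.1,
    seed: int | None = None,
) -> dict:
    """Cohort fixture for the variant filter cascade, with planted truth.

    The focal sample carries ``n_true`` genuine private somatic variants
    (VAF >= 0.05, absent from all other samples), ``n_artifacts`` recurrent
    technical artifacts (VAF above the context baseline in >= 2 other
    samples, emulating shared strain-background noise), and hard-filter
    victims: low-read variants, SNP-database sites, and variants inside
    repeat and copy-number-altered regions.  A random-site background panel
    (``n_panel_samples`` x ``n_sites_per_class`` per class, VAFs scaled
    Beta(0.5, 30) — an explicit modelling invention) supports baseline
    construction.  Returns a dict with keys ``variants, cohort, panel,
    regions, snp_sites, truth``.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for cross-sample filtering")
    rng = np.random.default_rng(seed)
    classes = np.array(CONTEXT_CLASSES)

    # background panel: per-class scaled Beta(0.5, 30) VAFs at random sites
    scales = background_scale * (0.5 + rng.random(len(classes)))
    rows_cls = np.repeat(classes, n_sites_per_class * n_panel_samples)
    site = np.tile(
        np.repeat(np.arange(n_sites_per_class), n_panel_samples), len(classes)
    )
    samp = np.tile(
        [f"P{j:02d}" for j in range(n_panel_samples)],
        n_sites_per_class * len(classes),
    )
    vafs = rng.beta(0.5, 30.0, size=len(rows_cls)) * np.repeat(
        scales, n_sites_per_class * n_panel_samples
    )
    panel = pd.DataFrame(
        {"context_class": rows_cls, "site_id": site, "sample_id": samp, "vaf": vafs}
    )

    other_samples = [f"S{j}" for j in range(1, n_samples)]
    depth = 90

    def make_variants(n, vaf_lo, vaf_hi, start_pos, category):
        v = rng.uniform(vaf_lo, vaf_hi, n)
        reads = np.maximum(np.rint(v * depth).astype(int), 3)
        return pd.DataFrame(
            {
                "chrom": "syn1",
                "pos": start_pos + np.arange(n) * 100,
                "ref": rng.choice(list("CT"), n),
                "alt": "A",
                "context_class": rng.choice(classes, n),
                "variant_reads": reads,
                "reference_reads": depth - reads,
                "sample_id": "S0",
                "category": category,
            }
        )

    parts = [make_variants(n_true, 0.05, 0.45, 10_000, "true_somatic")]
    parts.append(make_variants(n_artifacts, 0.05, 0.45, 200_000, "recurrent_artifact"))
    # hard-filter victims
    low = make_variants(3, 0.01, 0.02, 300_000, "low_reads")
    low["variant_reads"] = rng.integers(1, 3, len(low))
    low["reference_reads"] = depth - low["variant_reads"]
    parts.append(low)
    parts.append(make_variants(3, 0.1, 0.4, 400_000, "snp_listed"))
    repeat_victims = make_variants(4, 0.1, 0.4, 500_000, "in_repeat")
    parts.append(repeat_victims)
    cna_victims = make_variants(2, 0.1, 0.4, 600_000, "in_cna")
    parts.append(cna_victims)
    variants = pd.concat(parts, ignore_index=True)
    truth_category = variants.pop("category")

    # cohort pileup matrix: VAF of each candidate in every OTHER sample
    cohort = pd.DataFrame(
        0.0, index=variants.index, columns=other_samples
    )
    art_idx = variants.index[truth_category == "recurrent_artifact"]
    for i in art_idx:
        hits = rng.choice(len(other_samples), size=rng.integers(2, len(other_samples) + 1), replace=False)
        cohort.loc[i, np.array(other_samples)[hits]] = rng.uniform(0.1, 0.3, len(hits))

    regions = {
        "repeat": pd.DataFrame(
            {
                "chrom": "syn1",
                "start": repeat_victims["pos"].to_numpy() - 1,
                "end": repeat_victims["pos"].to_numpy() + 49,
            }
        ),
        "cna": pd.DataFrame(
            {
                "chrom": "syn1",
                "start": cna_victims["pos"].to_numpy() - 1,
                "end": cna_victims["pos"].to_numpy() + 9,
            }
        ),
    }
    snp_mask = truth_category == "snp_listed"
    snp_sites = variants.loc[snp_mask, ["chrom", "pos", "ref", "alt"]].reset_index(
        drop=True
    )
    truth = {
        "category": truth_category.to_dict(),
        "n_true": n_true,
        "n_artifacts": n_artifacts,
        "true_index": variants.index[truth_category == "true_somatic"].tolist(),
        "n_samples": n_samples,
        "n_panel_samples": n_panel_samples,
        "background_scale": background_scale,
        "seed": seed,
    }
    return {
        "variants": variants,
        "cohort": cohort,
        "panel": panel,
        "regions": regions,
        "snp_sites": snp_sites,
        "truth": truth,
    }
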