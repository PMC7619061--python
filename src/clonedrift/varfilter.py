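"""Post-call somatic-variant filtering for deep-WGS cohorts.

Implements the filter cascade applied to somatic SNV/indel calls before any
VAF-based clonality analysis:

- VAF computation with the pseudo-diploid correction on male gonosomes;
- a cross-sample recurrence filter against a trinucleotide-context
  background baseline (panel-of-normals style): variants whose VAF in any
  *other* sample exceeds the upper 95% confidence bound of that context
  class's background VAF are technical artifacts of the strain background
  and are removed;
- hard filters: minimum variant-read count, SNP-database sites, and
  repeat / simple-repeat / copy-number-altered / LOH region exclusions;
- an indel cross-sample filter (any indel called in another animal's raw
  call set is removed; survivors must be confirmed by a second caller);
- germline heterozygous-site selection and tumor-VAF evaluation for LOH
  screening;
- two-caller structural-variant breakpoint concordance.

All filters are pure functions on pandas DataFrames returning
``(kept, removed)`` with a per-row ``reason`` column on the removed side, so
``kept + removed == input`` exactly and every removal is auditable.

Coordinates: variant tables are 1-based; BED region sets are 0-based
half-open, so a 1-based position p overlaps [start, end) iff
start < p <= end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXT_CLASSES",
    "collapse_context",
    "compute_vaf",
    "build_baseline",
    "recurrence_filter",
    "hard_filters",
    "indel_cross_sample_filter",
    "select_germline_hets",
    "evaluate_loh",
    "sv_concordance",
    "VariantFilterCascade",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"
SV_TYPES = frozenset({"DEL", "INS", "INV", "TRA", "DUP"})


def _context_classes() -> tuple[str, ...]:
    out = []
    for ref in "CT":
        for alt in _BASES:
            if alt == ref:
                continue
            for left in _BASES:
                for right in _BASES:
                    out.append(f"{left}[{ref}>{alt}]{right}")
    return tuple(out)


#: The 96 pyrimidine-centered substitution-in-trinucleotide classes.
CONTEXT_CLASSES: tuple[str, ...] = _context_classes()


def collapse_context(ref: str, alt: str, left: str, right: str) -> str:
    """Pyrimidine-collapsed trinucleotide class, e.g. ``A[C>T]G``.

    Purine references are reverse-complemented (flanks swap sides).
    """
    ref, alt, left, right = ref.upper(), alt.upper(), left.upper(), right.upper()
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        left, right = _COMPLEMENT[right], _COMPLEMENT[left]
    cls = f"{left}[{ref}>{alt}]{right}"
    if cls not in _CLASS_SET:
        raise ValueError(f"not a valid substitution context: {cls}")
    return cls


_CLASS_SET = frozenset(CONTEXT_CLASSES)
_GONOSOMES = {"X", "Y", "chrX", "chrY"}


def compute_vaf(variants: pd.DataFrame, sex: str | None = None) -> pd.DataFrame:
    """Add a ``vaf`` column: variant reads / (variant + reference reads).

    For male samples, gonosomal (X/Y) variants are hemizygous, so the raw
    VAF (near 1 for a clonal variant) is halved to a pseudo-diploid VAF
    comparable with autosomes.
    """
    depth = variants["variant_reads"] + variants["reference_reads"]
    if (depth <= 0).any():
        bad = variants.index[depth <= 0].tolist()
        raise ValueError(f"undefined VAF: zero depth at rows {bad}")
    out = variants.copy()
    vaf = variants["variant_reads"] / depth
    if sex == "male":
        gono = out["chrom"].astype(str).isin(_GONOSOMES)
        vaf = vaf.where(~gono, vaf / 2.0)
    out["vaf"] = vaf
    return out


@dataclass(frozen=True)
class BaselineModel:
    """Per-context upper bounds of the background-VAF confidence interval."""

    upper: pd.Series  # index: the 96 context classes
    ci_level: float
    n_sites: int
    panel_samples: int
    mode: str

    def __post_init__(self):
        missing = sorted(_CLASS_SET - set(self.upper.index))
        if missing:
            raise ValueError(f"baseline missing context classes: {missing[:5]}...")
        if ((self.upper < 0) | (self.upper > 1)).any():
            raise ValueError("baseline bounds must lie in [0, 1]")


def build_baseline(
    panel: pd.DataFrame,
    n_sites: int = 100,
    ci_level: float = 0.95,
    mode: str = "per_site",
    seed: int | None = None,
) -> BaselineModel:
    """Background-VAF baseline from a panel of unrelated samples.

    ``panel`` is long-form with columns ``context_class, site_id, sample_id,
    vaf``: the pileup VAF at ``n_sites`` random sites per substitution class
    across the panel samples.  Per class, the upper limit of the
    ``ci_level`` percentile interval of the background VAF distribution is
    stored.  ``mode="per_site"`` pools every (site, sample) observation;
    ``mode="per_sample"`` first averages per sample.  If ``n_sites`` exceeds
    the sites present, that class errors; with a ``seed`` a deterministic
    subsample of exactly ``n_sites`` sites per class is used.
    """
    if mode not in ("per_site", "per_sample"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    required = {"context_class", "site_id", "sample_id", "vaf"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    present = set(panel["context_class"].unique())
    missing = sorted(_CLASS_SET - present)
    if missing:
        raise ValueError(f"panel lacks {len(missing)} context classes: {missing}")
    rng = np.random.default_rng(seed)
    q_hi = 1.0 - (1.0 - ci_level) / 2.0
    uppers = {}
    for cls, grp in panel.groupby("context_class", sort=True):
        sites = np.sort(grp["site_id"].unique())
        if len(sites) < n_sites:
            raise ValueError(
                f"class {cls}: {len(sites)} sites < required {n_sites}"
            )
        chosen = rng.choice(sites, size=n_sites, replace=False) if len(sites) > n_sites else sites
        sub = grp[grp["site_id"].isin(chosen)]
        values = (
            sub.groupby("sample_id")["vaf"].mean()
            if mode == "per_sample"
            else sub["vaf"]
        )
        uppers[cls] = float(np.quantile(values, q_hi))
    return BaselineModel(
        upper=pd.Series(uppers).reindex(list(CONTEXT_CLASSES)),
        ci_level=ci_level,
        n_sites=n_sites,
        panel_samples=panel["sample_id"].nunique(),
        mode=mode,
    )


def _split(variants: pd.DataFrame, removed_mask, reasons) -> tuple[pd.DataFrame, pd.DataFrame]:
    removed = variants[removed_mask].copy()
    removed["reason"] = reasons
    return variants[~removed_mask].copy(), removed


def recurrence_filter(
    variants: pd.DataFrame,
    cohort: pd.DataFrame,
    baseline: BaselineModel,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove variants recurring above the context baseline in other samples.

    ``cohort`` is a wide matrix (index aligned with ``variants``' index,
    columns = the *other* samples' ids) of pileup VAFs for each candidate
    variant.  A variant is removed iff its VAF in ANY other sample strictly
    exceeds its class's upper bound (ties are kept); the removal reason
    names the offending sample and VAF.
    """
    missing = set(variants["context_class"]) - set(baseline.upper.index)
    if missing:
        raise ValueError(f"variant classes missing from baseline: {sorted(missing)}")
    bounds = baseline.upper.loc[variants["context_class"]].to_numpy()
    mat = cohort.loc[variants.index].to_numpy(dtype=float)
    exceed = mat > bounds[:, None]
    removed_mask = pd.Series(exceed.any(axis=1), index=variants.index)
    reasons = []
    cols = np.asarray(cohort.columns)
    for i in np.flatnonzero(exceed.any(axis=1)):
        j = int(np.argmax(exceed[i]))
        reasons.append(
            f"recurrent_artifact:sample={cols[j]},vaf={mat[i, j]:.4g},"
            f"bound={bounds[i]:.4g}"
        )
    return _split(variants, removed_mask, reasons)


def _in_regions(chrom: pd.Series, pos: pd.Series, regions: pd.DataFrame) -> np.ndarray:
    """1-based positions against 0-based half-open intervals (merged per chrom)."""
    hit = np.zeros(len(chrom), dtype=bool)
    for c, grp in regions.groupby("chrom"):
        sel = (chrom == c).to_numpy()
        if not sel.any():
            continue
        iv = grp.sort_values("start")[["start", "end"]].to_numpy()
        # merge overlapping intervals
        merged = [list(iv[0])]
        for s, e in iv[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        merged = np.asarray(merged)
        p0 = pos.to_numpy()[sel] - 1  # 0-based coordinate of the base
        idx = np.searchsorted(merged[:, 0], p0, side="right") - 1
        ok = (idx >= 0) & (p0 < merged[np.clip(idx, 0, None), 1])
        hit[sel] = ok
    return hit


def hard_filters(
    variants: pd.DataFrame,
    regions: dict[str, pd.DataFrame] | None = None,
    snp_sites: pd.DataFrame | None = None,
    min_variant_reads: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential hard filters with per-rule reason codes.

    Rules, in order: variant reads < ``min_variant_reads``; site listed in
    the SNP database (matched on chrom/pos/ref/alt when alleles are present,
    else chrom/pos); overlap with each labelled region set (repeat,
    simple_repeat, cna, loh, ...).
    """
    current = variants
    removed_parts = []

    low = current["variant_reads"] < min_variant_reads
    current, rem = _split(current, low, f"min_reads<{min_variant_reads}")
    removed_parts.append(rem)

    if snp_sites is not None and len(snp_sites) and len(current):
        if {"ref", "alt"}.issubset(snp_sites.columns) and {"ref", "alt"}.issubset(
            current.columns
        ):
            keys = set(map(tuple, snp_sites[["chrom", "pos", "ref", "alt"]].to_numpy()))
            mask = current.apply(
                lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]) in keys, axis=1
            )
        else:
            keys = set(map(tuple, snp_sites[["chrom", "pos"]].to_numpy()))
            mask = current.apply(lambda r: (r["chrom"], r["pos"]) in keys, axis=1)
        current, rem = _split(current, mask.astype(bool), "snp_database")
        removed_parts.append(rem)

    for label, regs in (regions or {}).items():
        if not len(current):
            break
        mask = pd.Series(
            _in_regions(current["chrom"], current["pos"], regs), index=current.index
        )
        current, rem = _split(current, mask, f"region:{label}")
        removed_parts.append(rem)

    removed = (
        pd.concat(removed_parts)
        if removed_parts
        else variants.iloc[0:0].assign(reason=pd.Series(dtype=str))
    )
    return current, removed


def indel_cross_sample_filter(
    indels: dict[str, pd.DataFrame],
    second_caller: dict[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Per-sample indel filtering against the cohort and a second caller.

    An indel (keyed chrom, pos, ref, alt) present in any *other* sample's
    raw call set is removed from every sample carrying it; survivors are
    kept only when the same key appears in that sample's second-caller set.
    """
    key_cols = ["chrom", "pos", "ref", "alt"]

    def keys(df: pd.DataFrame) -> set[tuple]:
        return set(map(tuple, df[key_cols].to_numpy())) if len(df) else set()

    raw_keys = {s: keys(df) for s, df in indels.items()}
    confirm_keys = {s: keys(df) for s, df in second_caller.items()}
    out = {}
    for sample, df in indels.items():
        others = set().union(
            *(raw_keys[s] for s in raw_keys if s != sample), set()
        )
        conf = confirm_keys.get(sample, set())
        if len(df):
            k = list(map(tuple, df[key_cols].to_numpy()))
            keep = [kk not in others and kk in conf for kk in k]
            out[sample] = df[np.asarray(keep, dtype=bool)].copy()
        else:
            out[sample] = df.copy()
    return out


def select_germline_hets(
    variants: pd.DataFrame,
    min_coverage: int = 10,
    min_mapping_quality: float = 60.0,
    min_base_quality: float = 37.0,
    vaf_window: tuple[float, float] = (0.4, 0.6),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heterozygous-site selection from a germline control sample.

    Keeps sites with coverage >= 10, variant and reference mapping quality
    at the maximum (60), median base quality at 37, and VAF strictly
    between 0.4 and 0.6.  Rows missing an annotation are rejected with a
    per-record reason.
    """
    required = ["coverage", "mq_variant", "mq_reference", "bq_variant", "bq_reference", "vaf"]
    reasons = pd.Series("", index=variants.index, dtype=object)
    for col in required:
        if col not in variants.columns:
            raise ValueError(f"missing annotation column {col!r}")
        miss = variants[col].isna()
        reasons[miss & (reasons == "")] = f"missing:{col}"
    lo, hi = vaf_window
    checks = [
        (variants["coverage"] < min_coverage, f"coverage<{min_coverage}"),
        (variants["mq_variant"] < min_mapping_quality, "mq_variant"),
        (variants["mq_reference"] < min_mapping_quality, "mq_reference"),
        (variants["bq_variant"] < min_base_quality, "bq_variant"),
        (variants["bq_reference"] < min_base_quality, "bq_reference"),
        (~(variants["vaf"] > lo) | ~(variants["vaf"] < hi), f"vaf_outside({lo},{hi})"),
    ]
    for mask, code in checks:
        mask = mask.fillna(True)
        reasons[mask & (reasons == "")] = code
    removed_mask = reasons != ""
    kept = variants[~removed_mask].copy()
    removed = variants[removed_mask].copy()
    removed["reason"] = reasons[removed_mask]
    return kept, removed


def evaluate_loh(
    het_sites: pd.DataFrame, tumor_pileup: pd.DataFrame
) -> pd.DataFrame:
    """Join tumor-sample pileup VAFs onto germline heterozygous sites.

    ``tumor_pileup`` needs columns chrom, pos, vaf.  Sites absent from the
    pileup are emitted with ``missing = True``; no statistical LOH calling
    is performed here (segmentation is downstream).
    """
    if het_sites.empty:
        return pd.DataFrame(columns=["chrom", "pos", "germline_vaf", "tumor_vaf", "missing"])
    merged = het_sites[["chrom", "pos", "vaf"]].rename(columns={"vaf": "germline_vaf"})
    merged = merged.merge(
        tumor_pileup[["chrom", "pos", "vaf"]].rename(columns={"vaf": "tumor_vaf"}),
        on=["chrom", "pos"],
        how="left",
    )
    merged["missing"] = merged["tumor_vaf"].isna()
    return merged


def sv_concordance(
    primary_calls: pd.DataFrame,
    confirm_calls: pd.DataFrame,
    radius: int = 1000,
    report_min_vaf: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-caller structural-variant concordance.

    A primary call is kept iff a confirming call of the *same type* exists
    with BOTH breakpoints on matching chromosomes within ``radius`` bp.
    ``(kept, reported)``: ``reported`` further restricts to VAF >
    ``report_min_vaf``.  Columns: sv_type, chrom1, pos1, chrom2, pos2, vaf.
    """
    for df, name in ((primary_calls, "primary"), (confirm_calls, "confirm")):
        bad = set(df["sv_type"].astype(str).str.upper()) - SV_TYPES
        if bad:
            raise ValueError(f"unknown SV type(s) in {name} calls: {sorted(bad)}")
    keep = np.zeros(len(primary_calls), dtype=bool)
    conf = confirm_calls.copy()
    conf["sv_type"] = conf["sv_type"].astype(str).str.upper()
    for i, (_, row) in enumerate(primary_calls.iterrows()):
        cand = conf[
            (conf["sv_type"] == str(row["sv_type"]).upper())
            & (conf["chrom1"] == row["chrom1"])
            & (conf["chrom2"] == row["chrom2"])
        ]
        if len(cand) == 0:
            continue
        ok = (np.abs(cand["pos1"] - row["pos1"]) <= radius) & (
            np.abs(cand["pos2"] - row["pos2"]) <= radius
        )
        keep[i] = bool(ok.any())
    kept = primary_calls[keep].copy()
    reported = kept[kept["vaf"] > report_min_vaf].copy()
    return kept, reported


class VariantFilterCascade:
    """The full SNV filter cascade as a transform.

    ``transform(variants, cohort)`` applies, in order: the hard filters
    (min reads, SNP list, region exclusions) and the cross-sample
    recurrence filter against the baseline.  Returns the kept frame;
    ``removed_`` holds the audit trail with reason codes, and
    ``removal_counts_`` the per-rule tally.
    """

    def __init__(
        self,
        baseline: BaselineModel | None = None,
        regions: dict[str, pd.DataFrame] | None = None,
        snp_sites: pd.DataFrame | None = None,
        min_variant_reads: int = 3,
        sex: str | None = None,
    ):
        self.baseline = baseline
        self.regions = regions
        self.snp_sites = snp_sites
        self.min_variant_reads = min_variant_reads
        self.sex = sex

    def get_params(self, deep: bool = True) -> dict:
        return {
            "baseline": self.baseline,
            "regions": self.regions,
            "snp_sites": self.snp_sites,
            "min_variant_reads": self.min_variant_reads,
            "sex": self.sex,
        }

    def set_params(self, **params) -> "VariantFilterCascade":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def transform(
        self, variants: pd.DataFrame, cohort: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        df = variants if "vaf" in variants.columns else compute_vaf(variants, self.sex)
        kept, removed_hard = hard_filters(
            df, self.regions, self.snp_sites, self.min_variant_reads
        )
        removed_parts = [removed_hard]
        if self.baseline is not None and cohort is not None and len(kept):
            kept, removed_rec = recurrence_filter(kept, cohort, self.baseline)
            removed_parts.append(removed_rec)
        self.removed_ = pd.concat(removed_parts) if removed_parts else df.iloc[0:0]
        self.removal_counts_ = (
            self.removed_["reason"].str.split(":").str[0].value_counts().to_dict()
            if len(self.removed_)
            else {}
        )
        self.kept_ = kept
        return kept
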