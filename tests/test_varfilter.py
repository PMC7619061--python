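"""Somatic-variant filter cascade: VAF, baseline, recurrence, hard filters,
indel cross-sample, germline hets, LOH, SV concordance."""

import numpy as np
import pandas as pd
import pytest

from clonedrift import varfilter
from clonedrift.varfilter import (
    CONTEXT_CLASSES,
    VariantFilterCascade,
    build_baseline,
    collapse_context,
    compute_vaf,
    evaluate_loh,
    hard_filters,
    indel_cross_sample_filter,
    recurrence_filter,
    select_germline_hets,
    sv_concordance,
)


def _variants(rows):
    return pd.DataFrame(rows)


class TestComputeVaf:
    def test_autosomal_fraction(self):
        df = _variants([{"chrom": "1", "pos": 100, "variant_reads": 10, "reference_reads": 30}])
        assert compute_vaf(df)["vaf"].iloc[0] == 0.25

    def test_zero_variant_reads(self):
        df = _variants([{"chrom": "2", "pos": 5, "variant_reads": 0, "reference_reads": 30}])
        assert compute_vaf(df)["vaf"].iloc[0] == 0.0

    def test_male_gonosome_pseudo_diploid_halving(self):
        df = _variants([
            {"chrom": "chrX", "pos": 1, "variant_reads": 28, "reference_reads": 2},
            {"chrom": "1", "pos": 2, "variant_reads": 28, "reference_reads": 2},
        ])
        out = compute_vaf(df, sex="male")
        assert out["vaf"].iloc[0] == pytest.approx(28 / 30 / 2, abs=1e-9)
        assert out["vaf"].iloc[1] == pytest.approx(28 / 30, abs=1e-9)
        # female samples keep the raw fraction on X
        out_f = compute_vaf(df, sex="female")
        assert out_f["vaf"].iloc[0] == pytest.approx(28 / 30)

    def test_zero_depth_errors(self):
        df = _variants([{"chrom": "1", "pos": 1, "variant_reads": 0, "reference_reads": 0}])
        with pytest.raises(ValueError, match="zero depth"):
            compute_vaf(df)


def _make_panel(rng, special_class=None, special_mean=0.02):
    rows = []
    for cls in CONTEXT_CLASSES:
        for site in range(100):
            for sample in ("P0", "P1", "P2"):
                if cls == special_class:
                    vaf = rng.beta(4, 4) * special_mean * 2
                else:
                    vaf = 0.0
                rows.append((cls, site, sample, vaf))
    return pd.DataFrame(rows, columns=["context_class", "site_id", "sample_id", "vaf"])


class TestBaseline:
    def test_all_zero_panel_gives_zero_bounds(self):
        panel = _make_panel(np.random.default_rng(0))
        bl = build_baseline(panel)
        assert (bl.upper == 0.0).all()
        assert len(bl.upper) == 96

    def test_elevated_class_has_higher_bound(self):
        panel = _make_panel(np.random.default_rng(1), special_class="A[C>T]A")
        bl = build_baseline(panel)
        assert bl.upper["A[C>T]A"] > bl.upper.drop("A[C>T]A").max()

    def test_all_96_classes_always_emitted(self):
        bl = build_baseline(_make_panel(np.random.default_rng(2)))
        assert sorted(bl.upper.index) == sorted(CONTEXT_CLASSES)

    def test_missing_class_errors_with_names(self):
        panel = _make_panel(np.random.default_rng(3))
        panel = panel[panel["context_class"] != "A[C>A]A"]
        with pytest.raises(ValueError, match=r"A\[C>A\]A"):
            build_baseline(panel)

    def test_insufficient_sites_errors(self):
        panel = _make_panel(np.random.default_rng(4))
        with pytest.raises(ValueError, match="sites"):
            build_baseline(panel, n_sites=200)

    def test_per_sample_mode_and_determinism(self):
        panel = _make_panel(np.random.default_rng(5), special_class="C[T>G]G")
        a = build_baseline(panel, mode="per_sample", seed=1)
        b = build_baseline(panel, mode="per_sample", seed=1)
        assert a.upper.equals(b.upper)
        assert a.mode == "per_sample"


class TestContextCollapse:
    def test_pyrimidine_reference_unchanged(self):
        assert collapse_context("C", "T", "A", "G") == "A[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        # G>A at 5'-T G C-3' == C>T at 5'-G C A-3'
        assert collapse_context("G", "A", "T", "C") == "G[C>T]A"

    def test_invalid_substitution_rejected(self):
        with pytest.raises(ValueError):
            collapse_context("C", "C", "A", "A")


class TestRecurrenceFilter:
    def _setup(self):
        variants = _variants(
            [
                {"chrom": "1", "pos": 10, "context_class": "A[C>T]A",
                 "variant_reads": 9, "reference_reads": 81, "vaf": 0.1},
                {"chrom": "1", "pos": 20, "context_class": "A[C>T]A",
                 "variant_reads": 9, "reference_reads": 81, "vaf": 0.1},
            ]
        )
        upper = pd.Series(0.0, index=list(CONTEXT_CLASSES))
        upper["A[C>T]A"] = 0.01
        baseline = varfilter.BaselineModel(
            upper=upper, ci_level=0.95, n_sites=100, panel_samples=3, mode="per_site"
        )
        return variants, baseline

    def test_absent_in_others_kept(self):
        variants, baseline = self._setup()
        cohort = pd.DataFrame(0.0, index=variants.index, columns=["S1", "S2"])
        kept, removed = recurrence_filter(variants, cohort, baseline)
        assert len(kept) == 2 and len(removed) == 0

    def test_recurrent_artifact_removed_with_reason(self):
        variants, baseline = self._setup()
        cohort = pd.DataFrame(0.0, index=variants.index, columns=["S1", "S2", "S3"])
        cohort.loc[1, ["S1", "S2", "S3"]] = 0.05
        kept, removed = recurrence_filter(variants, cohort, baseline)
        assert kept.index.tolist() == [0]
        assert removed.index.tolist() == [1]
        assert "S1" in removed["reason"].iloc[0]

    def test_tie_with_bound_is_kept(self):
        variants, baseline = self._setup()
        cohort = pd.DataFrame(0.0, index=variants.index, columns=["S1"])
        cohort.loc[0, "S1"] = 0.01  # exactly the bound: "higher than" is strict
        kept, _ = recurrence_filter(variants, cohort, baseline)
        assert 0 in kept.index

    def test_missing_class_errors(self):
        variants, baseline = self._setup()
        variants.loc[0, "context_class"] = None
        cohort = pd.DataFrame(0.0, index=variants.index, columns=["S1"])
        with pytest.raises(ValueError):
            recurrence_filter(variants, cohort, baseline)

    def test_planted_artifacts_exactly_removed(self, filter_fixture):
        fx = filter_fixture
        bl = build_baseline(fx["panel"], seed=0)
        cats = pd.Series(fx["truth"]["category"])
        clean = fx["variants"][cats.isin(["true_somatic", "recurrent_artifact"])]
        kept, removed = recurrence_filter(
            compute_vaf(clean), fx["cohort"].loc[clean.index], bl
        )
        assert set(removed.index) == set(cats.index[cats == "recurrent_artifact"])
        assert len(kept) == fx["truth"]["n_true"]


class TestHardFilters:
    def _toy(self):
        # 20 variants: 4 in repeats, 3 low-read, 1 SNP-listed, disjoint
        rows = []
        for i in range(20):
            rows.append(
                {"chrom": "1", "pos": 1000 + i * 10, "ref": "C", "alt": "T",
                 "variant_reads": 10, "reference_reads": 80}
            )
        df = pd.DataFrame(rows)
        df.loc[0:2, "variant_reads"] = 2  # rows 0,1,2 low-read
        repeats = pd.DataFrame(
            {"chrom": ["1"], "start": [1039], "end": [1070]}  # covers pos 1040..1070
        )
        snps = df.loc[[8], ["chrom", "pos", "ref", "alt"]]  # pos 1080, disjoint
        return df, {"repeat": repeats}, snps

    def test_toy_table_count(self):
        df, regions, snps = self._toy()
        kept, removed = hard_filters(df, regions, snps)
        # 3 low-read + 1 SNP-listed + 4 in-repeat (disjoint) -> 12 kept
        assert len(kept) + len(removed) == 20
        assert (removed["reason"] == "min_reads<3").sum() == 3
        assert (removed["reason"] == "snp_database").sum() == 1
        assert (removed["reason"] == "region:repeat").sum() == 4
        assert len(kept) == 12

    def test_low_read_variant_removed(self):
        df = _variants([{"chrom": "1", "pos": 5, "ref": "C", "alt": "A",
                         "variant_reads": 2, "reference_reads": 88}])
        kept, removed = hard_filters(df)
        assert len(kept) == 0 and removed["reason"].iloc[0] == "min_reads<3"

    def test_halfopen_boundary_positions(self):
        # interval [100, 110): 1-based positions 101..110 overlap, 100 and 111 do not
        df = _variants(
            [{"chrom": "1", "pos": p, "ref": "C", "alt": "A",
              "variant_reads": 10, "reference_reads": 80} for p in (100, 101, 110, 111)]
        )
        regions = {"repeat": pd.DataFrame({"chrom": ["1"], "start": [100], "end": [110]})}
        kept, removed = hard_filters(df, regions)
        assert kept["pos"].tolist() == [100, 111]
        assert removed["pos"].tolist() == [101, 110]

    def test_idempotent(self):
        df, regions, snps = self._toy()
        kept1, _ = hard_filters(df, regions, snps)
        kept2, removed2 = hard_filters(kept1, regions, snps)
        assert kept1.equals(kept2) and len(removed2) == 0

    def test_partition_is_exact(self):
        df, regions, snps = self._toy()
        kept, removed = hard_filters(df, regions, snps)
        recombined = pd.concat([kept, removed.drop(columns="reason")]).sort_index()
        assert recombined.equals(df)


class TestIndelFilter:
    def _indel(self, chrom, pos, ref, alt):
        return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}

    def test_unique_confirmed_kept(self):
        calls = {"m1": pd.DataFrame([self._indel("1", 5, "CT", "C")]),
                 "m2": pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])}
        second = {"m1": pd.DataFrame([self._indel("1", 5, "CT", "C")])}
        out = indel_cross_sample_filter(calls, second)
        assert len(out["m1"]) == 1

    def test_shared_indel_removed_from_both(self):
        shared = self._indel("2", 9, "A", "AT")
        calls = {"m1": pd.DataFrame([shared]), "m2": pd.DataFrame([shared])}
        second = {"m1": pd.DataFrame([shared]), "m2": pd.DataFrame([shared])}
        out = indel_cross_sample_filter(calls, second)
        assert len(out["m1"]) == 0 and len(out["m2"]) == 0

    def test_unconfirmed_removed(self):
        calls = {"m1": pd.DataFrame([self._indel("1", 5, "CT", "C")]),
                 "m2": pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])}
        out = indel_cross_sample_filter(calls, {"m1": pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])})
        assert len(out["m1"]) == 0


class TestGermlineHets:
    def _site(self, **overrides):
        base = {"chrom": "1", "pos": 1, "coverage": 40, "mq_variant": 60,
                "mq_reference": 60, "bq_variant": 37, "bq_reference": 37, "vaf": 0.5}
        base.update(overrides)
        return base

    def test_good_site_kept(self):
        kept, removed = select_germline_hets(pd.DataFrame([self._site()]))
        assert len(kept) == 1 and len(removed) == 0

    def test_boundary_vaf_rejected_strictly(self):
        kept, removed = select_germline_hets(pd.DataFrame([self._site(vaf=0.40)]))
        assert len(kept) == 0
        assert "vaf_outside" in removed["reason"].iloc[0]

    def test_low_coverage_rejected(self):
        kept, removed = select_germline_hets(pd.DataFrame([self._site(coverage=9)]))
        assert len(kept) == 0 and removed["reason"].iloc[0] == "coverage<10"

    def test_missing_annotation_per_record_reason(self):
        kept, removed = select_germline_hets(
            pd.DataFrame([self._site(), self._site(bq_variant=np.nan)])
        )
        assert len(kept) == 1
        assert removed["reason"].iloc[0] == "missing:bq_variant"


class TestEvaluateLoh:
    def test_balanced_site_reported(self):
        hets = pd.DataFrame([{"chrom": "1", "pos": 5, "vaf": 0.5}])
        tumor = pd.DataFrame([{"chrom": "1", "pos": 5, "vaf": 0.5}])
        out = evaluate_loh(hets, tumor)
        assert out["tumor_vaf"].iloc[0] == 0.5 and not out["missing"].iloc[0]

    def test_loh_deviations_reported(self):
        hets = pd.DataFrame(
            [{"chrom": "1", "pos": p, "vaf": 0.5} for p in (1, 2, 3)]
        )
        tumor = pd.DataFrame(
            [{"chrom": "1", "pos": 1, "vaf": 0.9},
             {"chrom": "1", "pos": 2, "vaf": 0.1}]
        )
        out = evaluate_loh(hets, tumor)
        assert out.loc[0, "tumor_vaf"] == 0.9
        assert out.loc[1, "tumor_vaf"] == 0.1
        assert bool(out.loc[2, "missing"])

    def test_empty_het_list(self):
        out = evaluate_loh(pd.DataFrame(), pd.DataFrame())
        assert out.empty


class TestSvConcordance:
    def _call(self, svtype, p1, p2, vaf=0.3, c1="1", c2="1"):
        return {"sv_type": svtype, "chrom1": c1, "pos1": p1, "chrom2": c2,
                "pos2": p2, "vaf": vaf}

    def test_same_type_within_radius_kept(self):
        primary = pd.DataFrame([self._call("DEL", 10_000, 20_000)])
        confirm = pd.DataFrame([self._call("DEL", 10_400, 20_900)])
        kept, reported = sv_concordance(primary, confirm)
        assert len(kept) == 1 and len(reported) == 1

    def test_type_mismatch_dropped(self):
        primary = pd.DataFrame([self._call("DEL", 10_000, 20_000)])
        confirm = pd.DataFrame([self._call("INV", 10_000, 20_000)])
        kept, _ = sv_concordance(primary, confirm)
        assert len(kept) == 0

    def test_one_breakpoint_outside_radius_dropped(self):
        primary = pd.DataFrame([self._call("DEL", 10_000, 20_000)])
        confirm = pd.DataFrame([self._call("DEL", 10_400, 21_500)])
        kept, _ = sv_concordance(primary, confirm)
        assert len(kept) == 0

    def test_low_vaf_kept_but_not_reported(self):
        primary = pd.DataFrame([self._call("DUP", 1_000, 2_000, vaf=0.15)])
        confirm = pd.DataFrame([self._call("DUP", 1_000, 2_000)])
        kept, reported = sv_concordance(primary, confirm)
        assert len(kept) == 1 and len(reported) == 0

    def test_unknown_type_errors(self):
        primary = pd.DataFrame([self._call("WEIRD", 1, 2)])
        with pytest.raises(ValueError, match="WEIRD"):
            sv_concordance(primary, primary)


class TestCascade:
    def test_full_cascade_retains_exactly_planted_somatics(self, filter_fixture):
        fx = filter_fixture
        bl = build_baseline(fx["panel"], seed=0)
        cascade = VariantFilterCascade(
            baseline=bl, regions=fx["regions"], snp_sites=fx["snp_sites"]
        )
        kept = cascade.transform(fx["variants"], fx["cohort"])
        cats = pd.Series(fx["truth"]["category"])
        assert set(kept.index) == set(cats.index[cats == "true_somatic"])
        # audit: kept + removed partitions the input
        assert len(kept) + len(cascade.removed_) == len(fx["variants"])
        assert set(kept.index) | set(cascade.removed_.index) == set(fx["variants"].index)

    def test_cascade_is_idempotent(self, filter_fixture):
        fx = filter_fixture
        bl = build_baseline(fx["panel"], seed=0)
        cascade = VariantFilterCascade(
            baseline=bl, regions=fx["regions"], snp_sites=fx["snp_sites"]
        )
        kept1 = cascade.transform(fx["variants"], fx["cohort"])
        kept2 = cascade.transform(kept1, fx["cohort"].loc[kept1.index])
        assert kept1.equals(kept2)

    def test_get_set_params(self):
        c = VariantFilterCascade(min_variant_reads=5)
        assert c.get_params()["min_variant_reads"] == 5
        c.set_params(min_variant_reads=3)
        assert c.min_variant_reads == 3
        with pytest.raises(ValueError):
            c.set_params(bogus=1)
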