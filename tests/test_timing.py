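"""Timing selection, density ratios, and the selection odds ratio."""

import math

import numpy as np
import pandas as pd
import pytest

from wgdloh import (
    compare_density_ratios,
    density_ratio,
    profiles_from_frame,
    select_timing,
    selection_odds_ratio,
)
from wgdloh.loh import LOHProfile
from wgdloh.timing import apply_class_filter, phase_classes
from wgdloh.types import GeneAnnotation

from conftest import mutations_df


def mut(sample, chrom, pos, timing, vt="SNV", fclass="nonsynonymous"):
    ref, alt = ("A", "T") if vt == "SNV" else ("AT", "A")
    return (sample, chrom, pos, ref, alt, vt, fclass, timing, "")


def loh_profile(sid, chrom_intervals):
    p = LOHProfile(sample_id=sid)
    for c, pairs in chrom_intervals.items():
        p.intervals[c] = np.array(pairs)
    return p


class TestSelectTiming:
    def test_wgd_pre_uses_early_and_clonal(self):
        df = mutations_df(
            [mut("S1", "1", i, "early_clonal") for i in range(2)]
            + [mut("S1", "1", 10 + i, "subclonal") for i in range(3)]
        )
        assert len(select_timing(df, wgd_status=True, phase="pre")) == 2

    def test_nwgd_pre_is_clonal_only(self):
        df = mutations_df(
            [mut("S1", "1", i, "clonal") for i in range(4)]
            + [mut("S1", "1", 10, "early_clonal")]
        )
        assert len(select_timing(df, wgd_status=False, phase="pre")) == 4

    def test_all_unassigned_gives_empty(self):
        df = mutations_df([mut("S1", "1", i, "unassigned") for i in range(3)])
        for wgd in (True, False):
            for phase in ("pre", "post"):
                assert select_timing(df, wgd, phase).empty

    def test_phase_class_sets(self):
        assert phase_classes("pre", True) == {"early_clonal", "clonal"}
        assert phase_classes("post", True) == {"late_clonal", "subclonal"}
        assert phase_classes("pre", False) == {"clonal"}
        assert phase_classes("post", False) == {"subclonal"}
        with pytest.raises(ValueError):
            phase_classes("during", True)


class TestDensityRatio:
    def test_nine_fold_enrichment(self):
        prof = loh_profile("S1", {"1": [(0, 10**6)]})
        muts = mutations_df(
            [mut("S1", "1", 100 + i, "clonal") for i in range(10)]
            + [mut("S1", "1", 2 * 10**6 + i, "clonal") for i in range(10)]
        )
        dr = density_ratio(muts, prof, {"1": 10**7}, "SNV")
        assert (dr.n_in, dr.n_out) == (10, 10)
        assert dr.log10_ratio == pytest.approx(math.log10(9), abs=1e-12)
        assert not dr.corrected

    def test_equal_densities_zero(self):
        prof = loh_profile("S1", {"1": [(0, 500)]})
        muts = mutations_df(
            [mut("S1", "1", 10, "clonal"), mut("S1", "1", 700, "clonal")]
        )
        dr = density_ratio(muts, prof, {"1": 1000}, "SNV")
        assert dr.log10_ratio == pytest.approx(0.0)

    def test_pseudocount_when_zero_inside(self):
        prof = loh_profile("S1", {"1": [(0, 500)]})
        muts = mutations_df([mut("S1", "1", 600 + i, "clonal") for i in range(10)])
        dr = density_ratio(muts, prof, {"1": 1000}, "SNV")
        assert dr.corrected
        assert dr.log10_ratio == pytest.approx(math.log10(0.5 / 10.5), abs=1e-12)

    def test_no_loh_not_computable(self):
        dr = density_ratio(
            mutations_df([mut("S1", "1", 5, "clonal")]),
            LOHProfile("S1"), {"1": 1000}, "SNV",
        )
        assert not dr.computable and np.isnan(dr.log10_ratio)

    def test_unknown_chromosome_is_error(self):
        prof = loh_profile("S1", {"1": [(0, 100)]})
        with pytest.raises(ValueError, match="not in genome"):
            density_ratio(
                mutations_df([mut("S1", "2", 5, "clonal")]), prof, {"1": 1000},
                "SNV",
            )

    def test_partition_counts_sum_to_selected(self):
        rng = np.random.default_rng(7)
        prof = loh_profile("S1", {"1": [(100, 400)], "2": [(0, 50)]})
        rows = [
            mut("S1", rng.choice(["1", "2"]), int(rng.integers(0, 1000)), "clonal")
            for _ in range(60)
        ]
        muts = mutations_df(rows)
        dr = density_ratio(muts, prof, {"1": 1000, "2": 1000}, "SNV")
        assert dr.n_in + dr.n_out == len(muts)


class TestCompareDensityRatios:
    def build_table(self, wgd_vals, nwgd_vals):
        rows = []
        for i, v in enumerate(wgd_vals):
            rows.append(("W%d" % i, "Lung", True, "SNV", "pre", 1, 1, 10, 10, v,
                         False, True))
        for i, v in enumerate(nwgd_vals):
            rows.append(("N%d" % i, "Lung", False, "SNV", "pre", 1, 1, 10, 10, v,
                         False, True))
        return pd.DataFrame(
            rows,
            columns=["sample", "cancer_type", "wgd_status", "variant_type",
                     "phase", "n_in", "n_out", "bp_in", "bp_out", "log10_ratio",
                     "corrected", "computable"],
        )

    def test_identical_groups_not_significant(self):
        t = self.build_table([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert compare_density_ratios(t).loc[0, "p_value"] > 0.99

    def test_fully_separated_4v4_exact(self):
        t = self.build_table([1.1, 1.2, 1.3, 1.4], [0.1, 0.2, 0.3, 0.4])
        # 2 of the C(8,4)=70 assignments are as extreme: p = 2/70
        assert compare_density_ratios(t).loc[0, "p_value"] == \
            pytest.approx(2 / 70, rel=1e-12)

    def test_insufficient_group_not_computable(self):
        t = self.build_table([0.5], [0.1, 0.2])
        out = compare_density_ratios(t)
        assert not out.loc[0, "computable"]


class TestSelectionOddsRatio:
    GENES = [
        GeneAnnotation("TSG1", "1", 0, 100, is_tsg=True),
        GeneAnnotation("OTH1", "1", 200, 300),
        GeneAnnotation("TSG2", "2", 0, 100, is_tsg=True),
        GeneAnnotation("OTH2", "2", 200, 300),
    ]

    def build(self, a, b, c, d):
        """Place a/b/c/d mutations in listed/other genes in/out of LOH."""
        prof = loh_profile("S1", {"1": [(0, 1000)]})
        rows = []
        rows += [mut("S1", "1", 10 + i % 90, "clonal") for i in range(a)]
        rows += [mut("S1", "1", 210 + i % 90, "clonal") for i in range(b)]
        rows += [mut("S1", "2", 10 + i % 90, "clonal") for i in range(c)]
        rows += [mut("S1", "2", 210 + i % 90, "clonal") for i in range(d)]
        # intergenic noise must be ignored
        rows += [mut("S1", "1", 400, "clonal"), mut("S1", "2", 500, "clonal")]
        return mutations_df(rows), {"S1": prof}

    def test_printed_formula(self):
        muts, profs = self.build(10, 90, 5, 95)
        res = selection_odds_ratio(muts, profs, self.GENES, "tsg")
        assert res.counts == (10, 90, 5, 95)
        assert res.odds_ratio == pytest.approx((10 / 90) / (5 / 95), rel=1e-12)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_null_is_one(self):
        muts, profs = self.build(10, 90, 10, 90)
        res = selection_odds_ratio(muts, profs, self.GENES, "tsg")
        assert res.odds_ratio == pytest.approx(1.0, rel=1e-12)

    def test_haldane_correction(self):
        muts, profs = self.build(3, 7, 0, 10)
        res = selection_odds_ratio(muts, profs, self.GENES, "tsg")
        assert res.corrected
        assert res.odds_ratio == pytest.approx((3.5 / 7.5) / (0.5 / 10.5),
                                               rel=1e-12)
        assert res.odds_ratio == pytest.approx(9.8, rel=1e-12)

    def test_empty_gene_list_is_error(self):
        muts, profs = self.build(1, 1, 1, 1)
        genes = [GeneAnnotation("OTH1", "1", 200, 300)]
        with pytest.raises(ValueError, match="empty"):
            selection_odds_ratio(muts, profs, genes, "tsg")

    def test_matches_brute_force_loop_on_random_cohorts(self):
        rng = np.random.default_rng(3)
        genes = [
            GeneAnnotation(f"G{i}", str(c), s, s + 50, is_tsg=bool(i % 3 == 0))
            for i, (c, s) in enumerate(
                (rng.integers(1, 4), rng.integers(0, 950)) for _ in range(12)
            )
        ]
        for _ in range(30):
            profs, rows = {}, []
            for sid in ("A", "B", "C"):
                ivs = {}
                for c in ("1", "2", "3"):
                    if rng.random() < 0.7:
                        s = int(rng.integers(0, 500))
                        ivs[c] = [(s, s + int(rng.integers(50, 400)))]
                profs[sid] = loh_profile(sid, ivs)
                for _ in range(int(rng.integers(5, 40))):
                    rows.append(
                        mut(sid, str(rng.integers(1, 4)),
                            int(rng.integers(0, 1000)), "clonal")
                    )
            muts = mutations_df(rows)
            res = selection_odds_ratio(muts, profs, genes, "tsg")
            # independent per-mutation classification loop
            a = b = c_ = d = 0
            for r in muts.itertuples(index=False):
                hit = [g for g in genes
                       if g.chrom == r.chrom and g.start <= r.pos < g.end]
                if not hit:
                    continue
                listed = any(g.is_tsg for g in hit)
                arr = profs[r.sample].intervals.get(r.chrom)
                in_loh = arr is not None and any(
                    s <= r.pos < e for s, e in arr
                )
                if in_loh and listed:
                    a += 1
                elif in_loh:
                    b += 1
                elif listed:
                    c_ += 1
                else:
                    d += 1
            assert res.counts == (a, b, c_, d)
            if not res.corrected:
                assert res.odds_ratio == pytest.approx((a / b) / (c_ / d),
                                                       rel=1e-12)

    def test_class_filters_partition_genic_snvs(self):
        rows = [
            mut("S1", "1", 10, "clonal", "SNV", "synonymous"),
            mut("S1", "1", 20, "clonal", "SNV", "nonsynonymous"),
            mut("S1", "1", 30, "clonal", "SNV", "stopgain"),
            mut("S1", "1", 40, "clonal", "INDEL", "other"),
        ]
        df = mutations_df(rows)
        assert len(apply_class_filter(df, "disruptive")) == 3
        assert len(apply_class_filter(df, "synonymous")) == 1
        with pytest.raises(ValueError):
            apply_class_filter(df, "nonsense-filter")
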