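"""LOH calling and LOH-derived cohort statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from wgdloh import (
    call_pre_wgd_loh,
    compare_loh_fraction,
    genome_fraction,
    per_chromosome_comparison,
    profiles_from_frame,
    tsg_loh_correlation,
)
from wgdloh.loh import LOHProfile
from wgdloh.types import GeneAnnotation

from conftest import samples_df, seg


class TestCalling:
    def test_minor_zero_segment_is_loh(self):
        prof = call_pre_wgd_loh([seg("S1", "17", 0, 1000, 2, 0)])
        assert prof.total_loh_bp == 1000
        assert prof.chrom_flags["17"] and not prof.chrom_flags["1"]

    def test_heterozygous_segment_is_not_loh(self):
        assert call_pre_wgd_loh([seg("S1", "1", 0, 1000, 1, 1)]).total_loh_bp == 0

    def test_abutting_loh_segments_merge(self):
        prof = call_pre_wgd_loh(
            [seg("S1", "1", 0, 500, 2, 0), seg("S1", "1", 500, 1000, 1, 0)]
        )
        assert len(prof.intervals["1"]) == 1
        assert prof.total_loh_bp == 1000

    def test_no_segments_gives_empty_profile(self):
        prof = call_pre_wgd_loh([])
        assert prof.total_loh_bp == 0
        assert not any(prof.chrom_flags.values())

    def test_sex_chromosomes_excluded(self):
        prof = call_pre_wgd_loh(
            [seg("S1", "X", 0, 1000, 1, 0), seg("S1", "2", 0, 100, 1, 0)]
        )
        assert prof.total_loh_bp == 100

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            call_pre_wgd_loh(
                [seg("S1", "1", 0, 500, 1, 1), seg("S1", "1", 400, 900, 1, 0)]
            )

    def test_idempotent_on_called_intervals(self):
        prof = call_pre_wgd_loh(
            [seg("S1", "1", 0, 500, 2, 0), seg("S1", "1", 500, 800, 1, 0),
             seg("S1", "2", 10, 40, 1, 0)]
        )
        again = call_pre_wgd_loh(
            [seg("S1", c, int(s), int(e), 1, 0)
             for c, arr in prof.intervals.items() for s, e in arr]
        )
        assert {c: a.tolist() for c, a in again.intervals.items()} == \
            {c: a.tolist() for c, a in prof.intervals.items()}

    def test_conservation_per_chromosome_sums(self):
        prof = call_pre_wgd_loh(
            [seg("S1", "1", 0, 500, 2, 0), seg("S1", "2", 10, 40, 1, 0),
             seg("S1", "3", 5, 10, 2, 1)]
        )
        assert sum(prof.loh_bp(c) for c in ("1", "2", "3")) == prof.total_loh_bp

    def test_matches_per_base_brute_force_on_random_segments(self):
        rng = np.random.default_rng(42)
        chrom_len = 200
        for _ in range(50):
            segments, covered = [], {}
            for chrom in ("1", "2", "3"):
                cuts = np.sort(rng.choice(np.arange(1, chrom_len), size=4,
                                          replace=False))
                bounds = [0, *cuts.tolist(), chrom_len]
                base = np.zeros(chrom_len, dtype=bool)
                for s, e in zip(bounds[:-1], bounds[1:]):
                    minor = int(rng.integers(0, 2))
                    segments.append(seg("S1", chrom, s, e, 2, minor))
                    if minor == 0:
                        base[s:e] = True
                covered[chrom] = base
            prof = call_pre_wgd_loh(segments)
            assert prof.total_loh_bp == sum(int(b.sum()) for b in covered.values())

    def test_frame_caller_equivalent_to_record_caller(self, small_cohort):
        frame_profiles = profiles_from_frame(small_cohort.segments)
        sub = small_cohort.segments[
            small_cohort.segments["sample"].isin(list(frame_profiles)[:5])
        ]
        for sid, grp in sub.groupby("sample"):
            rec = call_pre_wgd_loh(
                [seg(r.sample, r.chrom, r.start, r.end, r.major_cn, r.minor_cn)
                 for r in grp.itertuples(index=False)]
            )
            assert rec.total_loh_bp == frame_profiles[sid].total_loh_bp


class TestGenomeFraction:
    def test_quarter_covered(self):
        prof = call_pre_wgd_loh([seg("S1", "1", 0, 25, 1, 0)])
        assert genome_fraction(prof, {"1": 100}) == 0.25

    def test_no_loh_is_zero_and_full_is_one(self):
        assert genome_fraction(call_pre_wgd_loh([]), {"1": 100}) == 0.0
        full = call_pre_wgd_loh([seg("S1", "1", 0, 100, 1, 0)])
        assert genome_fraction(full, {"1": 100}) == 1.0

    def test_interval_beyond_chromosome_end_is_error(self):
        prof = call_pre_wgd_loh([seg("S1", "1", 0, 150, 1, 0)])
        with pytest.raises(ValueError, match="beyond end"):
            genome_fraction(prof, {"1": 100})


def _profile(sid, frac, genome_len=100, chrom="1"):
    p = LOHProfile(sample_id=sid)
    if frac > 0:
        p.intervals[chrom] = np.array([[0, int(frac * genome_len)]])
    return p


class TestFractionComparison:
    def exact_ranksum(self, x, y):
        """Enumeration oracle: exact two-sided rank-sum p-value (no ties)."""
        pooled = sorted(list(x) + list(y))
        n = len(x)
        obs = sum(pooled.index(v) + 1 for v in x)
        ranks = [
            sum(i + 1 for i in idx) for idx in combinations(range(len(pooled)), n)
        ]
        mu = np.mean(ranks)
        extreme = sum(abs(r - mu) >= abs(obs - mu) - 1e-12 for r in ranks)
        return extreme / len(ranks)

    def build(self, wgd_fracs, nwgd_fracs):
        profiles, rows = {}, []
        for i, f in enumerate(wgd_fracs):
            sid = f"W{i}"
            profiles[sid] = _profile(sid, f)
            rows.append((sid, "Lung", True, 0.8, 3.8))
        for i, f in enumerate(nwgd_fracs):
            sid = f"N{i}"
            profiles[sid] = _profile(sid, f)
            rows.append((sid, "Lung", False, 0.8, 2.0))
        return profiles, samples_df(rows)

    def test_identical_distributions_not_significant(self):
        profiles, sdf = self.build([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        out = compare_loh_fraction(profiles, sdf, {"1": 100})
        assert out.loc[0, "p_value"] > 0.99

    def test_fully_separated_3v3_matches_exact_enumeration(self):
        w, n = [0.4, 0.5, 0.6], [0.1, 0.2, 0.3]
        profiles, sdf = self.build(w, n)
        out = compare_loh_fraction(profiles, sdf, {"1": 100})
        # all 20 rank assignments: one-sided 1/20 = 0.05, two-sided 0.1
        assert out.loc[0, "p_value"] == pytest.approx(self.exact_ranksum(w, n))
        assert out.loc[0, "p_value"] == pytest.approx(0.1)

    def test_empty_stratum_marked_not_computable(self):
        profiles, sdf = self.build([0.4, 0.5], [])
        out = compare_loh_fraction(profiles, sdf, {"1": 100})
        assert not out.loc[0, "computable"]
        assert np.isnan(out.loc[0, "p_value"])

    def test_by_cancer_type_applies_bh(self):
        profiles, sdf = self.build([0.4, 0.5, 0.6], [0.1, 0.2, 0.3])
        sdf.loc[sdf["sample"].isin(["W0", "N0"]), "cancer_type"] = "CNS"
        out = compare_loh_fraction(profiles, sdf, {"1": 100}, by_cancer_type=True)
        assert set(out["cancer_type"]) == {"Lung", "CNS"}
        assert (out["q_value"].dropna() >= out["p_value"].dropna()).all()


class TestPerChromosome:
    def build(self, w_has, w_n, n_has, n_n):
        profiles, rows = {}, []
        for i in range(w_n):
            sid = f"W{i}"
            profiles[sid] = _profile(sid, 0.5 if i < w_has else 0.0)
            rows.append((sid, "Lung", True, 0.8, 3.8))
        for i in range(n_n):
            sid = f"N{i}"
            profiles[sid] = _profile(sid, 0.5 if i < n_has else 0.0)
            rows.append((sid, "Lung", False, 0.8, 2.0))
        return profiles, samples_df(rows)

    def test_ratio_and_fisher_p(self):
        profiles, sdf = self.build(10, 10, 5, 10)
        out = per_chromosome_comparison(profiles, sdf).set_index("chrom")
        row = out.loc["1"]
        assert row["ratio"] == pytest.approx(2.0)
        # hypergeometric enumeration of [[10,0],[5,5]]
        assert row["p_value"] == pytest.approx(0.03250773993808, rel=1e-10)
        assert row["sig_05"] and row["sig_10"]

    def test_equal_proportions_ratio_one(self):
        profiles, sdf = self.build(5, 10, 5, 10)
        out = per_chromosome_comparison(profiles, sdf).set_index("chrom")
        assert out.loc["1", "ratio"] == pytest.approx(1.0)

    def test_no_loh_anywhere_is_nan_and_nwgd_zero_is_inf(self):
        profiles, sdf = self.build(3, 5, 0, 5)
        out = per_chromosome_comparison(profiles, sdf).set_index("chrom")
        assert np.isinf(out.loc["1", "ratio"])
        assert np.isnan(out.loc["2", "ratio"])


class TestCorrelation:
    def test_derived_four_chromosome_pearson(self):
        props = {"1": 0.1, "2": 0.2, "3": 0.3, "4": 0.4}
        counts = {"1": 1, "2": 2, "3": 3, "4": 5}
        profiles, rows = {}, []
        sid_i = 0
        for _ in range(10):
            profiles[f"S{sid_i}"] = LOHProfile(sample_id=f"S{sid_i}")
            rows.append((f"S{sid_i}", "Lung", True, 0.8, 3.8))
            sid_i += 1
        for chrom, p in props.items():
            for k in range(int(p * 10)):
                profiles[f"S{k}"].intervals.setdefault(
                    chrom, np.array([[0, 10]])
                )
        genes = []
        for chrom, n in counts.items():
            genes += [
                GeneAnnotation(f"T{chrom}_{i}", chrom, i * 10, i * 10 + 5,
                               is_tsg=True)
                for i in range(n)
            ]
        res = tsg_loh_correlation(
            profiles, samples_df(rows), genes, chroms=("1", "2", "3", "4")
        )
        # direct Pearson formula on (0.1,0.2,0.3,0.4) vs (1,2,3,5)
        assert res["r"] == pytest.approx(0.98270762982399, rel=1e-9)

    def test_proportional_gives_r_one_and_constant_not_computable(self):
        a, b = LOHProfile("A"), LOHProfile("B")
        a.intervals["1"] = np.array([[0, 10]])
        b.intervals["1"] = np.array([[0, 10]])
        a.intervals["2"] = np.array([[0, 10]])
        profiles = {"A": a, "B": b}
        sdf = samples_df([("A", "L", True, 0.8, 3.0), ("B", "L", True, 0.8, 3.0)])
        # per-chrom LOH proportions (1.0, 0.5, 0.0) vs TSG counts (2, 1, 0)
        genes = [
            GeneAnnotation("T1a", "1", 0, 5, is_tsg=True),
            GeneAnnotation("T1b", "1", 10, 15, is_tsg=True),
            GeneAnnotation("T2", "2", 0, 5, is_tsg=True),
        ]
        res = tsg_loh_correlation(profiles, sdf, genes, chroms=("1", "2", "3"))
        assert res["r"] == pytest.approx(1.0)
        res2 = tsg_loh_correlation({"A": LOHProfile("A"), "B": LOHProfile("B")},
                                   sdf, genes, chroms=("1", "2", "3"))
        assert np.isnan(res2["r"])
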