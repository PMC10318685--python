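"""Pre-WGD LOH calling and LOH-derived cohort statistics.

A region is called LOH when its minor allele copy number is 0. Because a
zero-copy allele is vanishingly unlikely to arise independently on both
homologue copies after a genome doubling, such regions are interpreted as
predating the WGD event; the single minor_cn = 0 rule uniformly covers
deletion-LOH, copy-neutral LOH, and LOH with gain. Only the 22 autosomes
enter any LOH statistic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import intervals as iv
from .stats import bh_adjust, fisher_p, pearson_with_p, ranksum_p
from .types import AUTOSOMES, CopyNumberSegment, GeneAnnotation, to_frame


@dataclass
class LOHProfile:
    """Per-sample LOH intervals with summary statistics."""

    sample_id: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_loh_bp(self) -> int:
        return int(sum(iv.total_bp(a) for a in self.intervals.values()))

    @property
    def chrom_flags(self) -> dict[str, bool]:
        return {c: len(self.intervals.get(c, ())) > 0 for c in AUTOSOMES}

    def loh_bp(self, chrom: str) -> int:
        return iv.total_bp(self.intervals.get(chrom, iv.EMPTY))

    def has_loh(self, chrom: str) -> bool:
        return len(self.intervals.get(chrom, ())) > 0


def call_pre_wgd_loh(segments: Iterable[CopyNumberSegment]) -> LOHProfile:
    """Call the pre-WGD LOH profile of one sample.

    LOH intervals are the autosomal segments with ``minor_cn == 0``;
    abutting or overlapping calls are merged. An empty segment list yields
    an all-zero profile.
    """
    segments = list(segments)
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else ""

    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    cover: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for s in segments:
        if not s.is_autosomal:
            continue
        cover[s.chrom].append((s.start, s.end))
        if s.minor_cn == 0:
            by_chrom[s.chrom].append((s.start, s.end))
    for chrom, spans in cover.items():
        merged = iv.merge(spans)
        if iv.total_bp(merged) != sum(e - s for s, e in spans):
            raise ValueError(f"overlapping segments on chromosome {chrom}")
    return LOHProfile(
        sample_id=sample_id,
        intervals={c: iv.merge(spans) for c, spans in by_chrom.items() if spans},
    )


def call_loh_profiles(
    segments: Iterable[CopyNumberSegment],
) -> dict[str, LOHProfile]:
    """Group segments by sample and call one profile per sample."""
    by_sample: dict[str, list[CopyNumberSegment]] = defaultdict(list)
    for s in segments:
        by_sample[s.sample_id].append(s)
    return {sid: call_pre_wgd_loh(segs) for sid, segs in by_sample.items()}


def profiles_from_frame(segments: pd.DataFrame) -> dict[str, LOHProfile]:
    """Vectorized profile calling from an internal-convention segment frame.

    Same LOH rule as :func:`call_pre_wgd_loh` (their equivalence is
    asserted in the test suite); preferred for large cohorts.
    """
    df = segments[segments["chrom"].isin(AUTOSOMES)]
    out = {sid: LOHProfile(sample_id=sid) for sid in segments["sample"].unique()}
    loh = df[df["minor_cn"] == 0]
    for (sid, chrom), sub in loh.groupby(["sample", "chrom"], sort=False):
        out[sid].intervals[str(chrom)] = iv.merge(
            np.column_stack([sub["start"].to_numpy(), sub["end"].to_numpy()])
        )
    return out


def genome_fraction(profile: LOHProfile, genome_lengths: Mapping[str, int]) -> float:
    """Fraction of the autosomal genome covered by LOH."""
    total = sum(int(genome_lengths[c]) for c in genome_lengths if c in AUTOSOMES)
    if total <= 0:
        raise ValueError("genome_lengths covers no autosomes")
    for chrom, arr in profile.intervals.items():
        if chrom not in genome_lengths:
            raise ValueError(f"LOH interval on chromosome {chrom} absent from genome")
        if len(arr) and arr[-1, 1] > genome_lengths[chrom]:
            raise ValueError(
                f"LOH interval beyond end of chromosome {chrom} "
                f"({arr[-1, 1]} > {genome_lengths[chrom]})"
            )
    return profile.total_loh_bp / total


def profile_table(
    profiles: Mapping[str, LOHProfile], genome_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """One row per sample: total LOH bp, genome fraction, per-chromosome flags."""
    rows = []
    for sid, prof in profiles.items():
        row = {
            "sample": sid,
            "total_loh_bp": prof.total_loh_bp,
            "genome_fraction": genome_fraction(prof, genome_lengths),
        }
        for c in AUTOSOMES:
            row[f"loh_chr{c}"] = prof.has_loh(c)
        rows.append(row)
    return pd.DataFrame(rows)


def _samples_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        df = to_frame(samples).rename(columns={"sample_id": "sample"})
    if "sample" not in df.columns and "sample_id" in df.columns:
        df = df.rename(columns={"sample_id": "sample"})
    return df


def compare_loh_fraction(
    profiles: Mapping[str, LOHProfile],
    samples,
    genome_lengths: Mapping[str, int],
    by_cancer_type: bool = False,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of LOH genome fractions, WGD vs nWGD.

    Pooled by default; with ``by_cancer_type`` one test per cancer type
    with BH adjustment across types. Strata with an empty side are kept in
    the table with ``computable = False``.
    """
    sdf = _samples_frame(samples)
    sdf = sdf[sdf["sample"].isin(profiles)]
    frac = {
        sid: genome_fraction(profiles[sid], genome_lengths) for sid in sdf["sample"]
    }
    sdf = sdf.assign(fraction=sdf["sample"].map(frac))

    groups = sdf.groupby("cancer_type") if by_cancer_type else [("ALL", sdf)]
    rows = []
    for name, grp in groups:
        w = grp.loc[grp["wgd_status"].astype(bool), "fraction"].to_numpy()
        n = grp.loc[~grp["wgd_status"].astype(bool), "fraction"].to_numpy()
        computable = len(w) >= 1 and len(n) >= 1
        rows.append(
            {
                "cancer_type": name,
                "n_wgd": len(w),
                "n_nwgd": len(n),
                "median_wgd": float(np.median(w)) if len(w) else np.nan,
                "median_nwgd": float(np.median(n)) if len(n) else np.nan,
                "p_value": ranksum_p(w, n) if computable else np.nan,
                "computable": computable,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"]) if by_cancer_type else out["p_value"]
    return out


def per_chromosome_comparison(
    profiles: Mapping[str, LOHProfile], samples
) -> pd.DataFrame:
    """Per-autosome proportion of samples with any LOH, WGD vs nWGD.

    Reports the WGD/nWGD proportion ratio (inf when only the nWGD side is
    zero, NaN when both are) and a two-sided Fisher's exact p on the 2x2
    has-LOH x WGD-status table, with significance flags at 0.05 and 0.1.
    """
    sdf = _samples_frame(samples)
    sdf = sdf[sdf["sample"].isin(profiles)]
    wgd_ids = sdf.loc[sdf["wgd_status"].astype(bool), "sample"]
    nwgd_ids = sdf.loc[~sdf["wgd_status"].astype(bool), "sample"]
    rows = []
    for chrom in AUTOSOMES:
        w_has = sum(profiles[s].has_loh(chrom) for s in wgd_ids)
        n_has = sum(profiles[s].has_loh(chrom) for s in nwgd_ids)
        n_w, n_n = len(wgd_ids), len(nwgd_ids)
        prop_w = w_has / n_w if n_w else np.nan
        prop_n = n_has / n_n if n_n else np.nan
        if prop_n and prop_n > 0:
            ratio = prop_w / prop_n
        elif prop_w and prop_w > 0:
            ratio = np.inf
        else:
            ratio = np.nan
        p = (
            fisher_p([[w_has, n_w - w_has], [n_has, n_n - n_has]])
            if n_w and n_n
            else np.nan
        )
        rows.append(
            {
                "chrom": chrom,
                "n_wgd": n_w,
                "n_nwgd": n_n,
                "prop_wgd": prop_w,
                "prop_nwgd": prop_n,
                "ratio": ratio,
                "p_value": p,
                "sig_05": bool(p < 0.05) if np.isfinite(p) else False,
                "sig_10": bool(p < 0.1) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def tsg_loh_correlation(
    profiles: Mapping[str, LOHProfile],
    samples,
    genes: Iterable[GeneAnnotation],
    gene_flag: str = "is_tsg",
    wgd_status: bool = True,
    chroms: tuple[str, ...] = AUTOSOMES,
) -> dict:
    """Pearson correlation between per-chromosome LOH sample proportions
    and gene-list counts, within one WGD stratum.

    Returns r, the two-sided t-distribution p, and the paired values (one
    pair per chromosome, all 22 autosomes by default). NaN r/p when either
    vector is constant.
    """
    sdf = _samples_frame(samples)
    mask = (sdf["wgd_status"].astype(bool) == wgd_status) & sdf["sample"].isin(
        profiles
    )
    ids = sdf.loc[mask, "sample"].tolist()
    counts = {c: 0 for c in chroms}
    for g in genes:
        if getattr(g, gene_flag) and g.chrom in counts:
            counts[g.chrom] += 1
    props = {
        c: (np.mean([profiles[s].has_loh(c) for s in ids]) if ids else np.nan)
        for c in chroms
    }
    x = np.array([props[c] for c in chroms], dtype=float)
    y = np.array([counts[c] for c in chroms], dtype=float)
    r, p = pearson_with_p(x, y)
    return {
        "gene_flag": gene_flag,
        "wgd_status": wgd_status,
        "r": r,
        "p_value": p,
        "proportions": x,
        "gene_counts": y,
    }
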