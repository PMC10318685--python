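"""Mutation-timing groups, in/out-LOH density ratios, and the pooled
selective-pressure odds ratio on gene lists.

Timing semantics
----------------
Mutations are labelled upstream (by a mutation-timing tool) as
early_clonal / clonal / late_clonal / subclonal. Relative to the genome
doubling, the "pre" phase uses early clonal plus clonal mutations in WGD
samples and clonal mutations in nWGD samples; the "post" phase uses late
clonal plus subclonal mutations in WGD samples and subclonal mutations in
nWGD samples. Unassigned labels never enter an analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import intervals as iv
from .loh import LOHProfile, _samples_frame
from .stats import bh_adjust, ranksum_p
from .types import AUTOSOMES, GeneAnnotation, to_frame

PHASE_CLASSES: dict[tuple[str, bool], frozenset[str]] = {
    ("pre", True): frozenset({"early_clonal", "clonal"}),
    ("pre", False): frozenset({"clonal"}),
    ("post", True): frozenset({"late_clonal", "subclonal"}),
    ("post", False): frozenset({"subclonal"}),
}

GENE_LISTS = {"essential": "is_essential", "cgc": "is_cgc", "tsg": "is_tsg"}

# Functional strata for the class-restricted odds ratios: indels and
# amino-acid-changing SNVs versus synonymous SNVs.
CLASS_FILTERS = {"disruptive", "synonymous"}


def mutations_frame(mutations) -> pd.DataFrame:
    if isinstance(mutations, pd.DataFrame):
        df = mutations.copy()
    else:
        df = to_frame(mutations)
    if "sample" not in df.columns and "sample_id" in df.columns:
        df = df.rename(columns={"sample_id": "sample"})
    return df


def phase_classes(phase: str, wgd_status: bool) -> frozenset[str]:
    if phase not in ("pre", "post"):
        raise ValueError(f"phase must be 'pre' or 'post', got {phase!r}")
    return PHASE_CLASSES[(phase, bool(wgd_status))]


def select_timing(mutations, wgd_status: bool, phase: str) -> pd.DataFrame:
    """Subset one sample's mutations to the phase-appropriate timing classes."""
    df = mutations_frame(mutations)
    if df.empty:
        return df
    return df[df["timing_class"].isin(phase_classes(phase, wgd_status))]


def select_timing_cohort(mutations, samples, phase: str) -> pd.DataFrame:
    """Phase-select a whole cohort, honouring each sample's WGD status."""
    df = mutations_frame(mutations)
    sdf = _samples_frame(samples)
    wgd = dict(zip(sdf["sample"], sdf["wgd_status"].astype(bool)))
    if df.empty:
        return df
    keep = [
        m.timing_class in phase_classes(phase, wgd.get(m.sample, False))
        for m in df.itertuples(index=False)
    ]
    return df[np.asarray(keep, dtype=bool)]


@dataclass
class DensityRatio:
    """Per-sample in/out-LOH mutation density contrast (log10 scale)."""

    sample_id: str
    variant_type: str
    phase: str
    n_in: int
    n_out: int
    bp_in: int
    bp_out: int
    log10_ratio: float
    corrected: bool
    computable: bool


def _in_loh_mask(df: pd.DataFrame, profile: LOHProfile) -> np.ndarray:
    mask = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = profile.intervals.get(str(chrom), iv.EMPTY)
        if len(arr):
            mask[df.index.get_indexer(sub.index)] = iv.contains(
                arr, sub["pos"].to_numpy()
            )
    return mask


def density_ratio(
    mutations,
    profile: LOHProfile,
    genome_lengths: Mapping[str, int],
    variant_type: str = "SNV",
    phase: str = "pre",
) -> DensityRatio:
    """In-LOH vs out-of-LOH mutation density of one (timing-selected)
    per-sample mutation set.

    ``log10((n_in / bp_in) / (n_out / bp_out))``. When either count is
    zero, 0.5 is added to both and the result is flagged corrected. A
    sample with no LOH (or fully-LOH) autosomal genome is not computable.
    """
    df = mutations_frame(mutations)
    if not df.empty:
        df = df[df["variant_type"] == variant_type]
        bad = set(df["chrom"]) - set(genome_lengths)
        bad -= {c for c in bad if c not in AUTOSOMES}
        if bad:
            raise ValueError(f"mutation on chromosome(s) {sorted(bad)} not in genome")
        df = df[df["chrom"].isin(AUTOSOMES)].reset_index(drop=True)
    total = sum(int(genome_lengths[c]) for c in genome_lengths if c in AUTOSOMES)
    bp_in = profile.total_loh_bp
    bp_out = total - bp_in
    if df.empty:
        n_in = n_out = 0
    else:
        in_mask = _in_loh_mask(df, profile)
        n_in = int(in_mask.sum())
        n_out = int(len(df) - n_in)
    if bp_in == 0 or bp_out == 0:
        return DensityRatio(
            profile.sample_id, variant_type, phase, n_in, n_out, bp_in, bp_out,
            float("nan"), False, False,
        )
    corrected = n_in == 0 or n_out == 0
    a, b = (n_in + 0.5, n_out + 0.5) if corrected else (n_in, n_out)
    ratio = (a / bp_in) / (b / bp_out)
    return DensityRatio(
        profile.sample_id, variant_type, phase, n_in, n_out, bp_in, bp_out,
        math.log10(ratio), corrected, True,
    )


def density_ratio_table(
    mutations,
    profiles: Mapping[str, LOHProfile],
    samples,
    genome_lengths: Mapping[str, int],
    phase: str = "pre",
    variant_types: Iterable[str] = ("SNV", "INDEL"),
) -> pd.DataFrame:
    """Per-sample density ratios for every requested variant type."""
    df = mutations_frame(mutations)
    sdf = _samples_frame(samples)
    rows = []
    muts_by_sample = dict(tuple(df.groupby("sample"))) if not df.empty else {}
    for srow in sdf.itertuples(index=False):
        sid = srow.sample
        if sid not in profiles:
            continue
        sel = select_timing(
            muts_by_sample.get(sid, df.iloc[0:0]), bool(srow.wgd_status), phase
        )
        for vt in variant_types:
            dr = density_ratio(sel, profiles[sid], genome_lengths, vt, phase)
            rows.append(
                {
                    "sample": sid,
                    "cancer_type": srow.cancer_type,
                    "wgd_status": bool(srow.wgd_status),
                    "variant_type": vt,
                    "phase": phase,
                    "n_in": dr.n_in,
                    "n_out": dr.n_out,
                    "bp_in": dr.bp_in,
                    "bp_out": dr.bp_out,
                    "log10_ratio": dr.log10_ratio,
                    "corrected": dr.corrected,
                    "computable": dr.computable,
                }
            )
    return pd.DataFrame(rows)


def compare_density_ratios(
    ratio_table: pd.DataFrame, by_cancer_type: bool = False
) -> pd.DataFrame:
    """Wilcoxon rank-sum WGD vs nWGD on per-sample log10 density ratios.

    Pooled ("ALL") or per cancer type with BH adjustment across types,
    one comparison per variant type. Groups with fewer than two
    computable ratios are reported as not computable.
    """
    df = ratio_table[ratio_table["computable"]]
    rows = []
    for vt, vt_df in df.groupby("variant_type"):
        groups = (
            vt_df.groupby("cancer_type") if by_cancer_type else [("ALL", vt_df)]
        )
        for name, grp in groups:
            w = grp.loc[grp["wgd_status"], "log10_ratio"].to_numpy()
            n = grp.loc[~grp["wgd_status"], "log10_ratio"].to_numpy()
            ok = len(w) >= 2 and len(n) >= 2
            rows.append(
                {
                    "variant_type": vt,
                    "cancer_type": name,
                    "n_wgd": len(w),
                    "n_nwgd": len(n),
                    "median_wgd": float(np.median(w)) if len(w) else np.nan,
                    "median_nwgd": float(np.median(n)) if len(n) else np.nan,
                    "p_value": ranksum_p(w, n) if ok else np.nan,
                    "computable": ok,
                }
            )
    out = pd.DataFrame(rows)
    if by_cancer_type:
        out["q_value"] = np.nan
        for vt in out["variant_type"].unique():
            m = out["variant_type"] == vt
            out.loc[m, "q_value"] = bh_adjust(out.loc[m, "p_value"])
    else:
        out["q_value"] = out["p_value"]
    return out


@dataclass
class SelectionResult:
    """Pooled 2x2 selective-pressure odds ratio for one gene list.

    a: listed-gene mutations in LOH; b: other genic mutations in LOH;
    c: listed-gene mutations outside LOH; d: other genic mutations outside
    LOH. Intergenic mutations are excluded from all cells. OR = (a/b)/(c/d)
    with a log-normal 95% CI; any zero cell triggers a Haldane 0.5
    correction of all four cells (flagged).
    """

    gene_list: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    se_log_or: float
    corrected: bool
    computable: bool
    class_filter: Optional[str] = None
    phase: Optional[str] = None
    stratum: Optional[str] = None

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _gene_interval_sets(
    genes: Iterable[GeneAnnotation], gene_flag: str
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], int]:
    genic: dict[str, list] = {}
    listed: dict[str, list] = {}
    n_listed = 0
    for g in genes:
        if g.chrom not in AUTOSOMES:
            continue
        genic.setdefault(g.chrom, []).append((g.start, g.end))
        if getattr(g, gene_flag):
            n_listed += 1
            listed.setdefault(g.chrom, []).append((g.start, g.end))
    return (
        {c: iv.merge(v) for c, v in genic.items()},
        {c: iv.merge(v) for c, v in listed.items()},
        n_listed,
    )


def apply_class_filter(df: pd.DataFrame, class_filter: Optional[str]) -> pd.DataFrame:
    if class_filter is None:
        return df
    if class_filter == "disruptive":
        keep = (df["variant_type"] == "INDEL") | df["functional_class"].isin(
            ["nonsynonymous", "stopgain"]
        )
    elif class_filter == "synonymous":
        keep = (df["variant_type"] == "SNV") & (
            df["functional_class"] == "synonymous"
        )
    else:
        raise ValueError(f"unknown class filter {class_filter!r}")
    return df[keep]


def selection_odds_ratio(
    mutations,
    profiles: Mapping[str, LOHProfile],
    genes: Iterable[GeneAnnotation],
    gene_list: str = "tsg",
    class_filter: Optional[str] = None,
    phase: Optional[str] = None,
    stratum: Optional[str] = None,
) -> SelectionResult:
    """Pooled odds ratio contrasting listed-gene vs other genic mutations
    inside vs outside each sample's LOH regions.

    ``mutations`` must already be timing-selected and restricted to the
    stratum of interest; cells are summed over all its samples. Gene
    membership is resolved by overlap of the mutation position with the
    gene interval; a position inside any listed gene counts as listed.
    """
    genes = list(genes)
    flag = GENE_LISTS.get(gene_list, gene_list)
    genic_iv, listed_iv, n_listed = _gene_interval_sets(genes, flag)
    if n_listed == 0:
        raise ValueError(f"gene list {gene_list!r} is empty")

    df = mutations_frame(mutations)
    a = b = c = d = 0
    if not df.empty:
        df = apply_class_filter(df, class_filter)
        df = df[df["chrom"].isin(AUTOSOMES)]
        for (sid, chrom), sub in df.groupby(["sample", "chrom"], sort=False):
            prof = profiles.get(sid)
            if prof is None:
                raise ValueError(f"no LOH profile for sample {sid}")
            pos = sub["pos"].to_numpy()
            in_loh = iv.contains(prof.intervals.get(chrom, iv.EMPTY), pos)
            in_genic = iv.contains(genic_iv.get(chrom, iv.EMPTY), pos)
            in_listed = iv.contains(listed_iv.get(chrom, iv.EMPTY), pos)
            a += int(np.sum(in_loh & in_listed))
            b += int(np.sum(in_loh & in_genic & ~in_listed))
            c += int(np.sum(~in_loh & in_listed))
            d += int(np.sum(~in_loh & in_genic & ~in_listed))

    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    odds = (aa / bb) / (cc / dd)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return SelectionResult(
        gene_list=gene_list,
        a=a, b=b, c=c, d=d,
        odds_ratio=odds,
        ci_low=odds * math.exp(-1.96 * se),
        ci_high=odds * math.exp(1.96 * se),
        se_log_or=se,
        corrected=corrected,
        computable=True,
        class_filter=class_filter,
        phase=phase,
        stratum=stratum,
    )


def selection_table(
    mutations,
    profiles: Mapping[str, LOHProfile],
    samples,
    genes: Iterable[GeneAnnotation],
    phase: str = "pre",
    gene_lists: Iterable[str] = ("essential", "cgc", "tsg"),
    class_filters: Iterable[Optional[str]] = (None,),
) -> pd.DataFrame:
    """One pooled SelectionResult per WGD stratum x gene list (x filter)."""
    genes = list(genes)
    sdf = _samples_frame(samples)
    sel = select_timing_cohort(mutations, sdf, phase)
    rows = []
    for wgd in (True, False):
        ids = set(sdf.loc[sdf["wgd_status"].astype(bool) == wgd, "sample"])
        sub = sel[sel["sample"].isin(ids)] if not sel.empty else sel
        prof = {s: p for s, p in profiles.items() if s in ids}
        for gl in gene_lists:
            for cf in class_filters:
                res = selection_odds_ratio(
                    sub, prof, genes, gl, cf, phase, "WGD" if wgd else "nWGD"
                )
                rows.append(
                    {
                        "stratum": res.stratum,
                        "phase": phase,
                        "gene_list": gl,
                        "class_filter": cf if cf else "all",
                        "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                        "odds_ratio": res.odds_ratio,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "corrected": res.corrected,
                    }
                )
    return pd.DataFrame(rows)
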