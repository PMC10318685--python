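"""Prognostic gene exploration.

Two screens, run within WGD strata (per cancer type and pooled):

* LOH-length percentile screen - samples are split into H (>= 75th
  percentile of total LOH length) and L (<= 25th percentile) groups, gene
  presence-in-LOH counts are normalized by group size, and genes in the
  top 25% of the difference n'_H - n'_L are survival-tested on their
  presence in LOH.
* TSG-mutation screen - every tumour suppressor gene mutated inside LOH
  in at least one sample is survival-tested on mutated-vs-not status.

Hits must satisfy p < 0.05, BH FDR < 0.25, and HR > 1; hits map to
chromosome arms via a cytoband table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import intervals as iv
from .loh import LOHProfile, _samples_frame
from .stats import bh_adjust
from .surv import DEFAULT_COVARIATES, fit_cox
from .timing import mutations_frame, select_timing
from .types import AUTOSOMES, CytobandArm, GeneAnnotation

logger = logging.getLogger("wgdloh")

HIT_P = 0.05
HIT_FDR = 0.25


@dataclass
class PercentileGroups:
    """H/L sample groups of one stratum, split on total LOH length."""

    H: list[str]
    L: list[str]
    p25: float
    p75: float

    def __post_init__(self) -> None:
        if set(self.H) & set(self.L):
            raise ValueError("H and L groups overlap")


def make_percentile_groups(loh_lengths: pd.Series) -> PercentileGroups:
    """Split samples on the 25th/75th percentiles (linear interpolation)
    of total LOH length; boundary-equal samples are included (>= / <=)."""
    v = loh_lengths.astype(float)
    if len(v) < 8:
        raise ValueError(f"stratum too small for percentile groups (n={len(v)})")
    p25, p75 = np.percentile(v.to_numpy(), [25, 75])
    if p25 == p75:
        raise ValueError("degenerate percentile split (25th == 75th)")
    return PercentileGroups(
        H=list(v.index[v >= p75]),
        L=list(v.index[v <= p25]),
        p25=float(p25),
        p75=float(p75),
    )


def genes_in_loh(
    profile: LOHProfile,
    genes: Iterable[GeneAnnotation],
    mode: str = "overlap",
) -> set[str]:
    """Genes intersecting the sample's LOH regions.

    ``overlap`` requires >= 1 bp of overlap; ``containment`` requires the
    full gene interval inside a single LOH interval.
    """
    if mode not in ("overlap", "containment"):
        raise ValueError(f"unknown mode {mode!r}")
    out = set()
    for g in genes:
        arr = profile.intervals.get(g.chrom)
        if arr is None or not len(arr):
            continue
        if mode == "overlap":
            if iv.total_bp(iv.intersect(arr, [(g.start, g.end)])) > 0:
                out.add(g.gene_id)
        else:
            idx = np.searchsorted(arr[:, 0], g.start, side="right") - 1
            if idx >= 0 and arr[idx, 0] <= g.start and g.end <= arr[idx, 1]:
                out.add(g.gene_id)
    return out


def gene_loh_sets(
    profiles: Mapping[str, LOHProfile],
    genes: Iterable[GeneAnnotation],
    mode: str = "overlap",
) -> dict[str, set[str]]:
    genes = list(genes)
    return {sid: genes_in_loh(p, genes, mode) for sid, p in profiles.items()}


def candidate_genes(
    groups: PercentileGroups, gene_sets: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Per-gene H/L presence counts, normalized difference, and the
    top-25% candidate flag.

    delta = n_H/|H| - n_L/|L| over genes observed in >= 1 sample of H u L;
    candidates have delta >= the 75th percentile of the delta distribution
    (ties at the threshold included).
    """
    seen: set[str] = set()
    for sid in list(groups.H) + list(groups.L):
        seen |= gene_sets.get(sid, set())
    if not seen:
        return pd.DataFrame(
            columns=["gene_id", "n_H", "n_L", "nH_norm", "nL_norm", "delta",
                     "is_candidate"]
        )
    rows = []
    for g in sorted(seen):
        n_h = sum(g in gene_sets.get(s, ()) for s in groups.H)
        n_l = sum(g in gene_sets.get(s, ()) for s in groups.L)
        rows.append((g, n_h, n_l, n_h / len(groups.H), n_l / len(groups.L)))
    df = pd.DataFrame(rows, columns=["gene_id", "n_H", "n_L", "nH_norm", "nL_norm"])
    df["delta"] = df["nH_norm"] - df["nL_norm"]
    threshold = np.percentile(df["delta"].to_numpy(), 75)
    df["is_candidate"] = df["delta"] >= threshold
    return df


def screen_survival(
    candidates: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    clinical,
    covariates: frozenset = DEFAULT_COVARIATES,
    stratum: str = "ALL",
) -> pd.DataFrame:
    """Cox fit per candidate gene on presence-in-LOH, BH-adjusted within
    the stratum; hits satisfy p < 0.05, FDR < 0.25, HR > 1.

    Genes with no presence contrast or a failed fit are recorded as
    untested (``tested = False``).
    """
    samples = list(gene_sets)
    rows = []
    for gene in candidates:
        labels = pd.Series(
            [gene in gene_sets[s] for s in samples], index=pd.Index(samples,
            name="sample"), dtype=bool,
        )
        res = fit_cox(labels, clinical, covariates, factor=gene, stratum=stratum)
        if not res.computable:
            logger.info("gene %s skipped in %s: %s", gene, stratum, res.message)
        rows.append(
            {
                "gene_id": gene,
                "stratum": stratum,
                "n_present": int(labels.sum()),
                "n_samples": res.n_samples,
                "hazard_ratio": res.hazard_ratio,
                "p_value": res.p_value,
                "tested": res.computable,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["gene_id", "stratum", "n_present", "n_samples",
                     "hazard_ratio", "p_value", "tested", "fdr", "is_hit"]
        )
    df["fdr"] = np.nan
    tested = df["tested"]
    df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p_value"])
    df["is_hit"] = (
        tested
        & (df["p_value"] < HIT_P)
        & (df["fdr"] < HIT_FDR)
        & (df["hazard_ratio"] > 1)
    )
    return df


def run_loh_gene_screen(
    profiles: Mapping[str, LOHProfile],
    samples,
    clinical,
    genes: Iterable[GeneAnnotation],
    by_cancer_type: bool = False,
    covariates: frozenset = DEFAULT_COVARIATES,
    mode: str = "overlap",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full LOH-length percentile screen.

    Returns (hits/tested table, candidate table), one block per
    cancer-type (or pooled "ALL") x WGD stratum. Strata too small or too
    uniform for percentile groups are skipped with a log entry.
    """
    genes = list(genes)
    sdf = _samples_frame(samples)
    sdf = sdf[sdf["sample"].isin(profiles)]
    gene_sets = gene_loh_sets(profiles, genes, mode)
    lengths = pd.Series({s: profiles[s].total_loh_bp for s in sdf["sample"]})

    blocks = sdf.groupby("cancer_type") if by_cancer_type else [("ALL", sdf)]
    screened, cands = [], []
    for ct, grp in blocks:
        for wgd in (True, False):
            stratum = f"{ct}:{'WGD' if wgd else 'nWGD'}"
            ids = grp.loc[grp["wgd_status"].astype(bool) == wgd, "sample"].tolist()
            try:
                groups = make_percentile_groups(lengths.loc[ids])
            except ValueError as exc:
                logger.info("stratum %s skipped: %s", stratum, exc)
                continue
            cand = candidate_genes(groups, gene_sets)
            cand.insert(0, "stratum", stratum)
            cands.append(cand)
            chosen = cand.loc[cand["is_candidate"], "gene_id"].tolist()
            res = screen_survival(
                chosen,
                {s: gene_sets[s] for s in ids},
                clinical,
                covariates,
                stratum=stratum,
            )
            if not res.empty:
                res.insert(1, "cancer_type", ct)
                screened.append(res)
    screened_df = pd.concat(screened, ignore_index=True) if screened else \
        pd.DataFrame()
    cand_df = pd.concat(cands, ignore_index=True) if cands else pd.DataFrame()
    return screened_df, cand_df


def tsg_mutation_screen(
    mutations,
    profiles: Mapping[str, LOHProfile],
    samples,
    clinical,
    genes: Iterable[GeneAnnotation],
    phase: str = "pre",
    by_cancer_type: bool = False,
    covariates: frozenset = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Survival screen on presence/absence of TSG mutations inside LOH.

    For each TSG mutated inside LOH in >= 1 sample of the stratum, fits a
    Cox model on mutated-vs-not with the standard covariates; the same
    p/FDR/HR retention thresholds apply.
    """
    genes = [g for g in genes if g.is_tsg and g.chrom in AUTOSOMES]
    mdf = mutations_frame(mutations)
    sdf = _samples_frame(samples)
    sdf = sdf[sdf["sample"].isin(profiles)]
    by_sample = dict(tuple(mdf.groupby("sample"))) if not mdf.empty else {}

    # per sample, the set of TSGs with a phase-selected mutation inside LOH
    mutated: dict[str, set[str]] = {}
    for srow in sdf.itertuples(index=False):
        sid = srow.sample
        prof = profiles[sid]
        sel = select_timing(
            by_sample.get(sid, mdf.iloc[0:0]), bool(srow.wgd_status), phase
        )
        hit_genes: set[str] = set()
        if not sel.empty:
            for chrom, sub in sel.groupby("chrom", sort=False):
                arr = prof.intervals.get(str(chrom), iv.EMPTY)
                if not len(arr):
                    continue
                pos = sub["pos"].to_numpy()
                in_loh = iv.contains(arr, pos)
                if not in_loh.any():
                    continue
                for g in genes:
                    if g.chrom != chrom:
                        continue
                    inside = (pos >= g.start) & (pos < g.end) & in_loh
                    if inside.any():
                        hit_genes.add(g.gene_id)
        mutated[sid] = hit_genes

    blocks = sdf.groupby("cancer_type") if by_cancer_type else [("ALL", sdf)]
    out = []
    for ct, grp in blocks:
        for wgd in (True, False):
            stratum = f"{ct}:{'WGD' if wgd else 'nWGD'}"
            ids = grp.loc[grp["wgd_status"].astype(bool) == wgd, "sample"].tolist()
            testable = sorted({g for s in ids for g in mutated[s]})
            res = screen_survival(
                testable,
                {s: mutated[s] for s in ids},
                clinical,
                covariates,
                stratum=stratum,
            )
            if not res.empty:
                res.insert(1, "cancer_type", ct)
                res = res.rename(columns={"n_present": "n_mutated"})
                out.append(res)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def map_to_arms(
    hits: pd.DataFrame,
    genes: Iterable[GeneAnnotation],
    cytobands: Iterable[CytobandArm],
) -> pd.DataFrame:
    """Count screen hits (and TSG hits) per chromosome arm and cancer type.

    The arm is assigned by the gene's start position; genes spanning the
    p/q boundary are assigned to the start arm with a warning.
    """
    gene_map = {g.gene_id: g for g in genes}
    arm_list = list(cytobands)
    if hits.empty:
        return pd.DataFrame(columns=["cancer_type", "chrom", "arm", "n_genes",
                                     "n_tsg"])
    rows = []
    hit_rows = hits[hits["is_hit"]] if "is_hit" in hits.columns else hits
    for h in hit_rows.itertuples(index=False):
        g = gene_map.get(h.gene_id)
        if g is None:
            raise ValueError(f"hit gene {h.gene_id} has no coordinates")
        arm = None
        for a in arm_list:
            if a.chrom == g.chrom and a.start <= g.start < a.end:
                arm = a
                break
        if arm is None:
            raise ValueError(f"gene {h.gene_id} not covered by cytobands")
        if g.end > arm.end:
            logger.warning(
                "gene %s spans the %s%s boundary; assigned by start",
                g.gene_id, g.chrom, arm.arm,
            )
        ct = getattr(h, "cancer_type", "ALL")
        rows.append((ct, g.chrom, arm.arm, g.is_tsg))
    df = pd.DataFrame(rows, columns=["cancer_type", "chrom", "arm", "is_tsg"])
    out = (
        df.groupby(["cancer_type", "chrom", "arm"])
        .agg(n_genes=("is_tsg", "size"), n_tsg=("is_tsg", "sum"))
        .reset_index()
    )
    out["n_tsg"] = out["n_tsg"].astype(int)
    return out
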