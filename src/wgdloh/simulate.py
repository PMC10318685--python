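"""Synthetic tumour-cohort generator.

Emits cohorts with the statistical structure the analysis assumes:

* per-sample LOH genome fraction drawn from a WGD-status-dependent Beta
  (WGD samples carry more LOH), with chromosome 17 up-weighted for LOH
  tract placement in WGD samples;
* somatic mutations placed by a Poisson process whose intensity inside
  LOH is multiplied per (stratum, phase), with TSG-overlapping positions
  inside LOH further up-weighted (the selective-pressure signal, strongest
  in nWGD samples);
* survival times from an exponential proportional-hazards model whose
  linear predictor is built from the planted factor effects, with
  independent exponential censoring.

All randomness flows from a single seed through per-sample sub-streams,
so an identical seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import intervals as iv
from . import io as cio
from .genomes import GRCH37_AUTOSOMES, toy_genome
from .types import AUTOSOMES, CytobandArm, GeneAnnotation

# Per-cancer-type (WGD, nWGD) sample counts of the pan-cancer
# whole-genome reference cohort; totals 806 WGD / 1,912 nWGD.
TABLE1_COUNTS: dict[str, tuple[int, int]] = {
    "Biliary": (6, 6),
    "Bladder": (15, 8),
    "Blood": (11, 191),
    "Bone/Soft tissue": (43, 55),
    "Breast": (105, 109),
    "CNS": (39, 255),
    "Colon/Rectum": (23, 37),
    "Esophagus": (60, 38),
    "Head and neck": (25, 80),
    "Kidney": (28, 161),
    "Liver": (85, 261),
    "Lung": (56, 30),
    "Myeloid": (0, 50),
    "Ovary": (68, 45),
    "Pancreas": (112, 212),
    "Prostate": (18, 233),
    "Skin": (58, 49),
    "Stomach": (29, 46),
    "Uterus": (25, 46),
}

LN = math.log


def default_wgd_frequencies() -> dict[str, tuple[int, int]]:
    """Per-cancer-type (WGD, nWGD) counts of the reference cohort."""
    return dict(TABLE1_COUNTS)


def _default_timing_mixture() -> dict:
    return {
        "wgd": {
            "early_clonal": 0.30,
            "clonal": 0.20,
            "late_clonal": 0.25,
            "subclonal": 0.25,
        },
        "nwgd": {"clonal": 0.55, "subclonal": 0.45},
    }


def _default_in_loh_enrichment() -> dict:
    return {
        "wgd": {"pre": 2.0, "post": 2.5},
        "nwgd": {"pre": 1.3, "post": 1.2},
    }


def _default_tsg_selection() -> dict:
    return {"wgd": 1.3, "nwgd": 2.0}


def _default_log_hrs() -> dict:
    return {
        "wgd": {
            "loh_length": LN(1.8),
            "chr17_loh": LN(1.5),
            "prognostic_gene": LN(2.5),
        },
        "nwgd": {
            "loh_length": LN(1.8),
            "chr17_loh": LN(1.5),
            "tsg_mutation_count": LN(2.0),
            "prognostic_gene": LN(2.5),
            "tsg_effect_gene": LN(2.5),
        },
    }


def _default_loh_beta() -> dict:
    # means 0.25 (WGD) and 0.10 (nWGD)
    return {"wgd": (2.5, 7.5), "nwgd": (1.2, 10.8)}


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    cancer_counts: dict = field(default_factory=default_wgd_frequencies)
    scale: float = 1.0
    chrom_length: int = 10_000_000
    n_chroms: int = 22
    use_grch37: bool = False
    loh_beta: dict = field(default_factory=_default_loh_beta)
    tract_mean_frac: float = 0.15
    chr17_enrichment: float = 3.0
    n_genes: int = 2000
    n_tsg: int = 100
    n_essential: int = 50
    n_cgc: int = 60
    gene_length: int = 20_000
    chr17_tsg_excess: float = 3.0
    mutation_rate: float = 2e-6
    indel_fraction: float = 0.1
    timing_mixture: dict = field(default_factory=_default_timing_mixture)
    in_loh_enrichment: dict = field(default_factory=_default_in_loh_enrichment)
    tsg_selection: dict = field(default_factory=_default_tsg_selection)
    survival_log_hrs: dict = field(default_factory=_default_log_hrs)
    prognostic_loh_boost: float = 2.5
    tsg_effect_loh_boost: float = 2.5
    baseline_hazard: float = 1.0 / 1500.0
    censoring_rate: float = 1.0 / 3000.0
    max_followup_days: float = 3650.0

    def genome(self) -> dict[str, int]:
        if self.use_grch37:
            return dict(GRCH37_AUTOSOMES)
        return toy_genome(self.chrom_length, self.n_chroms)

    def scaled_counts(self) -> dict[str, tuple[int, int]]:
        out = {}
        for ct, (w, n) in self.cancer_counts.items():
            sw = int(round(w * self.scale))
            sn = int(round(n * self.scale))
            out[ct] = (max(sw, 1) if w > 0 else 0, max(sn, 1) if n > 0 else 0)
        return out

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """All planted effects off: uniform mutations, no survival signal."""
        base = dict(
            in_loh_enrichment={"wgd": {"pre": 1.0, "post": 1.0},
                               "nwgd": {"pre": 1.0, "post": 1.0}},
            tsg_selection={"wgd": 1.0, "nwgd": 1.0},
            survival_log_hrs={"wgd": {}, "nwgd": {}},
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Cohort:
    """In-memory synthetic cohort plus its generator ground truth."""

    samples: pd.DataFrame
    segments: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    genes: list
    cytobands: list
    ground_truth: pd.DataFrame
    genome_lengths: dict
    config: SimConfig


class _GlobalCoords:
    """Flatten the per-chromosome coordinate system into one axis."""

    def __init__(self, genome: dict[str, int]):
        self.chroms = [c for c in AUTOSOMES if c in genome]
        lens = np.array([genome[c] for c in self.chroms], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lens)])
        self.total = int(self.offsets[-1])
        self._index = {c: i for i, c in enumerate(self.chroms)}

    def to_global(self, per_chrom: dict[str, np.ndarray]) -> np.ndarray:
        parts = []
        for c, arr in per_chrom.items():
            if len(arr):
                parts.append(np.asarray(arr) + self.offsets[self._index[c]])
        return iv.merge(np.concatenate(parts)) if parts else iv.EMPTY.copy()

    def split(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(self.offsets, positions, side="right") - 1
        return idx, positions - self.offsets[idx]

    def chrom_names(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.chroms, dtype=object)[idx]


def _make_genes(cfg: SimConfig, genome: dict[str, int], rng) -> list[GeneAnnotation]:
    chroms = [c for c in AUTOSOMES if c in genome]
    pitch = cfg.gene_length * 2
    slots = {c: genome[c] // pitch for c in chroms}
    total_slots = sum(slots.values())
    if cfg.n_genes > total_slots:
        raise ValueError("gene catalog does not fit the genome")
    lens = np.array([genome[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(cfg.n_genes, lens / lens.sum())
    n_per = np.minimum(n_per, [slots[c] for c in chroms])
    genes = []
    for c, k in zip(chroms, n_per):
        chosen = rng.choice(slots[c], size=int(k), replace=False)
        for s in np.sort(chosen):
            start = int(s) * pitch
            genes.append(
                GeneAnnotation(
                    gene_id=f"G{c}_{int(s)}", chrom=c,
                    start=start, end=start + cfg.gene_length,
                )
            )
    # TSG flags with a chr17 excess, then independent essential/CGC draws
    w = np.array(
        [cfg.chr17_tsg_excess if g.chrom == "17" else 1.0 for g in genes]
    )
    tsg_idx = rng.choice(len(genes), size=min(cfg.n_tsg, len(genes)),
                         replace=False, p=w / w.sum())
    for i in tsg_idx:
        genes[i].is_tsg = True
    for attr, n in (("is_essential", cfg.n_essential), ("is_cgc", cfg.n_cgc)):
        for i in rng.choice(len(genes), size=min(n, len(genes)), replace=False):
            setattr(genes[i], attr, True)
    return genes


def _make_cytobands(genome: dict[str, int]) -> list[CytobandArm]:
    out = []
    for c in (cc for cc in AUTOSOMES if cc in genome):
        mid = int(genome[c] * 0.4)
        out.append(CytobandArm(chrom=c, arm="p", start=0, end=mid))
        out.append(CytobandArm(chrom=c, arm="q", start=mid, end=genome[c]))
    return out


def _place_loh(
    rng, coords: _GlobalCoords, genome: dict[str, int],
    target_bp: int, chr17_weight: float, tract_mean: float,
    anchors: tuple = (),
) -> dict[str, np.ndarray]:
    """Draw non-overlapping LOH tracts until exactly ``target_bp`` is
    covered, choosing chromosomes by length (chr17 up-weighted).

    ``anchors`` are (chrom, start, end, probability) tuples modelling
    recurrently lost loci: with the given probability a tract overlapping
    the locus is placed first.
    """
    if target_bp > coords.total:
        raise ValueError("infeasible LOH target fraction (> 1)")
    gaps: dict[str, list[list[int]]] = {
        c: [[0, genome[c]]] for c in coords.chroms
    }
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in coords.chroms}
    remaining = int(target_bp)
    for c, a0, a1, p_anchor in anchors:
        if remaining <= 0 or rng.random() >= p_anchor:
            continue
        free = [g for g in gaps[c] if g[0] < a1 and g[1] > a0]
        if not free:
            continue
        g0, g1 = free[0]
        lo0, hi0 = max(g0, a0), min(g1, a1)
        if lo0 >= hi0:
            continue
        tract = int(rng.exponential(tract_mean)) + 1
        tract = min(max(tract, a1 - a0), remaining, g1 - g0)
        lo = max(g0, lo0 - tract + 1)
        hi = min(g1 - tract, hi0 - 1)
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        placed[c].append((start, start + tract))
        gaps[c].remove([g0, g1])
        if start > g0:
            gaps[c].append([g0, start])
        if start + tract < g1:
            gaps[c].append([start + tract, g1])
        remaining -= tract
    while remaining > 0:
        free = np.array(
            [sum(g[1] - g[0] for g in gaps[c]) for c in coords.chroms],
            dtype=float,
        )
        w = free * np.array(
            [chr17_weight if c == "17" else 1.0 for c in coords.chroms]
        )
        if w.sum() <= 0:
            raise ValueError("no free genome left for LOH placement")
        ci = rng.choice(len(coords.chroms), p=w / w.sum())
        c = coords.chroms[ci]
        glens = np.array([g[1] - g[0] for g in gaps[c]], dtype=float)
        gi = rng.choice(len(gaps[c]), p=glens / glens.sum())
        g0, g1 = gaps[c][gi]
        tract = int(rng.exponential(tract_mean)) + 1
        tract = min(tract, remaining, g1 - g0)
        start = int(rng.integers(g0, g1 - tract + 1))
        placed[c].append((start, start + tract))
        gaps[c].pop(gi)
        if start > g0:
            gaps[c].append([g0, start])
        if start + tract < g1:
            gaps[c].append([start + tract, g1])
        remaining -= tract
    return {c: iv.merge(v) for c, v in placed.items() if v}


_BASES = np.array(list("ACGT"))


def _mutation_attributes(rng, n: int, indel_fraction: float):
    is_indel = rng.random(n) < indel_fraction
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    ref = _BASES[ref_i].astype(object)
    alt = _BASES[alt_i].astype(object)
    ref[is_indel] = ref[is_indel] + alt[is_indel]
    alt[is_indel] = [r[0] for r in ref[is_indel]]
    vt = np.where(is_indel, "INDEL", "SNV")
    return ref, alt, vt


_FCLASSES = np.array(["nonsynonymous", "synonymous", "stopgain", "other"])
_FPROBS = np.array([0.45, 0.30, 0.10, 0.15])


def simulate_cohort(config: Optional[SimConfig] = None, seed: int = 0) -> Cohort:
    """Generate a full synthetic cohort (all six file payloads plus the
    ground truth) from one seed."""
    cfg = config or SimConfig()
    genome = cfg.genome()
    coords = _GlobalCoords(genome)
    root = np.random.SeedSequence(seed)

    counts = cfg.scaled_counts()
    plan: list[tuple[str, bool]] = []
    for ct in sorted(counts):
        w, n = counts[ct]
        plan.extend((ct, True) for _ in range(w))
        plan.extend((ct, False) for _ in range(n))
    n_samples = len(plan)

    streams = root.spawn(1 + 2 * n_samples)
    gene_rng = np.random.default_rng(streams[0])
    genes = _make_genes(cfg, genome, gene_rng)
    cytobands = _make_cytobands(genome)

    tsg_global = coords.to_global(
        _group_intervals(g for g in genes if g.is_tsg)
    )
    # gene lookup table in global coordinates
    g_iv = []
    for g in genes:
        off = coords.offsets[coords._index[g.chrom]]
        g_iv.append((g.start + off, g.end + off, g.gene_id))
    g_iv.sort()
    g_starts = np.array([x[0] for x in g_iv], dtype=np.int64)
    g_ends = np.array([x[1] for x in g_iv], dtype=np.int64)
    g_names = np.array([x[2] for x in g_iv], dtype=object)

    prog_gene = _pick_gene(genes, chrom="16", tsg=False)
    pten_like = _pick_gene(genes, chrom="10", tsg=True)

    tract_mean = cfg.tract_mean_frac * np.mean(
        [genome[c] for c in coords.chroms]
    )

    seg_frames, mut_frames, truth_rows, sample_rows = [], [], [], []
    for i, (ct, wgd) in enumerate(plan):
        rng = np.random.default_rng(streams[1 + 2 * i])
        sid = f"S{i:05d}"
        stratum = "wgd" if wgd else "nwgd"
        a, b = cfg.loh_beta[stratum]
        frac = float(rng.beta(a, b))
        target = int(round(frac * coords.total))
        anchors = []
        if prog_gene is not None:
            anchors.append(
                (prog_gene.chrom, prog_gene.start, prog_gene.end,
                 min(1.0, frac * cfg.prognostic_loh_boost))
            )
        if pten_like is not None:
            anchors.append(
                (pten_like.chrom, pten_like.start, pten_like.end,
                 min(1.0, frac * cfg.tsg_effect_loh_boost))
            )
        loh = _place_loh(
            rng, coords, genome, target,
            cfg.chr17_enrichment if wgd else 1.0, tract_mean,
            anchors=tuple(anchors),
        )
        loh_global = coords.to_global(loh)
        bp_in = iv.total_bp(loh_global)
        out_global = iv.complement(loh_global, coords.total)
        tsg_in = iv.intersect(loh_global, tsg_global)
        tsg_in_bp = iv.total_bp(tsg_in)
        nontsg_in = iv.subtract(loh_global, tsg_global)

        seg_frames.append(_segments_frame(sid, loh, genome, coords, wgd))

        # mutations per timing class
        mix = cfg.timing_mixture[stratum]
        ts = cfg.tsg_selection[stratum]
        mut_pos, mut_class = [], []
        n_tsg_pre = 0
        pre_in = pre_out = post_in = post_out = 0
        for tclass, weight in mix.items():
            phase = "pre" if tclass in ("early_clonal", "clonal") else "post"
            rate = cfg.mutation_rate * weight
            enrich = cfg.in_loh_enrichment[stratum][phase]
            lam_out = rate * iv.total_bp(out_global)
            lam_in = rate * enrich * (
                iv.total_bp(nontsg_in) + ts * tsg_in_bp
            )
            n_tot = rng.poisson(lam_in + lam_out)
            if n_tot == 0:
                continue
            p_in = lam_in / (lam_in + lam_out) if (lam_in + lam_out) else 0.0
            n_in = rng.binomial(n_tot, p_in)
            n_out = n_tot - n_in
            denom = iv.total_bp(nontsg_in) + ts * tsg_in_bp
            n_t = rng.binomial(n_in, ts * tsg_in_bp / denom) if denom > 0 else 0
            pos = []
            if n_t:
                pos.append(iv.sample_positions(tsg_in, n_t, rng))
            if n_in - n_t:
                pos.append(iv.sample_positions(nontsg_in, n_in - n_t, rng))
            if n_out:
                pos.append(iv.sample_positions(out_global, n_out, rng))
            pos = np.concatenate(pos) if pos else np.empty(0, dtype=np.int64)
            mut_pos.append(pos)
            mut_class.append(np.full(len(pos), tclass, dtype=object))
            if phase == "pre":
                n_tsg_pre += int(n_t)
                pre_in += int(n_in)
                pre_out += int(n_out)
            else:
                post_in += int(n_in)
                post_out += int(n_out)

        if mut_pos:
            pos = np.concatenate(mut_pos)
            tcls = np.concatenate(mut_class)
            order = np.argsort(pos, kind="stable")
            pos, tcls = pos[order], tcls[order]
            ref, alt, vt = _mutation_attributes(rng, len(pos), cfg.indel_fraction)
            gi = np.searchsorted(g_starts, pos, side="right") - 1
            in_gene = (gi >= 0) & (pos < g_ends[np.maximum(gi, 0)])
            gene_id = np.where(in_gene, g_names[np.maximum(gi, 0)], "")
            fclass = np.where(
                in_gene,
                rng.choice(_FCLASSES, size=len(pos), p=_FPROBS),
                "other",
            )
            ci, cpos = coords.split(pos)
            mut_frames.append(
                pd.DataFrame(
                    {
                        "sample": sid,
                        "chrom": coords.chrom_names(ci),
                        "pos": cpos,
                        "ref": ref,
                        "alt": alt,
                        "variant_type": vt,
                        "functional_class": fclass,
                        "timing_class": tcls,
                        "gene_id": gene_id,
                    }
                )
            )
            pten_mutated = bool(
                pten_like is not None
                and np.any(
                    (gene_id == pten_like.gene_id)
                    & iv.contains(loh_global, pos)
                    & np.isin(tcls, ["early_clonal", "clonal"])
                )
            )
        else:
            pten_mutated = False

        bp_out = coords.total - bp_in
        if bp_in > 0 and bp_out > 0:
            ni, no = (pre_in, pre_out) if pre_in and pre_out else \
                (pre_in + 0.5, pre_out + 0.5)
            dens = math.log10((ni / bp_in) / (no / bp_out))
        else:
            dens = float("nan")
        prog_present = bool(
            prog_gene is not None
            and iv.total_bp(
                iv.intersect(
                    loh.get(prog_gene.chrom, iv.EMPTY),
                    [(prog_gene.start, prog_gene.end)],
                )
            )
            > 0
        )
        truth_rows.append(
            {
                "sample": sid,
                "cancer_type": ct,
                "wgd_status": wgd,
                "target_fraction": frac,
                "realized_fraction": bp_in / coords.total,
                "total_loh_bp": bp_in,
                "chr17_loh": "17" in loh and len(loh["17"]) > 0,
                "tsg_mutation_count": n_tsg_pre,
                "density_ratio": dens,
                "prognostic_gene_in_loh": prog_present,
                "tsg_effect_gene_mutated": pten_mutated,
            }
        )
        ploidy = 4.0 * (1 - bp_in / coords.total) + 2.0 * bp_in / coords.total \
            if wgd else 2.0 - bp_in / coords.total
        sample_rows.append(
            {
                "sample": sid,
                "cancer_type": ct,
                "wgd_status": wgd,
                "purity": round(float(rng.uniform(0.3, 0.95)), 4),
                "ploidy": round(ploidy, 4),
            }
        )

    truth = pd.DataFrame(truth_rows)
    samples = pd.DataFrame(sample_rows)

    # planted survival effects act on the same median-split labels the
    # analysis recomputes
    lp = np.zeros(n_samples)
    for stratum, wgd in (("wgd", True), ("nwgd", False)):
        m = truth["wgd_status"] == wgd
        if not m.any():
            continue
        effects = cfg.survival_log_hrs.get(stratum, {})
        for factor, beta in effects.items():
            if beta == 0:
                continue
            if factor == "loh_length":
                v = truth.loc[m, "total_loh_bp"].astype(float)
                label = v > v.median()
            elif factor == "chr17_loh":
                label = truth.loc[m, "chr17_loh"].astype(bool)
            elif factor == "tsg_mutation_count":
                v = truth.loc[m, "tsg_mutation_count"].astype(float)
                label = v > v.median()
            elif factor == "density_ratio":
                v = truth.loc[m, "density_ratio"].astype(float)
                label = v > v.median()
            elif factor == "prognostic_gene":
                label = truth.loc[m, "prognostic_gene_in_loh"].astype(bool)
            elif factor == "tsg_effect_gene":
                label = truth.loc[m, "tsg_effect_gene_mutated"].astype(bool)
            else:
                raise ValueError(f"unknown survival factor {factor!r}")
            lp[m.to_numpy()] += beta * label.to_numpy().astype(float)
    truth["linear_predictor"] = lp

    clin_rows = []
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = np.random.default_rng(streams[2 + 2 * i])
        hazard = cfg.baseline_hazard * math.exp(row.linear_predictor)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / cfg.censoring_rate)
        t = min(t_event, t_cens, cfg.max_followup_days)
        clin_rows.append(
            {
                "sample": row.sample,
                "survival_days": round(t, 1),
                "event": bool(t_event <= min(t_cens, cfg.max_followup_days)),
                "age_at_diagnosis": round(
                    float(np.clip(rng.normal(62, 11), 20, 90)), 1
                ),
                "sex": "male" if rng.random() < 0.5 else "female",
                "cancer_type": row.cancer_type,
                "stage": "",
            }
        )

    truth["prognostic_gene_id"] = prog_gene.gene_id if prog_gene else ""
    truth["tsg_effect_gene_id"] = pten_like.gene_id if pten_like else ""

    return Cohort(
        samples=samples,
        segments=pd.concat(seg_frames, ignore_index=True)
        if seg_frames else pd.DataFrame(
            columns=["sample", "chrom", "start", "end", "major_cn", "minor_cn"]
        ),
        mutations=pd.concat(mut_frames, ignore_index=True)
        if mut_frames else pd.DataFrame(
            columns=["sample", "chrom", "pos", "ref", "alt", "variant_type",
                     "functional_class", "timing_class", "gene_id"]
        ),
        clinical=pd.DataFrame(clin_rows),
        genes=genes,
        cytobands=cytobands,
        ground_truth=truth,
        genome_lengths=genome,
        config=cfg,
    )


def _group_intervals(genes) -> dict[str, np.ndarray]:
    out: dict[str, list] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append((g.start, g.end))
    return {c: iv.merge(v) for c, v in out.items()}


def _pick_gene(genes, chrom: str, tsg: bool):
    """Designated planted gene: prefers the requested chromosome."""
    matches = [g for g in genes if g.is_tsg == tsg]
    on_chrom = [g for g in matches if g.chrom == chrom]
    if on_chrom:
        return on_chrom[0]
    return matches[0] if matches else None


def _segments_frame(sid, loh, genome, coords, wgd) -> pd.DataFrame:
    rows = []
    major_loh = 2 if wgd else 1
    major_n, minor_n = (2, 2) if wgd else (1, 1)
    for c in coords.chroms:
        arr = loh.get(c, iv.EMPTY)
        for s, e in arr:
            rows.append((sid, c, int(s), int(e), major_loh, 0))
        for s, e in iv.complement(arr, genome[c]):
            rows.append((sid, c, int(s), int(e), major_n, minor_n))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "major_cn", "minor_cn"]
    )


def write_cohort(cohort: Cohort, outdir, seed: Optional[int] = None) -> dict:
    """Write the six cohort files, the ground truth, and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_segments(cohort.segments, outdir / "segments.seg")
    cio.write_mutations(cohort.mutations, outdir / "mutations.tsv")
    cio.write_samples(cohort.samples, outdir / "samples.tsv")
    cio.write_clinical(cohort.clinical, outdir / "clinical.tsv")
    cio.write_genes(cohort.genes, outdir / "genes.bed", list_dir=outdir)
    cio.write_cytobands(cohort.cytobands, outdir / "cytoBand.txt")
    cohort.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    from . import __version__

    manifest = {
        "seed": seed,
        "version": __version__,
        "n_samples": int(len(cohort.samples)),
        "config": cohort.config.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
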