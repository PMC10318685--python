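"""Readers and writers for every on-disk format the pipeline touches.

Conventions
-----------
* Segment files (ASCAT-like ``.seg`` TSV) are 1-based inclusive on disk.
* Mutation tables carry 1-based positions.
* BED and UCSC cytoband files are 0-based half-open.
* Everything is converted to the internal 0-based half-open convention
  here and only here; downstream modules never see on-disk coordinates.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    AUTOSOMES,
    TIMING_CLASSES,
    ClinicalRecord,
    CopyNumberSegment,
    CytobandArm,
    GeneAnnotation,
    SampleRecord,
    SomaticMutation,
    normalize_chrom,
)

logger = logging.getLogger("wgdloh")

SEGMENT_COLUMNS = ["sample", "chromosome", "startpos", "endpos", "nMajor", "nMinor"]
MUTATION_COLUMNS = [
    "sample",
    "chromosome",
    "position",
    "ref",
    "alt",
    "functional_class",
    "timing_class",
]
CLINICAL_COLUMNS = [
    "sample",
    "survival_days",
    "event",
    "age_at_diagnosis",
    "sex",
    "cancer_type",
]
SAMPLE_COLUMNS = ["sample", "cancer_type", "wgd_status", "purity", "ploidy"]


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return df


def read_segments(path) -> list[CopyNumberSegment]:
    """Read an ASCAT-dialect segment TSV (1-based inclusive coordinates)."""
    df = _read_tsv(path, SEGMENT_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            seg = CopyNumberSegment(
                sample_id=row.sample,
                chrom=row.chromosome,
                start=int(row.startpos) - 1,
                end=int(row.endpos),
                major_cn=int(row.nMajor),
                minor_cn=int(row.nMinor),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        if not seg.is_autosomal:
            logger.debug("line %d: non-autosomal segment on chr%s", i, seg.chrom)
        out.append(seg)
    return out


def write_segments(segments, path) -> None:
    """Write segments (records or an internal-convention DataFrame) back to
    the 1-based inclusive on-disk dialect."""
    if isinstance(segments, pd.DataFrame):
        df = pd.DataFrame(
            {
                "sample": segments["sample"],
                "chromosome": segments["chrom"],
                "startpos": segments["start"].astype(int) + 1,
                "endpos": segments["end"].astype(int),
                "nMajor": segments["major_cn"].astype(int),
                "nMinor": segments["minor_cn"].astype(int),
            }
        )
        df.to_csv(path, sep="\t", index=False)
        return
    rows = [
        (s.sample_id, s.chrom, s.start + 1, s.end, s.major_cn, s.minor_cn)
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutations(path) -> list[SomaticMutation]:
    """Read a MAF-like mutation TSV; unknown timing labels become
    ``unassigned`` with a logged warning."""
    df = _read_tsv(path, MUTATION_COLUMNS)
    has_gene = "gene" in df.columns
    out = []
    n_unknown = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        timing = row.timing_class
        if timing not in TIMING_CLASSES:
            n_unknown += 1
            timing = "unassigned"
        vt = "SNV" if (len(row.ref) == 1 and len(row.alt) == 1) else "INDEL"
        try:
            mut = SomaticMutation(
                sample_id=row.sample,
                chrom=row.chromosome,
                pos=int(row.position) - 1,
                ref=row.ref,
                alt=row.alt,
                variant_type=vt,
                functional_class=row.functional_class,
                timing_class=timing,
                gene_id=row.gene if has_gene else "",
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        out.append(mut)
    if n_unknown:
        logger.warning(
            "%s: %d mutation(s) with unrecognized timing label set to 'unassigned'",
            path,
            n_unknown,
        )
    return out


def write_mutations(mutations, path) -> None:
    cols = MUTATION_COLUMNS[:5] + ["variant_type"] + MUTATION_COLUMNS[5:] + ["gene"]
    if isinstance(mutations, pd.DataFrame):
        df = pd.DataFrame(
            {
                "sample": mutations["sample"],
                "chromosome": mutations["chrom"],
                "position": mutations["pos"].astype(int) + 1,
                "ref": mutations["ref"],
                "alt": mutations["alt"],
                "variant_type": mutations["variant_type"],
                "functional_class": mutations["functional_class"],
                "timing_class": mutations["timing_class"],
                "gene": mutations.get("gene_id", ""),
            }
        )
        df[cols].to_csv(path, sep="\t", index=False)
        return
    rows = [
        (
            m.sample_id,
            m.chrom,
            m.pos + 1,
            m.ref,
            m.alt,
            m.variant_type,
            m.functional_class,
            m.timing_class,
            m.gene_id,
        )
        for m in mutations
    ]
    cols = MUTATION_COLUMNS[:5] + ["variant_type"] + MUTATION_COLUMNS[5:] + ["gene"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


_TRUTHY = {"true", "1", "yes", "t", "wgd"}
_FALSY = {"false", "0", "no", "f", "nwgd"}


def _parse_bool(value: str, where: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValueError(f"{where}: cannot parse boolean {value!r}")


def read_samples(path) -> list[SampleRecord]:
    df = _read_tsv(path, SAMPLE_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                SampleRecord(
                    sample_id=row.sample,
                    cancer_type=row.cancer_type,
                    wgd_status=_parse_bool(row.wgd_status, f"line {i}"),
                    purity=float(row.purity),
                    ploidy=float(row.ploidy),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return out


def write_samples(samples, path) -> None:
    if isinstance(samples, pd.DataFrame):
        samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)
        return
    rows = [
        (s.sample_id, s.cancer_type, s.wgd_status, s.purity, s.ploidy)
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> list[ClinicalRecord]:
    df = _read_tsv(path, CLINICAL_COLUMNS)
    has_stage = "stage" in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        stage = getattr(row, "stage", "") if has_stage else ""
        try:
            out.append(
                ClinicalRecord(
                    sample_id=row.sample,
                    survival_days=float(row.survival_days),
                    event=_parse_bool(row.event, f"line {i}"),
                    age_at_diagnosis=float(row.age_at_diagnosis),
                    sex=row.sex,
                    cancer_type=row.cancer_type,
                    stage=stage if stage != "" else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return out


def write_clinical(records, path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "stage" not in df.columns:
            df["stage"] = ""
        df["stage"] = df["stage"].fillna("")
        df[CLINICAL_COLUMNS + ["stage"]].to_csv(path, sep="\t", index=False)
        return
    rows = [
        (
            r.sample_id,
            r.survival_days,
            r.event,
            r.age_at_diagnosis,
            r.sex,
            r.cancer_type,
            r.stage if r.stage is not None else "",
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS + ["stage"]).to_csv(
        path, sep="\t", index=False
    )


def _read_membership(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_genes(
    bed_path,
    essential_path=None,
    cgc_path=None,
    tsg_path=None,
) -> list[GeneAnnotation]:
    """Read a gene BED (0-based half-open) plus optional one-gene-per-line
    membership files for the essential / CGC / TSG lists.

    Membership entries absent from the BED are warned about and ignored.
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    lists = {
        "is_essential": _read_membership(essential_path) if essential_path else set(),
        "is_cgc": _read_membership(cgc_path) if cgc_path else set(),
        "is_tsg": _read_membership(tsg_path) if tsg_path else set(),
    }
    known = set(bed["gene_id"])
    for flag, members in lists.items():
        orphans = members - known
        if orphans:
            logger.warning(
                "%d %s gene(s) not present in %s; ignored",
                len(orphans),
                flag.removeprefix("is_"),
                bed_path,
            )
    out = []
    for i, row in enumerate(bed.itertuples(index=False), start=1):
        try:
            out.append(
                GeneAnnotation(
                    gene_id=row.gene_id,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    is_essential=row.gene_id in lists["is_essential"],
                    is_cgc=row.gene_id in lists["is_cgc"],
                    is_tsg=row.gene_id in lists["is_tsg"],
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{bed_path}: line {i}: {exc}") from exc
    return out


def write_genes(genes: Iterable[GeneAnnotation], bed_path, list_dir=None) -> None:
    """Write the gene BED and, when ``list_dir`` is given, the three
    membership files (essential.txt, cgc.txt, tsg.txt)."""
    genes = list(genes)
    rows = [(g.chrom, g.start, g.end, g.gene_id) for g in genes]
    pd.DataFrame(rows).to_csv(bed_path, sep="\t", index=False, header=False)
    if list_dir is not None:
        list_dir = Path(list_dir)
        for flag, fname in (
            ("is_essential", "essential.txt"),
            ("is_cgc", "cgc.txt"),
            ("is_tsg", "tsg.txt"),
        ):
            members = [g.gene_id for g in genes if getattr(g, flag)]
            (list_dir / fname).write_text("".join(m + "\n" for m in members))


def read_cytobands(path) -> list[CytobandArm]:
    """Read a UCSC cytoBand file and collapse bands into p/q arms."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str},
    )
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["arm"] = df["band"].str[0]
    bad = ~df["arm"].isin(["p", "q"])
    if bad.any():
        raise ValueError(f"{path}: band name(s) not starting with p/q")
    out = []
    for (chrom, arm), grp in df.groupby(["chrom", "arm"], sort=False):
        out.append(
            CytobandArm(
                chrom=chrom, arm=arm, start=int(grp["start"].min()),
                end=int(grp["end"].max()),
            )
        )
    out.sort(key=lambda a: (_chrom_order(a.chrom), a.arm))
    return out


def write_cytobands(arms: Iterable[CytobandArm], path) -> None:
    rows = [
        (f"chr{a.chrom}", a.start, a.end, f"{a.arm}11", "gneg") for a in arms
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def _chrom_order(chrom: str) -> int:
    try:
        return AUTOSOMES.index(chrom)
    except ValueError:
        return 100 + ord(chrom[0])
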