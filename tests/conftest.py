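import numpy as np
import pandas as pd
import pytest

from wgdloh import SimConfig, profiles_from_frame, simulate_cohort
from wgdloh.types import CopyNumberSegment, GeneAnnotation


def seg(sample, chrom, start, end, major, minor):
    return CopyNumberSegment(sample, chrom, start, end, major, minor)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest two-type cohort reused by read-only tests."""
    cfg = SimConfig(
        cancer_counts={"Lung": (40, 30), "CNS": (20, 50)},
        n_genes=250, n_tsg=25, n_essential=12, n_cgc=15,
        chrom_length=1_000_000, mutation_rate=2e-5,
    )
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return profiles_from_frame(small_cohort.segments)


@pytest.fixture
def toy_genes():
    return [
        GeneAnnotation("TSG1", "1", 100, 200, is_tsg=True),
        GeneAnnotation("TSG2", "2", 100, 200, is_tsg=True),
        GeneAnnotation("ESS1", "1", 300, 400, is_essential=True),
        GeneAnnotation("OTH1", "1", 500, 600),
        GeneAnnotation("OTH2", "2", 500, 600),
    ]


def samples_df(rows):
    return pd.DataFrame(
        rows, columns=["sample", "cancer_type", "wgd_status", "purity", "ploidy"]
    )


def clinical_df(rows):
    return pd.DataFrame(
        rows,
        columns=["sample", "survival_days", "event", "age_at_diagnosis",
                 "sex", "cancer_type", "stage"],
    )


def mutations_df(rows):
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "variant_type",
                 "functional_class", "timing_class", "gene_id"],
    )
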