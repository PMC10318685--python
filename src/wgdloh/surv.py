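"""Cox proportional-hazards screening of LOH-derived factors and
Kaplan-Meier summaries.

Four factors are screened within each WGD stratum: total LOH length,
LOH on chromosome 17, the count of phase-selected mutations in tumour
suppressor genes inside LOH, and the in/out-LOH mutation density ratio.
Continuous factors are median-split (ties go to the low group); chr17 LOH
is used as presence/absence. Cancer type, sex, and age at diagnosis are
covariates; stage enters only when recorded for at least 80% of the
stratum. Ties in event times are handled with the Efron approximation
(lifelines' default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from . import intervals as iv
from .loh import LOHProfile, _samples_frame
from .timing import _in_loh_mask, mutations_frame, select_timing
from .types import AUTOSOMES, GeneAnnotation, to_frame

logger = logging.getLogger("wgdloh")

PRE_FACTORS = ("loh_length", "chr17_loh", "tsg_mutation_count", "density_ratio")
POST_FACTORS = ("tsg_mutation_count", "density_ratio")
DEFAULT_COVARIATES = frozenset({"age", "sex", "cancer_type", "stage"})
STAGE_COVERAGE_MIN = 0.8


def dichotomize(values, mode: str = "median_split") -> np.ndarray:
    """Binary high/low labels for a factor.

    ``median_split``: strictly above the median is high. ``presence_absence``
    passes booleans through. A constant vector cannot be median-split.
    """
    v = np.asarray(values)
    if mode == "presence_absence":
        return v.astype(bool)
    if mode != "median_split":
        raise ValueError(f"unknown dichotomization mode {mode!r}")
    v = v.astype(float)
    if len(np.unique(v[np.isfinite(v)])) < 2:
        raise ValueError("degenerate median split: all values identical")
    return v > np.nanmedian(v)


@dataclass
class SurvivalResult:
    factor: str
    stratum: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_samples: int
    n_events: int
    n_dropped: int
    computable: bool
    message: str = ""


def _clinical_frame(clinical) -> pd.DataFrame:
    if isinstance(clinical, pd.DataFrame):
        df = clinical.copy()
    else:
        df = to_frame(clinical).rename(columns={"sample_id": "sample"})
    if "sample" not in df.columns and "sample_id" in df.columns:
        df = df.rename(columns={"sample_id": "sample"})
    return df


def _design_matrix(
    labels: pd.Series, clinical: pd.DataFrame, covariates: frozenset
) -> tuple[pd.DataFrame, int]:
    df = clinical.set_index("sample").copy()
    df = df.join(labels.rename("factor"), how="inner")
    n_before = len(df)
    df = df[df["factor"].notna() & df["survival_days"].notna()]
    design = pd.DataFrame(
        {
            "duration": df["survival_days"].astype(float),
            "event": df["event"].astype(bool).astype(int),
            "factor": df["factor"].astype(bool).astype(int),
        },
        index=df.index,
    )
    if "age" in covariates and "age_at_diagnosis" in df.columns:
        design["age"] = df["age_at_diagnosis"].astype(float)
    if "sex" in covariates and "sex" in df.columns:
        design["sex_male"] = (df["sex"] == "male").astype(int)
    if "cancer_type" in covariates and "cancer_type" in df.columns:
        types = sorted(df["cancer_type"].unique())
        for t in types[1:]:
            design[f"ct_{t}"] = (df["cancer_type"] == t).astype(int)
    if "stage" in covariates and "stage" in df.columns:
        stage = df["stage"].astype(object).mask(lambda s: s == "")
        if stage.notna().mean() >= STAGE_COVERAGE_MIN:
            codes = pd.Categorical(stage).codes.astype(float)
            codes[codes < 0] = np.nan
            design["stage"] = codes
        else:
            logger.debug("stage recorded for <%.0f%% of stratum; dropped",
                         100 * STAGE_COVERAGE_MIN)
    design = design.dropna()
    # constant columns (single sex, single cancer type) carry no contrast
    keep = [
        c for c in design.columns
        if c in ("duration", "event", "factor") or design[c].nunique() > 1
    ]
    return design[keep], n_before - len(design)


def fit_cox(
    labels: pd.Series,
    clinical,
    covariates: frozenset = DEFAULT_COVARIATES,
    factor: str = "factor",
    stratum: str = "ALL",
) -> SurvivalResult:
    """Cox PH fit of one binary factor with covariate adjustment.

    Returns the factor's hazard ratio with Wald 95% CI and two-sided p.
    Non-convergence or a degenerate design yields a non-computable result
    rather than an exception.
    """
    cdf = _clinical_frame(clinical)
    design, n_dropped = _design_matrix(labels, cdf, covariates)
    n = len(design)
    n_events = int(design["event"].sum()) if n else 0

    def _fail(msg: str) -> SurvivalResult:
        return SurvivalResult(
            factor, stratum, np.nan, np.nan, np.nan, np.nan,
            n, n_events, n_dropped, False, msg,
        )

    if n == 0 or n_events == 0:
        return _fail("no samples or no events")
    if design["factor"].nunique() < 2:
        return _fail("factor has no contrast")
    cph = CoxPHFitter()
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="duration", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        return _fail(f"non-convergence: {exc}")
    hr = float(np.exp(cph.params_["factor"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["factor"])
    p = float(cph.summary.loc["factor", "p"])
    if not np.isfinite(hr) or hr > 1e6 or hr < 1e-6:
        return _fail("complete separation")
    return SurvivalResult(
        factor, stratum, hr, float(lo), float(hi), p,
        n, n_events, n_dropped, True,
    )


def km_summary(labels: pd.Series, clinical) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per factor group.

    Returns, per group label, a table of event times with numbers at risk,
    observed events, and the survival estimate. Empty groups are omitted
    with a warning.
    """
    cdf = _clinical_frame(clinical).set_index("sample")
    cdf = cdf.join(labels.rename("factor"), how="inner")
    out: dict[str, pd.DataFrame] = {}
    for name, grp in cdf.groupby(cdf["factor"].astype(bool)):
        if grp.empty:
            logger.warning("empty factor group %s omitted from KM summary", name)
            continue
        km = KaplanMeierFitter()
        km.fit(
            grp["survival_days"].astype(float),
            grp["event"].astype(bool),
            label=str(name),
        )
        table = km.event_table
        surv = km.survival_function_.iloc[:, 0]
        out[str(name)] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "at_risk": table["at_risk"].to_numpy(dtype=int),
                "events": table["observed"].to_numpy(dtype=int),
                "censored": table["censored"].to_numpy(dtype=int),
                "survival": surv.reindex(table.index).to_numpy(dtype=float),
            }
        )
    return out


def compute_factors(
    mutations,
    profiles: Mapping[str, LOHProfile],
    samples,
    genes: Iterable[GeneAnnotation],
    genome_lengths: Mapping[str, int],
    phase: str = "pre",
) -> pd.DataFrame:
    """Per-sample values of the four screened factors.

    ``tsg_mutation_count`` counts phase-selected mutations overlapping a
    TSG inside the sample's LOH; ``density_ratio`` is the combined
    SNV+indel log10 in/out density contrast.
    """
    genes = list(genes)
    tsg_iv = {}
    for g in genes:
        if g.is_tsg and g.chrom in AUTOSOMES:
            tsg_iv.setdefault(g.chrom, []).append((g.start, g.end))
    tsg_iv = {c: iv.merge(v) for c, v in tsg_iv.items()}

    mdf = mutations_frame(mutations)
    by_sample = dict(tuple(mdf.groupby("sample"))) if not mdf.empty else {}
    sdf = _samples_frame(samples)
    total = sum(int(genome_lengths[c]) for c in genome_lengths if c in AUTOSOMES)
    rows = []
    for srow in sdf.itertuples(index=False):
        sid = srow.sample
        prof = profiles.get(sid)
        if prof is None:
            continue
        sel = select_timing(
            by_sample.get(sid, mdf.iloc[0:0]), bool(srow.wgd_status), phase
        )
        sel = sel[sel["chrom"].isin(AUTOSOMES)].reset_index(drop=True) \
            if not sel.empty else sel
        tsg_count = 0
        n_in = 0
        if not sel.empty:
            in_loh = _in_loh_mask(sel, prof)
            n_in = int(in_loh.sum())
            for chrom, sub in sel.groupby("chrom", sort=False):
                arr = tsg_iv.get(str(chrom))
                if arr is None or not len(arr):
                    continue
                loh_arr = prof.intervals.get(str(chrom), iv.EMPTY)
                if not len(loh_arr):
                    continue
                pos = sub["pos"].to_numpy()
                tsg_count += int(
                    np.sum(iv.contains(arr, pos) & iv.contains(loh_arr, pos))
                )
        bp_in = prof.total_loh_bp
        bp_out = total - bp_in
        n_out = (len(sel) if not sel.empty else 0) - n_in
        if bp_in > 0 and bp_out > 0:
            ni, no = (n_in + 0.5, n_out + 0.5) if (n_in == 0 or n_out == 0) \
                else (n_in, n_out)
            dens = np.log10((ni / bp_in) / (no / bp_out))
        else:
            dens = np.nan
        rows.append(
            {
                "sample": sid,
                "wgd_status": bool(srow.wgd_status),
                "loh_length": bp_in,
                "chr17_loh": prof.has_loh("17"),
                "tsg_mutation_count": tsg_count,
                "density_ratio": dens,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


FACTOR_MODES = {
    "loh_length": "median_split",
    "chr17_loh": "presence_absence",
    "tsg_mutation_count": "median_split",
    "density_ratio": "median_split",
}


def run_factor_screen(
    factors: pd.DataFrame,
    clinical,
    phase: str = "pre",
    covariates: frozenset = DEFAULT_COVARIATES,
) -> list[SurvivalResult]:
    """One Cox fit per factor x WGD stratum.

    The pre phase screens all four factors; the post phase screens the two
    late-mutation factors (TSG mutation load in LOH and the density ratio).
    Degenerate strata propagate as non-computable results.
    """
    names = PRE_FACTORS if phase == "pre" else POST_FACTORS
    results = []
    for wgd in (True, False):
        stratum = "WGD" if wgd else "nWGD"
        stratum_df = factors[factors["wgd_status"] == wgd]
        for name in names:
            sub = stratum_df[np.isfinite(stratum_df[name].astype(float))]
            try:
                labels = pd.Series(
                    dichotomize(sub[name], FACTOR_MODES[name]), index=sub.index
                )
            except ValueError as exc:
                results.append(
                    SurvivalResult(name, stratum, np.nan, np.nan, np.nan, np.nan,
                                   len(sub), 0, 0, False, str(exc))
                )
                continue
            results.append(
                fit_cox(labels, clinical, covariates, factor=name, stratum=stratum)
            )
    return results


def results_table(results: Sequence[SurvivalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
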