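"""Mutation-burden summaries, the age-accumulation clock, and extrapolation.

Per subject x tissue, summarises filtered somatic SNV counts and the VAF
distribution (mean, median, fraction below a low-VAF threshold) plus the
six-way consequence-category composition.  The mutation clock is an ordinary
least-squares regression of per-subject SNV count on age (an optional Poisson
GLM with identity link is offered for rate-style inference); exome slopes are
extrapolated to the genome by base-pair scaling, and tissue slopes compared as
a fold ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, InvalidInputError, ReferentialIntegrityError

EXOME_BP = 75e6
GENOME_BP = 3e9

CONSEQUENCE_CATEGORIES = (
    "Non-synonymous",
    "Synonymous",
    "UTR",
    "Intronic",
    "Splicing",
    "Intergenic",
)


@dataclass
class RateFit:
    tissue: str
    slope: float  # SNVs per exome per year
    intercept: float
    slope_se: float
    n_subjects: int


def summarize_burden(
    calls: pd.DataFrame,
    subjects: pd.DataFrame,
    vaf_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per subject x tissue burden table.

    ``calls`` needs columns subject_id, tissue, vaf and (optionally) category;
    ``subjects`` needs subject_id, group, age.  Subjects without calls appear
    with n_snvs 0 and NaN VAF statistics.  Calls referencing unknown subjects
    raise a referential-integrity error.
    """
    known = set(subjects["subject_id"])
    orphans = set(calls["subject_id"]) - known
    if orphans:
        raise ReferentialIntegrityError(f"calls reference unknown subjects: {sorted(orphans)[:5]}")

    tissues = sorted(calls["tissue"].unique()) if len(calls) else ["brain"]
    rows = []
    grouped = calls.groupby(["subject_id", "tissue"]) if len(calls) else None
    groups = dict(list(grouped)) if grouped is not None else {}
    for _, subj in subjects.iterrows():
        for tissue in tissues:
            sub = groups.get((subj["subject_id"], tissue))
            row = {
                "subject_id": subj["subject_id"],
                "group": subj["group"],
                "tissue": tissue,
                "age": subj["age"],
            }
            if sub is None or len(sub) == 0:
                row.update(
                    n_snvs=0,
                    mean_vaf=np.nan,
                    median_vaf=np.nan,
                    frac_below_threshold=np.nan,
                )
                for cat in CONSEQUENCE_CATEGORIES:
                    row[f"n_{cat}"] = 0
            else:
                vafs = sub["vaf"].to_numpy(dtype=float)
                row.update(
                    n_snvs=len(sub),
                    mean_vaf=float(vafs.mean()),
                    median_vaf=float(np.median(vafs)),
                    frac_below_threshold=float((vafs < vaf_threshold).mean()),
                )
                cats = sub["category"] if "category" in sub else pd.Series(dtype=str)
                counts = cats.value_counts()
                for cat in CONSEQUENCE_CATEGORIES:
                    row[f"n_{cat}"] = int(counts.get(cat, 0))
            rows.append(row)
    return pd.DataFrame(rows)


def pooled_low_vaf_fraction(
    calls: pd.DataFrame, tissue: str, vaf_threshold: float = 0.05
) -> tuple[int, int, float]:
    """(n below threshold, n total, percent to 1 decimal) pooled over a tissue."""
    sub = calls[calls["tissue"] == tissue]
    if len(sub) == 0:
        raise InvalidInputError(f"no calls for tissue {tissue!r}")
    below = int((sub["vaf"] < vaf_threshold).sum())
    total = int(len(sub))
    return below, total, round(100.0 * below / total, 1)


def fit_accumulation_rate(
    burden: pd.DataFrame,
    tissue: str,
    model: str = "ols",
) -> RateFit:
    """Regress per-subject SNV count on age for one tissue.

    ``model='ols'`` (default) is ordinary least squares; ``model='poisson'``
    fits a Poisson GLM with identity link so the slope keeps its
    SNVs-per-year units.
    """
    sub = burden[burden["tissue"] == tissue].dropna(subset=["age"])
    if len(sub) < 3:
        raise FitError(f"need >= 3 subjects with ages for tissue {tissue!r}")
    ages = sub["age"].to_numpy(dtype=float)
    counts = sub["n_snvs"].to_numpy(dtype=float)
    if np.ptp(ages) == 0:
        raise FitError("all subjects share one age; the slope is unidentifiable")
    X = sm.add_constant(ages)
    if model == "ols":
        fit = sm.OLS(counts, X).fit()
    elif model == "poisson":
        # identity link keeps the slope in SNVs/year; statsmodels warns that
        # the link does not respect the Poisson domain, which is fine here
        # (fitted means stay positive over observed ages)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                counts, X, family=sm.families.Poisson(link=sm.families.links.Identity())
            ).fit()
    else:
        raise InvalidInputError(f"unknown regression model {model!r}")
    return RateFit(
        tissue=tissue,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        n_subjects=int(len(sub)),
    )


def extrapolate_and_compare(
    brain_fit: RateFit,
    blood_fit: RateFit,
    exome_bp: float = EXOME_BP,
    genome_bp: float = GENOME_BP,
) -> dict:
    """Genome-scaled yearly rates per tissue plus the blood/brain fold ratio.

    genome_rate = exome slope x genome_bp / exome_bp; the fold ratio is
    reported both raw and rounded to 1 decimal.  A zero brain slope with
    non-zero blood slope yields an infinity-marked ratio.
    """
    if exome_bp <= 0:
        raise InvalidInputError("exome_bp must be positive")
    if brain_fit.slope < 0 or blood_fit.slope < 0:
        raise InvalidInputError("slopes must be >= 0 for extrapolation")
    scale = genome_bp / exome_bp
    if brain_fit.slope == 0:
        ratio = float("inf") if blood_fit.slope > 0 else float("nan")
    else:
        ratio = blood_fit.slope / brain_fit.slope
    return {
        "genome_rate_brain": brain_fit.slope * scale,
        "genome_rate_blood": blood_fit.slope * scale,
        "fold_ratio": ratio,
        "fold_ratio_1dp": round(ratio, 1) if np.isfinite(ratio) else ratio,
    }
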