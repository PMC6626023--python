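"""Targeted-amplicon validation against platform background error.

A candidate mosaic variant re-sequenced on a deep amplicon platform is accepted
as a true somatic call when its alt-allele count is statistically above the
platform's background error rate for that substitution class (one-sided exact
binomial test).  The module also summarises validation precision and the
cross-platform VAF concordance of the validated calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import ConfigurationError, InvalidInputError

#: Per-substitution background error rates (VAF units) of a two-step PCR
#: amplicon platform, pyrimidine-centred classes.
BACKGROUND_ERROR_RATES: dict[str, float] = {
    "T>A": 0.00312107,
    "T>C": 0.007970457,
    "T>G": 7.58e-04,
    "C>T": 0.004071926,
    "C>G": 7.65e-04,
    "C>A": 0.001847634,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def normalize_substitution(ref: str, alt: str) -> str:
    """Fold a substitution onto the pyrimidine-reference convention.

    A G>A call is reported (and tested) as C>T, etc.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise InvalidInputError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def check_error_table(table: dict[str, float]) -> None:
    missing = [c for c in BACKGROUND_ERROR_RATES if c not in table]
    if missing:
        raise ConfigurationError(f"error table missing substitution classes: {missing}")
    bad = {c: r for c, r in table.items() if not 0.0 < r < 1.0}
    if bad:
        raise ConfigurationError(f"error rates outside (0,1): {bad}")


@dataclass
class ValidationRecord:
    """One amplicon-resequenced candidate with its background-error verdict."""

    variant_key: str
    depth: int
    alt_count: int
    substitution: str
    p_value: float
    validated: bool
    wes_vaf: float | None = None
    amplicon_vaf: float | None = None


def background_error_test(
    alt_count: int,
    depth: int,
    substitution: str,
    table: dict[str, float] | None = None,
    alpha: float = 0.05,
    variant_key: str = "",
    wes_vaf: float | None = None,
) -> ValidationRecord:
    """One-sided exact binomial test of an amplicon count against background.

    p = P(X >= alt_count | n = depth, p = background rate of the class);
    the call validates when p < alpha.
    """
    if depth <= 0:
        raise InvalidInputError("amplicon depth must be positive")
    if not 0 <= alt_count <= depth:
        raise InvalidInputError("alt_count must lie in [0, depth]")
    table = BACKGROUND_ERROR_RATES if table is None else table
    if substitution not in table:
        # try pyrimidine normalisation of e.g. "G>A"
        try:
            ref, alt = substitution.split(">")
            substitution = normalize_substitution(ref, alt)
        except (ValueError, InvalidInputError):
            pass
    if substitution not in table:
        raise ConfigurationError(f"substitution class {substitution!r} not in error table")
    rate = table[substitution]
    p = stats.binomtest(alt_count, depth, rate, alternative="greater").pvalue
    return ValidationRecord(
        variant_key=variant_key,
        depth=depth,
        alt_count=alt_count,
        substitution=substitution,
        p_value=float(p),
        validated=bool(p < alpha),
        wes_vaf=wes_vaf,
        amplicon_vaf=alt_count / depth,
    )


def validation_summary(records: list[ValidationRecord]) -> dict:
    """Precision and cross-platform VAF concordance of a validation experiment.

    precision = validated / tested; Pearson r of (WES VAF, amplicon VAF) over
    validated records with both VAFs present, defined only at >= 3 such pairs.
    """
    if not records:
        raise InvalidInputError("no validation records supplied")
    n_tested = len(records)
    n_validated = sum(r.validated for r in records)
    precision = n_validated / n_tested
    pairs = [
        (r.wes_vaf, r.amplicon_vaf)
        for r in records
        if r.validated and r.wes_vaf is not None and r.amplicon_vaf is not None
    ]
    pearson_r = None
    if len(pairs) >= 3:
        xs, ys = zip(*pairs)
        pearson_r = float(stats.pearsonr(xs, ys).statistic)
    return {
        "n_tested": n_tested,
        "n_validated": n_validated,
        "precision": precision,
        "precision_pct": round(100.0 * precision, 1),
        "pearson_r": pearson_r,
    }
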