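"""Synthetic cohort generator: subjects, truth mosaic variants, allele counts.

Emulates the per-site count structure of a deep-exome somatic mosaicism study:
elderly AD and non-AD subjects with APOE genotypes, truth somatic SNVs whose
expected number grows linearly with age (a clock-like Poisson model), variant
allele fractions concentrated below 5%, trinucleotide contexts drawn from a
configurable signature mixture, and per-site read counts at ~584x mean depth
with class-specific background error in the case tissue, matched normal and a
panel of normals.  Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidParameterError
from .signatures import (
    COMPLEMENT,
    SignatureCatalog,
    channel_context,
    reverse_complement,
    synthetic_catalog,
)
from .validation import BACKGROUND_ERROR_RATES, check_error_table, normalize_substitution

# ---------------------------------------------------------------------------
# Defaults: the simulated study conditions
# ---------------------------------------------------------------------------

#: Signature-mixture weights for brain tissue: the three dominant ageing-brain
#: processes (flat clock-like, CpG deamination, oxidative damage) with the
#: relative proportions observed for hippocampal somatic SNVs, renormalised to 1.
DEFAULT_BRAIN_MIX = {
    "flat_aging": 0.39,
    "clocklike_deamination": 0.25,
    "oxidative_damage": 0.36,
}

#: Blood tissue: clonal-hematopoiesis-like mixture dominated by the flat
#: clock-like process plus CpG deamination.
DEFAULT_BLOOD_MIX = {"flat_aging": 0.78, "clocklike_deamination": 0.22}

#: Truncated Beta parameters for mosaic VAFs; Beta(1.2, 40) on (0.005, 0.40)
#: puts the median near 2% and ~86% of mass below 5%.
DEFAULT_VAF_DIST = (1.2, 40.0)
VAF_BOUNDS = (0.005, 0.40)

DEFAULT_DEPTH_MEAN = 584.0
DEFAULT_N_PANEL = 21
DEFAULT_SLOPE = 0.53  # somatic SNVs per exome per year (brain)
BLOOD_SLOPE = 2.55

_CONTIG = "chrS"
_CONTIG_LENGTH = 30_000_000


@lru_cache(maxsize=1)
def _default_catalog() -> SignatureCatalog:
    return synthetic_catalog()


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "AD" | "nonAD"
    tissue: str  # case tissue sampled
    age: int
    onset_age: int | None
    apoe_rs429358: str  # unphased genotype, e.g. "C/T"
    apoe_rs7412: str
    braak: int

    def __post_init__(self) -> None:
        if self.group not in ("AD", "nonAD"):
            raise InvalidParameterError(f"unknown group {self.group!r}")
        if not 0 <= self.braak <= 6:
            raise InvalidParameterError("Braak stage must lie in [0, 6]")
        if self.onset_age is not None and self.age < self.onset_age:
            raise InvalidParameterError("age must be >= onset age")


@dataclass
class TruthVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    true_vaf: float
    context: str  # 3-mer centred on the site, as written (may be purine strand)
    channel: int  # 0-95, pyrimidine-centred convention
    gene: str
    pathogenic: bool = False

    def __post_init__(self) -> None:
        assert self.context[1] == self.ref
        assert 0.0 < self.true_vaf < 0.5


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "tissue": [s.tissue for s in subjects],
            "age": [s.age for s in subjects],
            "onset_age": [s.onset_age for s in subjects],
            "apoe_rs429358": [s.apoe_rs429358 for s in subjects],
            "apoe_rs7412": [s.apoe_rs7412 for s in subjects],
            "braak": [s.braak for s in subjects],
        }
    )


def truths_to_frame(truths: list[TruthVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [t.chrom for t in truths],
            "pos": [t.pos for t in truths],
            "ref": [t.ref for t in truths],
            "alt": [t.alt for t in truths],
            "true_vaf": [t.true_vaf for t in truths],
            "context": [t.context for t in truths],
            "channel": [t.channel for t in truths],
            "gene": [t.gene for t in truths],
            "pathogenic": [t.pathogenic for t in truths],
        }
    )


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------


def _draw_apoe(rng: np.random.Generator, e4_freq: float, e2_freq: float) -> tuple[str, str]:
    """Draw two epsilon haplotypes and express them as per-site genotypes.

    e4 = rs429358-C / rs7412-C; e3 = T/C; e2 = T/T.
    """
    haps = rng.choice(
        ["e2", "e3", "e4"],
        size=2,
        p=[e2_freq, 1.0 - e2_freq - e4_freq, e4_freq],
    )
    site1 = sorted("C" if h == "e4" else "T" for h in haps)
    site2 = sorted("T" if h == "e2" else "C" for h in haps)
    return "/".join(site1), "/".join(site2)


def generate_cohort(
    n_ad: int,
    n_nonad: int,
    age_range: tuple[int, int],
    seed: int,
    e4_freq_ad: float = 0.39,
    e4_freq_nonad: float = 0.16,
    e2_freq: float = 0.05,
) -> list[SubjectRecord]:
    """Generate a synthetic subject table.

    Ages are uniform over ``age_range`` (inclusive); APOE genotypes are drawn
    from group-specific epsilon-4 haplotype frequencies; AD subjects receive an
    onset age 2-18 years before death and a high Braak stage, non-AD subjects
    Braak 0-1.
    """
    if n_ad < 0 or n_nonad < 0 or n_ad + n_nonad < 1:
        raise InvalidParameterError("cohort must contain at least one subject")
    lo, hi = int(age_range[0]), int(age_range[1])
    if hi < lo:
        raise InvalidParameterError(f"empty age range {age_range}")
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    for group, n, e4 in (("AD", n_ad, e4_freq_ad), ("nonAD", n_nonad, e4_freq_nonad)):
        for i in range(n):
            age = int(rng.integers(lo, hi + 1))
            if group == "AD":
                onset = max(48, age - int(rng.integers(2, 19)))
                braak = int(rng.choice([3, 4, 5, 6], p=[0.15, 0.30, 0.30, 0.25]))
            else:
                onset = None
                braak = int(rng.choice([0, 1]))
            g1, g2 = _draw_apoe(rng, e4, e2_freq)
            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}_{i + 1:03d}",
                    group=group,
                    tissue="brain",
                    age=age,
                    onset_age=onset,
                    apoe_rs429358=g1,
                    apoe_rs7412=g2,
                    braak=braak,
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# Truth variants
# ---------------------------------------------------------------------------


def _truncated_beta(rng: np.random.Generator, a: float, b: float, n: int) -> np.ndarray:
    lo, hi = VAF_BOUNDS
    dist = stats.beta(a, b)
    u = rng.random(n)
    q = dist.cdf(lo) + u * (dist.cdf(hi) - dist.cdf(lo))
    return dist.ppf(q)


def _distinct_positions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Distinct 1-based positions on the synthetic contig (rejection sampling)."""
    pos = rng.integers(2, _CONTIG_LENGTH, size=n)
    while len(np.unique(pos)) < n:  # collisions are ~n^2 / 3e7: rare
        pos = np.unique(pos)
        pos = np.concatenate([pos, rng.integers(2, _CONTIG_LENGTH, size=n - len(pos))])
    return pos


def generate_truth_variants(
    subject: SubjectRecord,
    slope: float = DEFAULT_SLOPE,
    intercept: float = 0.0,
    signature_mix: dict[str, float] | None = None,
    vaf_dist: tuple[float, float] = DEFAULT_VAF_DIST,
    seed: int = 0,
    catalog: SignatureCatalog | None = None,
    n_genes: int = 1000,
    pathogenic_rate: float = 0.014,
) -> list[TruthVariant]:
    """Draw a subject's truth mosaic SNVs under the linear age clock.

    The variant count is Poisson with mean ``intercept + slope * age``
    (clamped at 0); each variant's 96-channel is drawn from the signature
    mixture, its VAF from a truncated Beta, and its strand of report is
    randomised so downstream spectrum building must strand-fold.
    """
    if slope < 0:
        raise InvalidParameterError("accumulation slope must be >= 0")
    signature_mix = DEFAULT_BRAIN_MIX if signature_mix is None else signature_mix
    if abs(sum(signature_mix.values()) - 1.0) > 1e-6:
        raise InvalidParameterError("signature mixture weights must sum to 1")
    catalog = _default_catalog() if catalog is None else catalog
    rng = np.random.default_rng(seed)

    mix = np.zeros(96)
    for name, w in signature_mix.items():
        if name not in catalog.signatures:
            raise InvalidParameterError(f"signature {name!r} not in catalog")
        mix += w * catalog.signatures[name]
    mix = mix / mix.sum()

    mean = max(0.0, intercept + slope * subject.age)
    n = int(rng.poisson(mean))
    if n == 0:
        return []
    channels = rng.choice(96, size=n, p=mix)
    vafs = _truncated_beta(rng, vaf_dist[0], vaf_dist[1], n)
    positions = _distinct_positions(rng, n)
    genes = rng.integers(0, n_genes, size=n)
    pathogenic = rng.random(n) < pathogenic_rate
    flip = rng.random(n) < 0.5  # report on the purine strand half the time

    truths: list[TruthVariant] = []
    for i in range(n):
        ref, alt, ctx = channel_context(int(channels[i]))
        if flip[i]:
            ctx = reverse_complement(ctx)
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        truths.append(
            TruthVariant(
                chrom=_CONTIG,
                pos=int(positions[i]),
                ref=ref,
                alt=alt,
                true_vaf=float(vafs[i]),
                context=ctx,
                channel=int(channels[i]),
                gene=f"G{int(genes[i]):04d}",
                pathogenic=bool(pathogenic[i]),
            )
        )
    return truths


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------


def generate_allele_counts(
    truths: list[TruthVariant],
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    n_panel: int = DEFAULT_N_PANEL,
    error_table: dict[str, float] | None = None,
    seed: int = 0,
    case_sample: str = "case_brain",
    normal_sample: str = "matched_blood",
    n_decoys: int = 0,
) -> pd.DataFrame:
    """Emit a per-site, per-sample read-count table (the pileup substrate).

    Case-tissue alt counts are Binomial(depth, true VAF + class error rate);
    matched-normal and panel counts are Binomial(depth, class error rate).
    ``n_decoys`` extra non-variant sites carry pure error noise in every
    sample.  Depths are Poisson around ``depth_mean``.
    """
    if depth_mean <= 0:
        raise InvalidParameterError("depth_mean must be positive")
    error_table = BACKGROUND_ERROR_RATES if error_table is None else error_table
    check_error_table(error_table)
    rng = np.random.default_rng(seed)

    used = {t.pos for t in truths}
    decoy_sites: list[tuple[int, int]] = []  # (pos, channel)
    while len(decoy_sites) < n_decoys:
        pos = int(rng.integers(2, _CONTIG_LENGTH))
        if pos in used:
            continue
        used.add(pos)
        decoy_sites.append((pos, int(rng.integers(0, 96))))

    rows: list[tuple] = []

    def emit(pos: int, ref: str, alt: str, sample: str, role: str, p_alt: float) -> None:
        depth = max(1, int(rng.poisson(depth_mean)))
        alt_count = int(rng.binomial(depth, min(1.0, p_alt)))
        rows.append((_CONTIG, pos, ref, alt, sample, role, depth, alt_count))

    panel_ids = [f"panel_{j + 1:02d}" for j in range(n_panel)]

    for t in truths:
        err = error_table[normalize_substitution(t.ref, t.alt)]
        emit(t.pos, t.ref, t.alt, case_sample, "case_tissue", t.true_vaf + err)
        emit(t.pos, t.ref, t.alt, normal_sample, "matched_normal", err)
        for pid in panel_ids:
            emit(t.pos, t.ref, t.alt, pid, "panel", err)

    for pos, chan in decoy_sites:
        ref, alt, _ = channel_context(chan)
        err = error_table[f"{ref}>{alt}"]
        emit(pos, ref, alt, case_sample, "case_tissue", err)
        emit(pos, ref, alt, normal_sample, "matched_normal", err)
        for pid in panel_ids:
            emit(pos, ref, alt, pid, "panel", err)

    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample_id", "role", "depth", "alt_count"],
    )


# ---------------------------------------------------------------------------
# Whole-study convenience and serialisation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    subjects: pd.DataFrame
    truths: pd.DataFrame  # with subject_id column
    counts: pd.DataFrame  # with subject_id column
    truth_lists: dict[str, list[TruthVariant]] = field(default_factory=dict)


def simulate_study(
    n_ad: int = 52,
    n_nonad: int = 11,
    age_range: tuple[int, int] = (57, 96),
    seed: int = 1,
    slope: float = DEFAULT_SLOPE,
    intercept: float = 0.0,
    signature_mix: dict[str, float] | None = None,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    n_panel: int = DEFAULT_N_PANEL,
    decoys_per_subject: int = 0,
    pathogenic_rate: float = 0.014,
) -> SimulatedStudy:
    """Generate a full cohort: subjects, per-subject truths and count tables."""
    subjects = generate_cohort(n_ad, n_nonad, age_range, seed)
    seeds = np.random.SeedSequence(seed).spawn(2 * len(subjects))
    truth_frames, count_frames, truth_lists = [], [], {}
    for i, subj in enumerate(subjects):
        t_seed = int(seeds[2 * i].generate_state(1)[0] % (2**31))
        c_seed = int(seeds[2 * i + 1].generate_state(1)[0] % (2**31))
        truths = generate_truth_variants(
            subj,
            slope=slope,
            intercept=intercept,
            signature_mix=signature_mix,
            seed=t_seed,
            pathogenic_rate=pathogenic_rate,
        )
        truth_lists[subj.subject_id] = truths
        tf = truths_to_frame(truths)
        tf.insert(0, "subject_id", subj.subject_id)
        truth_frames.append(tf)
        counts = generate_allele_counts(
            truths,
            depth_mean=depth_mean,
            n_panel=n_panel,
            seed=c_seed,
            case_sample=f"{subj.subject_id}_brain",
            normal_sample=f"{subj.subject_id}_blood",
            n_decoys=decoys_per_subject,
        )
        counts.insert(0, "subject_id", subj.subject_id)
        count_frames.append(counts)
    return SimulatedStudy(
        subjects=subjects_to_frame(subjects),
        truths=pd.concat(truth_frames, ignore_index=True),
        counts=pd.concat(count_frames, ignore_index=True),
        truth_lists=truth_lists,
    )


def write_site_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_site_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "sample_id", "role", "depth", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"site-count table missing columns: {sorted(missing)}")
    return df


def write_truth_vcf(truths: list[TruthVariant], path) -> None:
    """Write the truth set as a minimal VCF (INFO keys TVAF, GENE, CHAN)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={_CONTIG},length={_CONTIG_LENGTH}>\n")
        fh.write('##INFO=<ID=TVAF,Number=1,Type=Float,Description="True VAF">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CHAN,Number=1,Type=Integer,Description="96-channel index">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for t in sorted(truths, key=lambda v: v.pos):
            info = f"TVAF={t.true_vaf:.6f};GENE={t.gene};CHAN={t.channel}"
            fh.write(f"{t.chrom}\t{t.pos}\t.\t{t.ref}\t{t.alt}\t.\t.\t{info}\n")
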