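"""Germline AD-risk genotyping, APOE epsilon resolution and carrier landscape.

Germline SNPs at catalogued risk sites are genotyped from filtered read counts
(VAF >= 40% calls a non-reference genotype; >= 90% a homozygote).  The two APOE
coding SNPs rs429358 and rs7412 are resolved into epsilon haplotypes
(e4 = 429358-C/7412-C, e3 = T/C, e2 = T/T).  Each AD subject is then placed in
the germline/somatic carrier landscape: pathogenic germline = two APOE e4
copies or a catalogued risk-modifier hit (APP/PSEN1/PSEN2/TREM2/MAPT);
pathogenic somatic = at least one putatively pathogenic brain somatic SNV in a
designated tau-phosphorylation pathway gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

VAF_HET = 0.40  # germline call threshold (inclusive)
VAF_HOM = 0.90  # homozygous-alternate threshold (inclusive)


@dataclass
class RiskSiteGenotype:
    site_id: str
    ref: str
    alt: str
    vaf: float
    genotype: str  # hom_ref | het | hom_alt

    def alt_copies(self) -> int:
        return {"hom_ref": 0, "het": 1, "hom_alt": 2}[self.genotype]


def genotype_site(
    site_id: str,
    ref: str,
    alt: str,
    alt_count: int,
    depth: int,
    vaf_het: float = VAF_HET,
    vaf_hom: float = VAF_HOM,
) -> RiskSiteGenotype:
    """Call a germline genotype from filtered read counts at one site."""
    if depth <= 0:
        raise InvalidInputError(f"{site_id}: depth must be positive")
    vaf = alt_count / depth
    if vaf >= vaf_hom:
        gt = "hom_alt"
    elif vaf >= vaf_het:
        gt = "het"
    else:
        gt = "hom_ref"
    return RiskSiteGenotype(site_id, ref, alt, vaf, gt)


def genotype_risk_sites(
    counts: pd.DataFrame,
    catalog: pd.DataFrame,
    sample_id: str,
    vaf_het: float = VAF_HET,
    vaf_hom: float = VAF_HOM,
) -> dict[str, RiskSiteGenotype]:
    """Genotype every catalogued risk site present in a sample's count table.

    ``catalog`` columns: site_id, chrom, pos, ref, alt, gene, classification.
    Sites absent from the counts are skipped with a warning.
    """
    sub = counts[counts["sample_id"] == sample_id]
    keyed = {(r.chrom, r.pos, r.ref, r.alt): r for r in sub.itertuples()}
    genotypes: dict[str, RiskSiteGenotype] = {}
    for row in catalog.itertuples():
        rec = keyed.get((row.chrom, row.pos, row.ref, row.alt))
        if rec is None:
            logger.warning("risk site %s absent from counts of %s", row.site_id, sample_id)
            continue
        genotypes[row.site_id] = genotype_site(
            row.site_id, row.ref, row.alt, rec.alt_count, rec.depth, vaf_het, vaf_hom
        )
    return genotypes


def default_risk_catalog() -> pd.DataFrame:
    """Synthetic risk-site catalog used by the simulator and tests.

    Coordinates are synthetic-contig placeholders; the named variants mirror
    well-known AD risk modifiers (PSEN1 p.E318G, TREM2 p.R62H / p.R47H) plus
    the two APOE epsilon-defining SNPs.
    """
    return pd.DataFrame(
        [
            ("rs429358", "chrS", 1_000_100, "T", "C", "APOE", "epsilon4_site"),
            ("rs7412", "chrS", 1_000_238, "C", "T", "APOE", "epsilon2_site"),
            ("PSEN1_E318G", "chrS", 2_000_500, "A", "G", "PSEN1", "risk_modifier"),
            ("TREM2_R62H", "chrS", 3_000_185, "G", "A", "TREM2", "risk_modifier"),
            ("TREM2_R47H", "chrS", 3_000_140, "G", "A", "TREM2", "risk_modifier"),
        ],
        columns=["site_id", "chrom", "pos", "ref", "alt", "gene", "classification"],
    )


# ---------------------------------------------------------------------------
# APOE epsilon haplotypes
# ---------------------------------------------------------------------------


def apoe_genotype(
    rs429358: RiskSiteGenotype, rs7412: RiskSiteGenotype
) -> tuple[int | None, str, bool]:
    """Resolve the two APOE SNP genotypes into (e4 copies, label, ambiguous).

    rs429358 alt = C (the e4-defining allele); rs7412 alt = T (the
    e2-defining allele).  A double heterozygote cannot be phased (e2/e4 vs
    e1/e3) and is returned as ambiguous with copies None.
    """
    c4 = rs429358.alt_copies()  # copies of 429358-C
    c2 = rs7412.alt_copies()  # copies of 7412-T
    if c4 == 1 and c2 == 1:
        logger.warning("double-heterozygous APOE genotype: unphaseable, flagged ambiguous")
        return None, "ambiguous", True
    if c4 + c2 > 2:
        logger.warning("inconsistent APOE genotypes (c4=%d, c2=%d)", c4, c2)
        return None, "inconsistent", True
    haps = ["e4"] * c4 + ["e2"] * c2 + ["e3"] * (2 - c4 - c2)
    label = "/".join(sorted(haps, key=lambda h: ("e2", "e3", "e4").index(h)))
    return c4, label.replace("e", "ε"), False


# ---------------------------------------------------------------------------
# Carrier landscape
# ---------------------------------------------------------------------------


@dataclass
class CarrierProfile:
    subject_id: str
    group: str
    apoe_e4_copies: int | None
    apoe_label: str
    risk_modifier_genes: set[str] = field(default_factory=set)
    somatic_pathway_genes: set[str] = field(default_factory=set)

    @property
    def has_pathogenic_germline(self) -> bool:
        return self.apoe_e4_copies == 2 or bool(self.risk_modifier_genes)

    @property
    def has_pathogenic_somatic(self) -> bool:
        return bool(self.somatic_pathway_genes)

    @property
    def category(self) -> str:
        g, s = self.has_pathogenic_germline, self.has_pathogenic_somatic
        if g and s:
            return "both"
        if g:
            return "germline_only"
        if s:
            return "somatic_only"
        return "none"


def build_carrier_profile(
    subject_id: str,
    group: str,
    genotypes: dict[str, RiskSiteGenotype],
    pathogenic_somatic_genes: set[str],
    pathway_genes: set[str],
    risk_modifier_sites: set[str] | None = None,
) -> CarrierProfile:
    """Assemble one subject's carrier profile from genotypes and somatic hits.

    ``pathogenic_somatic_genes`` are the genes carrying the subject's
    putatively pathogenic brain somatic SNVs; only those inside
    ``pathway_genes`` (the designated tau-phosphorylation pathway union)
    raise the somatic flag.
    """
    g1, g2 = genotypes.get("rs429358"), genotypes.get("rs7412")
    if g1 is not None and g2 is not None:
        copies, label, _ = apoe_genotype(g1, g2)
    else:
        copies, label = None, "undetermined"
        logger.warning("subject %s: APOE sites not fully genotyped", subject_id)
    modifiers = {
        gt.site_id
        for sid, gt in genotypes.items()
        if sid not in ("rs429358", "rs7412")
        and gt.genotype != "hom_ref"
        and (risk_modifier_sites is None or sid in risk_modifier_sites)
    }
    return CarrierProfile(
        subject_id=subject_id,
        group=group,
        apoe_e4_copies=copies,
        apoe_label=label,
        risk_modifier_genes=modifiers,
        somatic_pathway_genes=pathogenic_somatic_genes & pathway_genes,
    )


def categorize_carriers(profiles: list[CarrierProfile], ad_only: bool = True) -> dict:
    """Cohort counts and percentages of the four carrier categories.

    Percentages are to 1 decimal; the somatic-carrier total is
    somatic_only + both.
    """
    if not profiles:
        raise InvalidInputError("no carrier profiles supplied")
    if ad_only:
        profiles = [p for p in profiles if p.group == "AD"]
        if not profiles:
            raise InvalidInputError("no AD profiles after filtering")
    n = len(profiles)
    counts = {c: 0 for c in ("germline_only", "somatic_only", "both", "none")}
    for p in profiles:
        counts[p.category] += 1
    pct = {c: round(100.0 * k / n, 1) for c, k in counts.items()}
    somatic_total = counts["somatic_only"] + counts["both"]
    return {
        "n": n,
        "counts": counts,
        "percent": pct,
        "somatic_total": somatic_total,
        "somatic_total_pct": round(100.0 * somatic_total / n, 1),
    }


def profiles_to_frame(profiles: list[CarrierProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "group": [p.group for p in profiles],
            "apoe_e4_copies": [p.apoe_e4_copies for p in profiles],
            "apoe_label": [p.apoe_label for p in profiles],
            "risk_modifier_genes": [",".join(sorted(p.risk_modifier_genes)) for p in profiles],
            "has_pathogenic_germline": [p.has_pathogenic_germline for p in profiles],
            "has_pathogenic_somatic": [p.has_pathogenic_somatic for p in profiles],
            "category": [p.category for p in profiles],
        }
    )
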