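"""Consequence classification, pathogenicity prioritisation and gene-set
permutation enrichment.

Variant consequence terms are collapsed into six categories (Non-synonymous,
Synonymous, UTR, Intronic, Splicing, Intergenic).  Non-synonymous variants that
are rare in the population (MAF < 0.01%) and deleterious (Phred-scaled
CADD > 20) are flagged putatively pathogenic.  Pathway over-representation of
the resulting gene set is tested by drawing same-sized gene sets from the
cohort gene pool (optionally stratified by gene-length quintile to neutralise
length bias) and comparing overlap counts, with the exact hypergeometric tail
computed alongside as the closed-form reference for the unstratified test.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnnotationError, InvalidParameterError

logger = logging.getLogger(__name__)

DEFAULT_MAF_CUTOFF = 1e-4  # 0.01% population frequency
DEFAULT_CADD_CUTOFF = 20.0  # strict >
DEFAULT_DRAW_SIZE = 174
DEFAULT_N_PERM = 10_000

_CATEGORY_TERMS = {
    "Non-synonymous": {
        "missense_variant",
        "stop_gained",
        "start_lost",
        "stop_lost",
        "splice_donor_variant",
        "splice_acceptor_variant",
    },
    "Synonymous": {"synonymous_variant"},
    "UTR": {"5_prime_utr_variant", "3_prime_utr_variant"},
    "Intronic": {
        "intron_variant",
        "mature_mirna_variant",
        "non_coding_transcript_exon_variant",
        "stop_retained_variant",
    },
    "Splicing": {"splice_region_variant"},
    "Intergenic": {"intergenic_variant", "upstream_gene_variant", "downstream_gene_variant"},
}

_TERM_TO_CATEGORY = {t: c for c, terms in _CATEGORY_TERMS.items() for t in terms}
# common aliases without the trailing "_variant" / "_gene_variant"
_TERM_TO_CATEGORY.update(
    {
        "missense": "Non-synonymous",
        "splice_donor": "Non-synonymous",
        "splice_acceptor": "Non-synonymous",
        "synonymous": "Synonymous",
        "intron": "Intronic",
        "intergenic": "Intergenic",
        "upstream": "Intergenic",
        "downstream": "Intergenic",
        "upstream_variant": "Intergenic",
        "downstream_variant": "Intergenic",
        "splice_region": "Splicing",
    }
)


def _normalize_term(term: str) -> str:
    t = term.strip().lower()
    t = t.replace("′", "_prime").replace("'", "_prime")
    t = re.sub(r"[\s\-]+", "_", t)
    t = re.sub(r"_+", "_", t)
    t = t.replace("5_prime_utr", "5_prime_utr").replace("five_prime_utr", "5_prime_utr")
    t = t.replace("three_prime_utr", "3_prime_utr")
    return t


def classify_consequence(term: str) -> str:
    """Map a consequence term to one of the six categories.

    Unknown terms are returned as ``"unclassified"`` (and logged), never an
    error: annotation sources drift.
    """
    if not term or not term.strip():
        raise AnnotationError("empty consequence term")
    cat = _TERM_TO_CATEGORY.get(_normalize_term(term))
    if cat is None:
        logger.warning("unclassified consequence term: %r", term)
        return "unclassified"
    return cat


@dataclass
class AnnotatedVariant:
    """A filtered call plus functional annotations used for prioritisation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence_term: str
    gene: str
    cadd: float | None = None
    maf: float | None = None  # population minor allele frequency; None = novel

    @property
    def category(self) -> str:
        return classify_consequence(self.consequence_term)


def filter_putatively_pathogenic(
    variants: list[AnnotatedVariant],
    maf_cut: float = DEFAULT_MAF_CUTOFF,
    cadd_cut: float = DEFAULT_CADD_CUTOFF,
) -> list[AnnotatedVariant]:
    """Keep rare, deleterious, non-synonymous variants.

    Retained iff (MAF absent or MAF < maf_cut) AND CADD > cadd_cut (strict)
    AND category Non-synonymous.  Candidates lacking a CADD score abort with
    an annotation error that lists them.
    """
    missing = [v for v in variants if v.cadd is None]
    if missing:
        keys = [f"{v.chrom}:{v.pos}{v.ref}>{v.alt}" for v in missing[:10]]
        raise AnnotationError(f"variants missing CADD scores: {keys}")
    return [
        v
        for v in variants
        if (v.maf is None or v.maf < maf_cut)
        and v.cadd > cadd_cut
        and v.category == "Non-synonymous"
    ]


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, set[str]]:
    """Read pathway gene sets from GMT (name, description, genes...)."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = {g for g in parts[2:] if g}
    return pathways


def write_gmt(pathways: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")


def synthetic_gene_sets(
    universe: list[str] | None = None,
    sizes: dict[str, int] | None = None,
    seed: int = 7,
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Synthetic three-pathway collection plus gene lengths, for tests.

    Mirrors the structure of the tau-phosphorylation-related KEGG pathways
    (PI3K-AKT-like 341 genes, MAPK-like 255, AMPK-like 124) over a synthetic
    gene universe; gene lengths are log-normal around 3 kb.
    """
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = [f"G{i:04d}" for i in range(1000)]
    if sizes is None:
        sizes = {"PI3K_AKT_like": 341, "MAPK_like": 255, "AMPK_like": 124}
    pathways = {
        name: set(rng.choice(universe, size=size, replace=False))
        for name, size in sizes.items()
    }
    lengths = {g: int(np.exp(rng.normal(8.0, 0.8))) for g in universe}
    return pathways, lengths


# ---------------------------------------------------------------------------
# Permutation enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    pathway: str
    observed_overlap: int
    perm_p: float
    n_perm: int
    hypergeom_p: float | None = None
    significant_5pct: bool | None = None
    bh_q: float | None = None


def _length_bins(genes: list[str], gene_lengths: dict[str, int], n_bins: int = 5) -> np.ndarray:
    lengths = np.array([gene_lengths.get(g, 0) for g in genes], dtype=float)
    edges = np.quantile(lengths, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, lengths, side="right")


def permutation_enrichment(
    query_genes: set[str],
    pool: set[str],
    pathways: dict[str, set[str]],
    draw_size: int | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    length_adjusted: bool = False,
    gene_lengths: dict[str, int] | None = None,
    bh_adjust: bool = False,
) -> list[EnrichmentResult]:
    """Permutation test of pathway overlap for a query gene set.

    Null draws of ``draw_size`` genes (default: |query|) are sampled without
    replacement from ``pool``; perm_p uses the +1 correction
    (1 + #{overlap >= observed}) / (n_perm + 1).  With ``length_adjusted``
    the null preserves the query's gene-length quintile composition
    (stratified resampling within pool length bins).  The exact
    hypergeometric upper tail is reported alongside for the unadjusted test.
    """
    pool_list = sorted(pool)
    if draw_size is None:
        draw_size = len(query_genes)
    if draw_size > len(pool_list):
        raise InvalidParameterError("draw_size exceeds the gene pool")
    if not query_genes <= pool:
        raise InvalidParameterError("query genes must be a subset of the pool")
    if length_adjusted and gene_lengths is None:
        raise InvalidParameterError("length adjustment requires gene_lengths")

    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool_list)
    N = len(pool_arr)

    # n_perm x draw_size index matrix of null draws
    if not length_adjusted:
        keys = rng.random((n_perm, N))
        draws = np.argpartition(keys, draw_size - 1, axis=1)[:, :draw_size]
    else:
        pool_bins = _length_bins(pool_list, gene_lengths)
        query_list = sorted(query_genes)
        # classify query genes with the pool's bin edges for consistency
        lengths = np.array([gene_lengths.get(g, 0) for g in pool_list], dtype=float)
        edges = np.quantile(lengths, np.linspace(0, 1, 6)[1:-1])
        qlen = np.array([gene_lengths.get(g, 0) for g in query_list], dtype=float)
        qbins = np.searchsorted(edges, qlen, side="right")
        # per-bin draw counts follow the query's composition, scaled to draw_size
        bin_counts = np.bincount(qbins, minlength=5).astype(float)
        bin_counts = np.round(bin_counts / bin_counts.sum() * draw_size).astype(int)
        while bin_counts.sum() > draw_size:
            bin_counts[np.argmax(bin_counts)] -= 1
        while bin_counts.sum() < draw_size:
            bin_counts[np.argmax(bin_counts)] += 1
        columns = []
        for b in range(5):
            members = np.flatnonzero(pool_bins == b)
            take = min(bin_counts[b], len(members))
            if take == 0:
                continue
            keys = rng.random((n_perm, len(members)))
            idx = np.argpartition(keys, take - 1, axis=1)[:, :take]
            columns.append(members[idx])
        draws = np.concatenate(columns, axis=1)

    results = []
    for name, genes in pathways.items():
        member = np.isin(pool_arr, sorted(genes))
        observed = len(query_genes & genes)
        null_overlaps = member[draws].sum(axis=1)
        perm_p = (1 + int((null_overlaps >= observed).sum())) / (n_perm + 1)
        K = int(member.sum())
        hyper = (
            float(stats.hypergeom.sf(observed - 1, N, K, draw_size))
            if not length_adjusted
            else None
        )
        results.append(
            EnrichmentResult(
                pathway=name,
                observed_overlap=observed,
                perm_p=float(perm_p),
                n_perm=n_perm,
                hypergeom_p=hyper,
                significant_5pct=perm_p < 0.05,
            )
        )
    if bh_adjust and results:
        qs = multipletests([r.perm_p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.bh_q = float(q)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "observed_overlap": [r.observed_overlap for r in results],
            "perm_p": [r.perm_p for r in results],
            "hypergeom_p": [r.hypergeom_p for r in results],
            "significant_5pct": [r.significant_5pct for r in results],
            "bh_q": [r.bh_q for r in results],
        }
    )
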