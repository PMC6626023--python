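"""96-channel mutation spectra and single-base-substitution signature refitting.

A single-base substitution is summarised by its pyrimidine-centred substitution
class (C>A, C>G, C>T, T>A, T>C, T>G) together with the bases immediately 5' and
3' of the mutated pyrimidine, giving 6 x 4 x 4 = 96 channels.  Variants reported
on the purine strand are reverse-complemented into this convention.  A signature
is a probability distribution over the 96 channels; an observed spectrum is
decomposed as a non-negative mixture of catalog signatures by maximising the
multinomial likelihood of the channel counts, and the signature subset is chosen
by exhaustive search under the Bayesian information criterion with cosine
similarity as tie-break.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .errors import BudgetError, ConfigurationError, InvalidInputError

# ---------------------------------------------------------------------------
# Channel conventions
# ---------------------------------------------------------------------------

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Channel order: substitution class (above order), then 5' base A,C,G,T,
#: then 3' base A,C,G,T.  Index = class*16 + 5'*4 + 3'.
CHANNEL_LABELS = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_CLASSES
    for f5 in BASES
    for f3 in BASES
)

#: The 32 pyrimidine-centred trinucleotide contexts, in channel-compatible
#: order (center C contexts first, then center T), used for exome adjustment.
PYRIMIDINE_CONTEXTS = tuple(
    f"{f5}{c}{f3}" for c in "CT" for f5 in BASES for f3 in BASES
)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_index(ref: str, alt: str, context: str) -> int:
    """Map a substitution and its trinucleotide context to a channel 0-95.

    ``context`` is the 3-mer centred on the mutated base; its middle base must
    equal ``ref``.  Purine-reference variants are folded onto the opposite
    strand.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise InvalidInputError(f"context {context!r} does not centre on ref {ref!r}")
    if ref == alt:
        raise InvalidInputError(f"ref equals alt ({ref!r})")
    if any(b not in BASES for b in context + alt):
        raise InvalidInputError(f"non-ACGT base in {context!r}>{alt!r}")
    if ref in "AG":  # purine reference: flip strand
        context = reverse_complement(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    sub = SUBSTITUTION_CLASSES.index(f"{ref}>{alt}")
    return sub * 16 + BASES.index(context[0]) * 4 + BASES.index(context[2])


def channel_parts(index: int) -> tuple[str, str, str]:
    """Inverse of :func:`channel_index`: (substitution class, 5' base, 3' base)."""
    sub, rest = divmod(index, 16)
    f5, f3 = divmod(rest, 4)
    return SUBSTITUTION_CLASSES[sub], BASES[f5], BASES[f3]


def channel_context(index: int) -> tuple[str, str, str]:
    """Return (ref, alt, context 3-mer) for a channel, pyrimidine-centred."""
    sub, f5, f3 = channel_parts(index)
    ref, alt = sub.split(">")
    return ref, alt, f5 + ref + f3


def context_index_of_channel(index: int) -> int:
    """Index of a channel's trinucleotide context within PYRIMIDINE_CONTEXTS."""
    _, _, ctx = channel_context(index)
    return PYRIMIDINE_CONTEXTS.index(ctx)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------


@dataclass
class Spectrum96:
    """Counts over the 96 substitution channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise InvalidInputError("a spectrum has exactly 96 channels")
        if (self.counts < 0).any():
            raise InvalidInputError("channel counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise InvalidInputError("zero-total spectrum")
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": CHANNEL_LABELS, "count": self.counts})


def build_mutation_spectrum(variants) -> Spectrum96:
    """Tally (ref, alt, context) triples into a 96-channel spectrum.

    Accepts any iterable of ``(ref, alt, context)``; purine-reference entries
    are strand-folded.
    """
    counts = np.zeros(96, dtype=np.int64)
    for ref, alt, context in variants:
        counts[channel_index(ref, alt, context)] += 1
    return Spectrum96(counts)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


@dataclass
class SignatureCatalog:
    """Named reference signatures, each a probability vector over 96 channels."""

    signatures: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, vec in self.signatures.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (96,):
                raise InvalidInputError(f"signature {name}: expected 96 channels")
            if (v < 0).any() or not math.isclose(v.sum(), 1.0, abs_tol=1e-8):
                raise InvalidInputError(f"signature {name}: not a probability vector")
            clean[name] = v
        self.signatures = clean

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    def matrix(self, subset: list[str] | None = None) -> np.ndarray:
        """96 x k matrix of the requested signatures (catalog order by default)."""
        names = self.names if subset is None else list(subset)
        missing = [n for n in names if n not in self.signatures]
        if missing:
            raise InvalidInputError(f"signatures not in catalog: {missing}")
        return np.column_stack([self.signatures[n] for n in names])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.signatures)
        df.insert(0, "channel", CHANNEL_LABELS)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> SignatureCatalog:
    """Load a 96 x S signature table (first column = channel labels).

    Rows may arrive in any order as long as the labels use the
    ``5'[REF>ALT]3'`` convention; they are re-indexed to the package's fixed
    channel order.
    """
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    order = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}
    try:
        idx = df[label_col].map(order).to_numpy()
    except KeyError as exc:  # pragma: no cover - defensive
        raise InvalidInputError(f"unrecognised channel label: {exc}") from exc
    if np.isnan(idx.astype(float)).any() or len(df) != 96:
        raise InvalidInputError("catalog must contain exactly the 96 channel labels")
    sigs: dict[str, np.ndarray] = {}
    for col in df.columns[1:]:
        vec = np.zeros(96)
        vec[idx.astype(int)] = df[col].to_numpy(dtype=float)
        sigs[col] = vec / vec.sum()
    return SignatureCatalog(sigs)


def synthetic_catalog(n_decoys: int = 2, seed: int = 20190712) -> SignatureCatalog:
    """Deterministic synthetic signature catalog for tests and simulation.

    Not COSMIC data.  Three named processes mimic the qualitative shapes that
    dominate ageing tissues, plus ``n_decoys`` random flat-ish decoys:

    * ``clocklike_deamination`` - CpG-focused C>T peaks (5-methylcytosine
      deamination; the shape class of SBS1).
    * ``flat_aging`` - broad, featureless distribution across all channels
      (the shape class of SBS5).
    * ``oxidative_damage`` - C>A-dominated spectrum (reactive-oxygen damage;
      the shape class of SBS18).
    """
    rng = np.random.default_rng(seed)
    sigs: dict[str, np.ndarray] = {}

    clock = np.full(96, 1e-4)
    for i in range(96):
        sub, _, f3 = channel_parts(i)
        if sub == "C>T" and f3 == "G":  # NpCpG deamination
            clock[i] = 0.22
        elif sub == "C>T":
            clock[i] = 0.004
    sigs["clocklike_deamination"] = clock / clock.sum()

    flat = 1.0 + 0.35 * rng.random(96)
    sigs["flat_aging"] = flat / flat.sum()

    oxo = np.full(96, 5e-4)
    for i in range(96):
        sub, f5, _ = channel_parts(i)
        if sub == "C>A":
            oxo[i] = 0.09 if f5 in "AG" else 0.035
    sigs["oxidative_damage"] = oxo / oxo.sum()

    for d in range(n_decoys):
        v = rng.dirichlet(np.full(96, 0.6))
        sigs[f"decoy_{d + 1}"] = v

    return SignatureCatalog(sigs)


def exome_adjust_catalog(
    catalog: SignatureCatalog,
    genome_freqs: dict[str, float],
    exome_freqs: dict[str, float],
) -> SignatureCatalog:
    """Rescale genome-derived signatures to exome trinucleotide composition.

    Each channel is multiplied by (exome frequency / genome frequency) of its
    pyrimidine-centred context, then the vector is renormalised to sum 1.
    """
    ratios = np.empty(96)
    for i in range(96):
        _, _, ctx = channel_context(i)
        if ctx not in genome_freqs or ctx not in exome_freqs:
            raise ConfigurationError(f"missing trinucleotide frequency for {ctx}")
        g, e = genome_freqs[ctx], exome_freqs[ctx]
        if g <= 0 or e <= 0:
            raise ConfigurationError(f"non-positive frequency for context {ctx}")
        ratios[i] = e / g
    adjusted = {}
    for name, vec in catalog.signatures.items():
        v = vec * ratios
        adjusted[name] = v / v.sum()
    return SignatureCatalog(adjusted)


# ---------------------------------------------------------------------------
# Exposure fitting and model selection
# ---------------------------------------------------------------------------


@dataclass
class DecompositionResult:
    selected: list[str]
    exposures: np.ndarray
    cosine: float
    bic: float
    loglik: float

    def exposure_map(self) -> dict[str, float]:
        return dict(zip(self.selected, map(float, self.exposures)))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


_EPS = 1e-12


def _multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    # constant log-multinomial-coefficient omitted: it cancels in BIC comparisons
    return float(counts @ np.log(np.maximum(probs, _EPS)))


def fit_exposures(
    spectrum: Spectrum96,
    subset: list[str],
    catalog: SignatureCatalog,
    method: str = "mle",
) -> DecompositionResult:
    """Fit non-negative, sum-to-one exposures of ``subset`` to a spectrum.

    ``method='mle'`` maximises the multinomial log-likelihood of the channel
    counts under the mixture (SLSQP on the simplex); ``method='nnls'`` runs
    non-negative least squares on channel fractions and renormalises, as a
    cross-check mode.
    """
    if not subset:
        raise InvalidInputError("subset of signatures must be nonempty")
    if spectrum.total == 0:
        raise InvalidInputError("zero-total spectrum")
    M = catalog.matrix(subset)  # 96 x k
    counts = spectrum.counts.astype(float)
    k = M.shape[1]

    if method == "nnls":
        target = spectrum.fractions()
        e, _ = nnls(M, target)
        if e.sum() == 0:
            e = np.full(k, 1.0 / k)
        e = e / e.sum()
    elif method == "mle":
        def neg_ll(e: np.ndarray) -> float:
            return -_multinomial_loglik(counts, M @ e)

        def grad(e: np.ndarray) -> np.ndarray:
            p = np.maximum(M @ e, _EPS)
            return -(M.T @ (counts / p))

        x0 = np.full(k, 1.0 / k)
        res = minimize(
            neg_ll,
            x0,
            jac=grad,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0}],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        e = np.clip(res.x, 0.0, None)
        e = e / e.sum()
    else:
        raise InvalidInputError(f"unknown fitting method {method!r}")

    recon = M @ e
    ll = _multinomial_loglik(counts, recon)
    bic = k * math.log(spectrum.total) - 2.0 * ll
    cos = cosine_similarity(recon, spectrum.fractions())
    return DecompositionResult(list(subset), e, cos, bic, ll)


def select_signature_model(
    spectrum: Spectrum96,
    catalog: SignatureCatalog,
    candidates: list[str] | None = None,
    max_k: int = 5,
    subset_budget: int = 20000,
    method: str = "mle",
) -> DecompositionResult:
    """Exhaustively search signature subsets of size <= max_k; pick minimal BIC.

    Ties (within 1e-9 of the best BIC) are broken by higher cosine similarity,
    then by smaller subset size.
    """
    if candidates is None:
        candidates = catalog.names
    if not candidates:
        raise InvalidInputError("candidate list must be nonempty")
    if max_k < 1:
        raise InvalidInputError("max_k must be >= 1")
    max_k = min(max_k, len(candidates))
    n_subsets = sum(math.comb(len(candidates), k) for k in range(1, max_k + 1))
    if n_subsets > subset_budget:
        raise BudgetError(
            f"{n_subsets} candidate subsets exceed the budget of {subset_budget}; "
            "shorten the candidate list or lower max_k"
        )

    best: DecompositionResult | None = None
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(candidates, k):
            fit = fit_exposures(spectrum, list(subset), catalog, method=method)
            if best is None:
                best = fit
                continue
            if fit.bic < best.bic - 1e-9:
                best = fit
            elif abs(fit.bic - best.bic) <= 1e-9:
                if (fit.cosine, -len(fit.selected)) > (best.cosine, -len(best.selected)):
                    best = fit
    assert best is not None
    return best
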