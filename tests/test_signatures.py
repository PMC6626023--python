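"""Spectrum building, exome adjustment, exposure fitting and model selection."""

import numpy as np
import pytest

from somamosaic.errors import BudgetError, InvalidInputError
from somamosaic.signatures import (
    CHANNEL_LABELS,
    PYRIMIDINE_CONTEXTS,
    Spectrum96,
    build_mutation_spectrum,
    channel_context,
    channel_index,
    cosine_similarity,
    exome_adjust_catalog,
    fit_exposures,
    read_catalog_tsv,
    select_signature_model,
    synthetic_catalog,
)


class TestChannels:
    def test_one_hot_pyrimidine(self):
        spec = build_mutation_spectrum([("C", "A", "ACA")])
        assert spec.total == 1
        assert spec.counts[channel_index("C", "A", "ACA")] == 1

    def test_purine_strand_folds_to_same_channel(self):
        # G>T in TGT is the reverse complement of C>A in ACA
        assert channel_index("G", "T", "TGT") == channel_index("C", "A", "ACA")

    def test_channel_roundtrip(self):
        for i in range(96):
            ref, alt, ctx = channel_context(i)
            assert channel_index(ref, alt, ctx) == i
        assert len(set(CHANNEL_LABELS)) == 96

    @pytest.mark.parametrize("bad", [("C", "C", "ACA"), ("C", "N", "ACA"), ("C", "T", "AGA")])
    def test_invalid_variants(self, bad):
        with pytest.raises(InvalidInputError):
            channel_index(*bad)

    def test_sampling_consistency(self, catalog, rng):
        sig = catalog.signatures["clocklike_deamination"]
        draws = rng.choice(96, size=1000, p=sig)
        spec = build_mutation_spectrum(channel_context(int(c)) for c in draws)
        assert cosine_similarity(spec.fractions(), sig) > 0.95


class TestCatalog:
    def test_synthetic_catalog_is_valid_and_deterministic(self, catalog):
        for vec in catalog.signatures.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-8)
            assert (vec >= 0).all()
        again = synthetic_catalog()
        assert all(np.array_equal(catalog.signatures[n], again.signatures[n])
                   for n in catalog.names)

    def test_tsv_roundtrip(self, catalog, tmp_path):
        path = tmp_path / "cat.tsv"
        catalog.write_tsv(path)
        loaded = read_catalog_tsv(path)
        for name in catalog.names:
            assert np.allclose(loaded.signatures[name], catalog.signatures[name], atol=1e-12)


class TestExomeAdjustment:
    def test_identity_adjustment(self, catalog):
        freqs = {ctx: 1.0 / 32 for ctx in PYRIMIDINE_CONTEXTS}
        adj = exome_adjust_catalog(catalog, freqs, freqs)
        for n in catalog.names:
            assert np.allclose(adj.signatures[n], catalog.signatures[n])

    def test_doubling_a_context_doubles_its_relative_weight(self, catalog):
        genome = {ctx: 1.0 / 32 for ctx in PYRIMIDINE_CONTEXTS}
        exome = dict(genome)
        exome["ACG"] = 2.0 / 32
        adj = exome_adjust_catalog(catalog, genome, exome)
        name = "flat_aging"
        target = [i for i in range(96) if channel_context(i)[2] == "ACG"]
        other = [i for i in range(96) if i not in target]
        before = catalog.signatures[name]
        after = adj.signatures[name]
        ratio_target = after[target] / before[target]
        ratio_other = after[other] / before[other]
        assert np.allclose(ratio_target / ratio_other.mean(), 2.0)
        assert after.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_frequency_rejected(self, catalog):
        genome = {ctx: 1.0 / 32 for ctx in PYRIMIDINE_CONTEXTS}
        bad = dict(genome)
        bad["ACA"] = 0.0
        with pytest.raises(Exception, match="frequency"):
            exome_adjust_catalog(catalog, bad, genome)


class TestFitExposures:
    def test_pure_source(self, catalog):
        sig = catalog.signatures["oxidative_damage"]
        counts = np.round(sig * 100000).astype(int)
        res = fit_exposures(Spectrum96(counts), ["oxidative_damage", "flat_aging"], catalog)
        assert res.exposure_map()["oxidative_damage"] == pytest.approx(1.0, abs=0.01)
        assert res.cosine > 0.999

    def test_mixture_recovery(self, catalog, rng):
        mix = 0.7 * catalog.signatures["flat_aging"] + 0.3 * catalog.signatures[
            "clocklike_deamination"]
        counts = rng.multinomial(10000, mix)
        res = fit_exposures(
            Spectrum96(counts), ["flat_aging", "clocklike_deamination"], catalog)
        e = res.exposure_map()
        assert e["flat_aging"] == pytest.approx(0.7, abs=0.05)
        assert e["clocklike_deamination"] == pytest.approx(0.3, abs=0.05)

    def test_optimum_beats_uniform(self, catalog, rng):
        mix = 0.5 * catalog.signatures["flat_aging"] + 0.5 * catalog.signatures[
            "oxidative_damage"]
        counts = rng.multinomial(5000, mix)
        spec = Spectrum96(counts)
        subset = ["flat_aging", "clocklike_deamination", "oxidative_damage"]
        res = fit_exposures(spec, subset, catalog)
        M = catalog.matrix(subset)
        uniform = counts @ np.log(np.maximum(M @ np.full(3, 1 / 3), 1e-12))
        assert res.loglik >= uniform

    def test_matches_fine_grid_search(self, catalog, rng):
        """2-signature MLE within 0.005 of a 0.001-step grid optimum."""
        mix = 0.6 * catalog.signatures["flat_aging"] + 0.4 * catalog.signatures[
            "oxidative_damage"]
        counts = rng.multinomial(8000, mix)
        spec = Spectrum96(counts)
        subset = ["flat_aging", "oxidative_damage"]
        res = fit_exposures(spec, subset, catalog)
        M = catalog.matrix(subset)
        grid = np.arange(0.0, 1.0001, 0.001)
        lls = counts @ np.log(np.maximum(
            np.outer(M[:, 0], grid) + np.outer(M[:, 1], 1 - grid), 1e-12))
        best = grid[np.argmax(lls)]
        assert res.exposure_map()["flat_aging"] == pytest.approx(best, abs=0.005)

    def test_reconstruction_is_probability_vector(self, catalog, rng):
        counts = rng.multinomial(2000, catalog.signatures["flat_aging"])
        res = fit_exposures(Spectrum96(counts), catalog.names, catalog)
        recon = catalog.matrix(res.selected) @ res.exposures
        assert recon.sum() == pytest.approx(1.0, abs=1e-8)
        assert (recon >= -1e-12).all()
        assert res.exposures.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nnls_mode_agrees_on_easy_mixture(self, catalog, rng):
        mix = 0.7 * catalog.signatures["flat_aging"] + 0.3 * catalog.signatures[
            "clocklike_deamination"]
        counts = rng.multinomial(20000, mix)
        spec = Spectrum96(counts)
        subset = ["flat_aging", "clocklike_deamination"]
        a = fit_exposures(spec, subset, catalog, method="mle")
        b = fit_exposures(spec, subset, catalog, method="nnls")
        assert np.allclose(a.exposures, b.exposures, atol=0.05)

    def test_zero_spectrum_rejected(self, catalog):
        with pytest.raises(InvalidInputError):
            fit_exposures(Spectrum96(np.zeros(96)), ["flat_aging"], catalog)


class TestModelSelection:
    def test_parsimony_on_pure_source(self, catalog):
        counts = np.round(catalog.signatures["clocklike_deamination"] * 20000).astype(int)
        best = select_signature_model(
            Spectrum96(counts), catalog,
            candidates=["clocklike_deamination", "flat_aging"], max_k=2)
        assert best.selected == ["clocklike_deamination"]

    def test_two_source_mixture_selected(self, catalog, rng):
        mix = 0.7 * catalog.signatures["flat_aging"] + 0.3 * catalog.signatures[
            "clocklike_deamination"]
        counts = rng.multinomial(10000, mix)
        best = select_signature_model(Spectrum96(counts), catalog, max_k=3)
        assert sorted(best.selected) == ["clocklike_deamination", "flat_aging"]

    def test_true_superset_never_beaten_by_strict_subset(self, catalog, rng):
        """At large n, BIC of the generating pair is below either singleton."""
        mix = 0.5 * catalog.signatures["flat_aging"] + 0.5 * catalog.signatures[
            "oxidative_damage"]
        counts = rng.multinomial(50000, mix)
        spec = Spectrum96(counts)
        pair = fit_exposures(spec, ["flat_aging", "oxidative_damage"], catalog)
        for single in (["flat_aging"], ["oxidative_damage"]):
            assert pair.bic <= fit_exposures(spec, single, catalog).bic

    def test_budget_guard(self, catalog):
        counts = np.round(catalog.signatures["flat_aging"] * 1000).astype(int)
        with pytest.raises(BudgetError):
            select_signature_model(Spectrum96(counts), catalog, max_k=5, subset_budget=3)
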