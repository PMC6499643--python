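"""Spectrum building, signature refitting, attribution and clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from cancereffects.catalog import CHANNEL_LABELS, SIGNATURE_NAMES
from cancereffects.channels import CHANNEL_INDEX, CHANNELS, ChannelKey
from cancereffects.signatures import (
    SignatureFit,
    TrinucSpectrum,
    apobec_flag,
    attribute_signatures,
    build_spectrum,
    cluster_fits,
    deconvolve,
    mean_context_profile,
    median_attribution,
    pooled_spectrum_profile,
)
from cancereffects.variant_io import VariantRecord


def _fit(sample, weights_dict, eligible=True, total=100):
    w = pd.Series(0.0, index=list(SIGNATURE_NAMES))
    for k, v in weights_dict.items():
        w[k] = v
    return SignatureFit(sample, w if eligible else None, 0.0, eligible, total)


def _spectrum_from(sigs, weights_dict, n, rng):
    w = np.zeros(len(SIGNATURE_NAMES))
    for k, v in weights_dict.items():
        w[SIGNATURE_NAMES.index(k)] = v
    q = w @ sigs.values
    return TrinucSpectrum(rng.multinomial(n, q / q.sum()), sample_id="sim")


class TestBuildSpectrum:
    def test_single_mutations_land_in_their_channels(self):
        recs = [
            VariantRecord("S", "c", 10, "C", "T", trinuc_ref="ACG"),
            VariantRecord("S", "c", 20, "G", "A", trinuc_ref="TGC"),  # folds to GCA>T
        ]
        spec = build_spectrum(recs)
        assert spec.total == 2
        assert spec.counts[CHANNEL_INDEX[ChannelKey("ACG", "T")]] == 1
        assert spec.counts[CHANNEL_INDEX[ChannelKey("GCA", "T")]] == 1

    def test_strand_flipped_copy_gives_identical_spectrum(self, small_cohort):
        from cancereffects.channels import reverse_complement

        recs = small_cohort.records[:300]
        flipped = [
            VariantRecord(r.sample_id, r.chrom, r.pos,
                          reverse_complement(r.ref), reverse_complement(r.alt),
                          trinuc_ref=reverse_complement(r.trinuc_ref))
            for r in recs
        ]
        assert (build_spectrum(recs).counts == build_spectrum(flipped).counts).all()


class TestDeconvolve:
    def test_pure_signature_recovered(self, sigs, rng):
        spec = _spectrum_from(sigs, {"Signature.2": 1.0}, 1000, rng)
        fit = deconvolve(spec, sigs)
        assert fit.eligible
        assert fit.weight("Signature.2") >= 0.95
        others = fit.weights.drop("Signature.2")
        assert (others == 0).all()

    def test_eligibility_is_strictly_greater_than_threshold(self, sigs, rng):
        spec = _spectrum_from(sigs, {"Signature.1": 1.0}, 50, rng)
        fit = deconvolve(spec, sigs, min_mutations=50)
        assert not fit.eligible and fit.weights is None
        fit51 = deconvolve(_spectrum_from(sigs, {"Signature.1": 1.0}, 51, rng), sigs)
        assert fit51.eligible

    def test_mixture_recovered_within_tolerance(self, sigs, rng):
        truth = {"Signature.1": 0.7, "Signature.13": 0.3}
        spec = _spectrum_from(sigs, truth, 5000, rng)
        fit = deconvolve(spec, sigs)
        for name, w in truth.items():
            assert abs(fit.weight(name) - w) <= 0.05

    def test_small_weights_zeroed_exactly(self, sigs, rng):
        spec = _spectrum_from(
            sigs, {"Signature.1": 0.5, "Signature.4": 0.47, "Signature.16": 0.03},
            5000, rng,
        )
        fit = deconvolve(spec, sigs, weight_cutoff=0.06)
        nonzero = fit.weights[fit.weights > 0]
        assert (nonzero >= 0.06).all()
        assert fit.weights.sum() <= 1 + 1e-9

    def test_degenerate_single_channel_spectrum_still_fits(self, sigs):
        counts = np.zeros(96, dtype=int)
        counts[0] = 200
        fit = deconvolve(TrinucSpectrum(counts, "deg"), sigs)
        assert fit.eligible and np.isfinite(fit.residual_sse)

    def test_fit_improves_on_empty_model(self, sigs, rng):
        spec = _spectrum_from(sigs, {"Signature.2": 0.6, "Signature.1": 0.4},
                              2000, rng)
        fit = deconvolve(spec, sigs)
        sse_empty = float(spec.fractions @ spec.fractions)
        assert fit.residual_sse < sse_empty


class TestApobecFlag:
    @pytest.mark.parametrize(
        "weights,expected",
        [
            ({"Signature.2": 0.30, "Signature.13": 0.19}, True),
            ({"Signature.13": 0.07}, True),
            ({"Signature.1": 0.9}, False),
        ],
    )
    def test_flag(self, weights, expected):
        assert apobec_flag(_fit("S", weights)) is expected

    def test_ineligible_fit_raises(self):
        with pytest.raises(ValueError):
            apobec_flag(_fit("S", {}, eligible=False))


class TestContextProfile:
    def test_single_tumor_pure_signature_equals_its_row(self, sigs):
        c = mean_context_profile([_fit("S", {"Signature.1": 1.0})], sigs)
        np.testing.assert_allclose(c, sigs.loc["Signature.1"].values, atol=1e-12)

    def test_identical_tumors_idempotent_and_normalized(self, sigs):
        fits = [_fit("A", {"Signature.2": 0.5, "Signature.4": 0.3}),
                _fit("B", {"Signature.2": 0.5, "Signature.4": 0.3})]
        c = mean_context_profile(fits, sigs)
        c1 = mean_context_profile(fits[:1], sigs)
        np.testing.assert_allclose(c, c1, atol=1e-12)
        assert c.sum() == pytest.approx(1.0, abs=1e-9)

    def test_cohort_mean_matches_planted_mixtures(self, sigs, rng):
        mixes = [{"Signature.1": 0.8, "Signature.2": 0.2},
                 {"Signature.13": 0.6, "Signature.4": 0.4},
                 {"Signature.16": 1.0}]
        fits = [_fit(f"S{i}", m) for i, m in enumerate(mixes)]
        c = mean_context_profile(fits, sigs)
        expected = np.zeros(96)
        for m in mixes:
            w = np.zeros(len(SIGNATURE_NAMES))
            for k, v in m.items():
                w[SIGNATURE_NAMES.index(k)] = v
            recon = w @ sigs.values
            expected += recon / recon.sum()
        expected /= expected.sum()
        assert np.abs(c - expected).sum() <= 0.01

    def test_no_eligible_fits_instructs_fallback(self, sigs):
        with pytest.raises(ValueError, match="pooled"):
            mean_context_profile([_fit("S", {}, eligible=False)], sigs)
        counts = np.zeros(96, dtype=int)
        counts[3] = 7
        prof = pooled_spectrum_profile([TrinucSpectrum(counts)])
        assert prof[3] == pytest.approx(1.0)


class TestAttribution:
    def test_single_signature_gets_everything(self, sigs):
        alpha = attribute_signatures(_fit("S", {"Signature.2": 1.0}), sigs,
                                     ChannelKey("TCA", "T"))
        assert alpha[SIGNATURE_NAMES.index("Signature.2")] == pytest.approx(1.0)

    def test_symmetric_mixture_splits_evenly(self, sigs):
        # two identical-probability signatures with equal weights
        custom = sigs.copy()
        custom.loc["Signature.5"] = custom.loc["Signature.6"].values
        alpha = attribute_signatures(
            _fit("S", {"Signature.5": 0.4, "Signature.6": 0.4}), custom,
            CHANNELS[10],
        )
        i5 = SIGNATURE_NAMES.index("Signature.5")
        i6 = SIGNATURE_NAMES.index("Signature.6")
        assert alpha[i5] == pytest.approx(0.5) and alpha[i6] == pytest.approx(0.5)

    def test_weight_probability_balance(self, sigs):
        """Weights (0.75, 0.25) against channel probabilities (0.02, 0.06)
        give equal attribution: 0.75*0.02 == 0.25*0.06."""
        custom = sigs.copy()
        for name, p in (("Signature.5", 0.02), ("Signature.6", 0.06)):
            row = np.full(96, (1.0 - p) / 95)
            row[0] = p
            custom.loc[name] = row
        alpha = attribute_signatures(
            _fit("S", {"Signature.5": 0.75, "Signature.6": 0.25}), custom,
            CHANNELS[0],
        )
        i5 = SIGNATURE_NAMES.index("Signature.5")
        i6 = SIGNATURE_NAMES.index("Signature.6")
        assert alpha[i5] == pytest.approx(0.5, abs=1e-12)
        assert alpha[i6] == pytest.approx(0.5, abs=1e-12)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_mass_channel_is_na(self, sigs):
        custom = sigs.copy()
        row = np.full(96, 1 / 95.0)
        row[0] = 0.0
        custom.loc["Signature.5"] = row
        alpha = attribute_signatures(_fit("S", {"Signature.5": 1.0}), custom,
                                     CHANNELS[0])
        assert alpha is None

    def test_median_attribution(self):
        a1 = np.array([0.2, 0.8]); a2 = np.array([0.5, 0.5]); a3 = np.array([0.9, 0.1])
        med = median_attribution([np.pad(a, (0, 28)) for a in (a1, a2, a3)])
        assert med[0] == pytest.approx(0.5) and med.sum() == pytest.approx(1.0)
        single = median_attribution([np.pad(a1, (0, 28))])
        np.testing.assert_allclose(single[:2], a1)


class TestClusterFits:
    def test_identical_rows_merge_at_height_zero(self):
        fits = [_fit("A", {"Signature.1": 0.5}), _fit("B", {"Signature.1": 0.5}),
                _fit("C", {"Signature.4": 0.9})]
        Z, order, newick = cluster_fits(fits)
        assert Z[0, 2] == pytest.approx(0.0)
        assert newick.count(",") == 2 and newick.endswith(";")

    def test_three_point_instance_matches_brute_force(self):
        """Points on a line at 0, 1, 3: complete linkage must first merge the
        pair at distance 1 and finish at the full diameter 3."""
        fits = [
            _fit("A", {"Signature.1": 0.0}),
            _fit("B", {"Signature.1": 1.0}),
            _fit("C", {"Signature.1": 3.0}),
        ]
        # brute-force agglomeration: merge {A,B} at 1; then complete-linkage
        # distance to C is max(3, 2) = 3
        Z, order, _ = cluster_fits(fits)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(3.0)

    def test_input_order_invariance(self):
        base = [("A", 0.1), ("B", 0.6), ("C", 0.25), ("D", 0.9)]
        fits = [_fit(s, {"Signature.2": w}) for s, w in base]
        Z1, order1, n1 = cluster_fits(fits)
        Z2, order2, n2 = cluster_fits(fits[::-1])
        np.testing.assert_allclose(Z1, Z2)
        assert order1 == order2 and n1 == n2

    def test_matches_scipy_reference_on_random_weights(self, rng):
        fits = [_fit(f"S{i}", {"Signature.1": float(rng.random()),
                               "Signature.2": float(rng.random()) * 0.4})
                for i in range(8)]
        Z, _, _ = cluster_fits(fits)
        X = np.vstack([f.weights.values for f in fits])
        ref = sch.linkage(X, method="complete", metric="euclidean")
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(ref[:, 2]), atol=1e-12)

    def test_fewer_than_two_tumors_raises(self):
        with pytest.raises(ValueError):
            cluster_fits([_fit("A", {"Signature.1": 1.0})])


def test_catalog_shape_and_normalization(sigs):
    assert sigs.shape == (30, 96)
    assert list(sigs.columns) == list(CHANNEL_LABELS)
    np.testing.assert_allclose(sigs.sum(axis=1).values, 1.0, atol=1e-9)
    assert (sigs.values >= 0).all()
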