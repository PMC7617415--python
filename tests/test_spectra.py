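"""96-channel spectra: collapse, normalisation, causal proportions, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rasco.braf_channels import (
    CLASS1_CHANNELS,
    CLASS2_3_CHANNELS,
    causal_channel_audit,
    channel_for_substitution,
)
from rasco.spectra import (
    CHANNELS,
    CHANNEL_INDEX,
    CausalChannelSet,
    MutationChannel,
    SeparationError,
    build_spectrum,
    causal_channel_proportion,
    collapse_to_pyrimidine,
    fit_presence_logistic,
    _revcomp,
)
from _oracles import irls_logistic

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestCollapse:
    def test_v600e_channel(self):
        assert collapse_to_pyrimidine("GTG", "T", "A").label == "G[T>A]G"

    def test_purine_reference_is_reverse_complemented(self):
        assert collapse_to_pyrimidine("AGC", "G", "A").label == "G[C>T]T"

    def test_malformed_context_rejected(self):
        with pytest.raises(ValueError):
            collapse_to_pyrimidine("GTGA", "T", "A")
        with pytest.raises(ValueError):
            collapse_to_pyrimidine("GAG", "T", "A")  # centre mismatch
        with pytest.raises(ValueError):
            collapse_to_pyrimidine("GTG", "T", "T")

    def test_strand_invariance_on_random_mutations(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            ctx = "".join(rng.choice(list(BASES), 3))
            ref = ctx[1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            fwd = collapse_to_pyrimidine(ctx, ref, alt)
            rev = collapse_to_pyrimidine(_revcomp(ctx), COMP[ref], COMP[alt])
            assert fwd == rev

    def test_idempotent_on_pyrimidine_output(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            ctx = "".join(rng.choice(list(BASES), 3))
            ref = ctx[1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            ch = collapse_to_pyrimidine(ctx, ref, alt)
            again = collapse_to_pyrimidine(ch.left + ch.ref + ch.right, ch.ref, ch.alt)
            assert again == ch

    def test_exactly_96_reachable_channels(self):
        seen = set()
        for l in BASES:
            for c in BASES:
                for r in BASES:
                    for alt in BASES:
                        if alt == c:
                            continue
                        seen.add(collapse_to_pyrimidine(l + c + r, c, alt).label)
        assert seen == set(CHANNEL_INDEX)
        assert len(seen) == 96


class TestSpectrum:
    def test_point_mass_catalog(self):
        s = build_spectrum([("GTG", "T", "A")] * 4)
        assert s.weight("G[T>A]G") == 1.0
        assert s.raw_counts.sum() == 4

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        catalog = []
        for _ in range(500):
            ctx = "".join(rng.choice(list(BASES), 3))
            alt = str(rng.choice([b for b in BASES if b != ctx[1]]))
            catalog.append((ctx, ctx[1], alt))
        s = build_spectrum(catalog)
        assert abs(s.channel_weights.sum() - 1.0) < 1e-12

    def test_scale_free(self):
        catalog = [("GTG", "T", "A")] * 3 + [("ACA", "C", "T")] * 7
        s1 = build_spectrum(catalog)
        s2 = build_spectrum(catalog * 2)
        assert np.allclose(s1.channel_weights, s2.channel_weights)
        assert np.array_equal(s2.raw_counts, 2 * s1.raw_counts)

    def test_concatenation_adds_raw_counts(self):
        a = [("GTG", "T", "A")] * 3
        b = [("TCT", "C", "G")] * 5
        assert np.array_equal(
            build_spectrum(a + b).raw_counts,
            build_spectrum(a).raw_counts + build_spectrum(b).raw_counts,
        )

    def test_empty_catalog_flagged(self):
        s = build_spectrum([])
        assert s.empty and s.channel_weights.sum() == 0

    def test_known_vector_recovery(self):
        """A 10,000-draw catalog recovers every channel weight within 0.015."""
        from rasco.simulate import CatalogConfig, generate_catalog, default_channel_vector
        from rasco.spectra import spectra_from_catalog

        vec = default_channel_vector()
        cat = generate_catalog(
            CatalogConfig(n_samples=1, mutations_per_sample=10_000, channel_probs=vec),
            seed=17,
        )
        (s,) = spectra_from_catalog(cat)
        assert np.max(np.abs(s.channel_weights - vec)) < 0.015


class TestCausalProportion:
    def test_class1_weight_passthrough(self):
        # spectrum with weight 0.0069 at the V600E channel
        counts = np.full(96, 1.0)
        counts /= counts.sum()
        i = CHANNEL_INDEX["G[T>A]G"]
        w = np.full(96, (1 - 0.0069) / 95)
        w[i] = 0.0069
        s = build_spectrum([("GTG", "T", "A")])  # placeholder; replace weights
        s = type(s)("x", s.raw_counts, w)
        assert causal_channel_proportion(s, CLASS1_CHANNELS) == pytest.approx(0.0069)

    def test_full_support_set_is_one(self):
        s = build_spectrum([("GTG", "T", "A"), ("TCT", "C", "G"), ("ACA", "C", "T")])
        full = CausalChannelSet("all", frozenset(CHANNELS))
        assert causal_channel_proportion(s, full) == pytest.approx(1.0)

    def test_partition_sums_to_one(self):
        s = build_spectrum([("GTG", "T", "A"), ("TCT", "C", "G"), ("ACA", "C", "T")] * 5)
        half1 = CausalChannelSet("h1", frozenset(CHANNELS[:48]))
        half2 = CausalChannelSet("h2", frozenset(CHANNELS[48:]))
        total = causal_channel_proportion(s, half1) + causal_channel_proportion(s, half2)
        assert total == pytest.approx(1.0)


class TestBrafChannelDerivation:
    def test_class1_set_is_the_v600e_channel(self):
        assert {c.label for c in CLASS1_CHANNELS.channels} == {"G[T>A]G"}

    def test_class2_3_set_has_16_channels(self):
        assert len(CLASS2_3_CHANNELS.channels) == 16

    def test_audit_table_consistency(self):
        audit = causal_channel_audit()
        assert set(audit.loc[audit.braf_class.isin([2, 3]), "channel"]) == {
            c.label for c in CLASS2_3_CHANNELS.channels
        }
        # the derivation reads the substituted base off the embedded CDS
        assert channel_for_substitution(1799, "T", "A") == "G[T>A]G"
        with pytest.raises(ValueError):
            channel_for_substitution(1799, "G", "A")  # reference mismatch


class TestLogistic:
    @staticmethod
    def _simulate(beta_channel, n, rng):
        x = rng.uniform(0, 0.3, n)
        loc = rng.integers(0, 2, n)
        msi = rng.integers(0, 2, n)
        age = rng.normal(68, 10, n)
        male = rng.integers(0, 2, n)
        lp = -1.0 + beta_channel * x + 0.3 * loc - 0.2 * msi + 0.1 * male
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        return pd.DataFrame(
            {
                "presence": y,
                "channel_proportion": x,
                "location_distal": loc,
                "mss": msi,
                "age": age,
                "male": male,
            }
        )

    def test_matches_irls_oracle(self):
        rng = np.random.default_rng(42)
        df = self._simulate(1.5, 50, rng)
        fit = fit_presence_logistic(df)
        X = np.column_stack(
            [
                np.ones(len(df)),
                df[["channel_proportion", "location_distal", "mss", "age", "male"]].to_numpy(),
            ]
        )
        beta, se = irls_logistic(X, df["presence"].to_numpy(float))
        assert np.allclose(fit["estimate"].to_numpy(), beta, atol=1e-6)
        assert np.allclose(fit["std_error"].to_numpy(), se, atol=1e-6)

    def test_null_channel_effect_within_wald_band(self):
        rng = np.random.default_rng(7)
        ok = 0
        for _ in range(50):
            df = self._simulate(0.0, 2000, rng)
            fit = fit_presence_logistic(df).set_index("term")
            est = fit.loc["channel_proportion", "estimate"]
            se = fit.loc["channel_proportion", "std_error"]
            ok += abs(est) < 2 * se
        assert ok >= 45  # >= 90% of replicates

    def test_single_class_outcome_raises(self):
        df = self._simulate(0.0, 100, np.random.default_rng(1))
        df["presence"] = 0
        with pytest.raises(SeparationError):
            fit_presence_logistic(df)

    def test_complete_separation_detected(self):
        n = 100
        rng = np.random.default_rng(2)
        df = self._simulate(0.0, n, rng)
        df["presence"] = (df["channel_proportion"] > 0.15).astype(int)
        with pytest.raises(SeparationError):
            fit_presence_logistic(df, covariates=())
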