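from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirspan.background import (
    CountMatrix,
    WeightingError,
    WeightTable,
    compute_weights,
    count_matches,
    load_bundled_counts,
    load_bundled_weights,
    region_proportions,
    shuffle_background,
    shuffle_sequence,
    signal_to_noise,
)
from mirspan.seedscan import SeedType
from mirspan.seqmodel import GeneRegions, MiRNA, RegionKind

MIR = MiRNA("mir", "UGGCAUGCAAGGAUCCAAGGAA")


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet="ACGUN", min_size=1, max_size=200),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_shuffle_conserves_composition(seq, seed):
    assert Counter(shuffle_sequence(seq, seed)) == Counter(seq)


def test_shuffle_is_deterministic():
    seq = "ACGUACGUGGGUUUACA"
    assert shuffle_sequence(seq, 7) == shuffle_sequence(seq, 7)
    assert shuffle_sequence("AAAA", 123) == "AAAA"


class TestCounting:
    def test_single_planted_site(self):
        gene = GeneRegions("g", {RegionKind.UTR3: "AAGCAUGCCAAA"})
        cm = count_matches([(MIR, gene)])
        assert cm[SeedType.T2t8A1, RegionKind.UTR3] == 1
        assert cm.counts.sum() == 1

    def test_additivity_under_duplication(self):
        rng = np.random.default_rng(11)
        gene = GeneRegions(
            "g", {r: "".join(rng.choice(list("ACGU"), 300)) for r in RegionKind}
        )
        once = count_matches([(MIR, gene)])
        twice = count_matches([(MIR, gene)] * 2)
        assert np.array_equal(twice.counts, 2 * once.counts)

    def test_background_equals_observed_for_degenerate_composition(self):
        # a one-letter sequence is invariant under shuffling
        gene = GeneRegions("g", {RegionKind.CDS: "A" * 100})
        pairs = [(MIR, gene)]
        obs = count_matches(pairs)
        bg = shuffle_background(pairs, n_shuffles=3, rng_seed=0)
        assert np.array_equal(obs.counts, bg.counts)

    def test_background_order_independent(self):
        rng = np.random.default_rng(12)
        genes = [
            GeneRegions(f"g{i}", {RegionKind.UTR3: "".join(rng.choice(list("ACGU"), 200))})
            for i in range(4)
        ]
        pairs = [(MIR, g) for g in genes]
        a = shuffle_background(pairs, n_shuffles=2, rng_seed=5)
        b = shuffle_background(list(reversed(pairs)), n_shuffles=2, rng_seed=5)
        assert np.allclose(a.counts, b.counts)


class TestSNR:
    def test_ratio(self):
        obs, bg = CountMatrix(), CountMatrix()
        obs[SeedType.T2t8A1, RegionKind.UTR3] = 100.0
        bg[SeedType.T2t8A1, RegionKind.UTR3] = 50.0
        bg.counts[bg.counts == 0] = 1.0
        snr = signal_to_noise(obs, bg)
        assert snr[0, 3] == pytest.approx(2.0)

    def test_corpus_against_itself_is_one(self):
        obs = CountMatrix(counts=np.arange(1, 21, dtype=float).reshape(5, 4))
        snr = signal_to_noise(obs, obs)
        assert np.allclose(snr, 1.0)

    def test_zero_background_cell_is_undefined_with_warning(self):
        obs = CountMatrix(counts=np.ones((5, 4)))
        bg = CountMatrix(counts=np.ones((5, 4)))
        bg[SeedType.T2t7, RegionKind.CDS] = 0.0
        with pytest.warns(UserWarning, match="2t7/cds"):
            snr = signal_to_noise(obs, bg)
        assert np.isnan(snr[3, 2]) and np.isfinite(snr).sum() == 19

    def test_published_corpus_reference_cell(self):
        obs, bg = load_bundled_counts()
        snr = signal_to_noise(obs, bg)
        assert snr[0, 3] == pytest.approx(2366 / 1069)


class TestWeights:
    def test_reference_cell_is_exactly_one(self):
        snr = np.full((5, 4), 1.2)
        snr[0, 3] = 2.2
        wt = compute_weights(snr)
        assert wt.weights[0, 3] == 1.0

    def test_known_ratio(self):
        # SNR 1.583 against reference 2.214 gives weight ~0.480
        snr = np.full((5, 4), 1.5)
        snr[0, 3] = 2.214
        snr[1, 3] = 1.583
        wt = compute_weights(snr)
        assert wt.weights[1, 3] == pytest.approx((1.583 - 1) / (2.214 - 1), abs=1e-9)

    def test_snr_one_gives_weight_zero(self):
        snr = np.full((5, 4), 1.0)
        snr[0, 3] = 2.0
        wt = compute_weights(snr)
        assert wt.weights[1, 1] == 0.0

    def test_depleted_cells_clamped_with_warning(self):
        snr = np.full((5, 4), 0.8)
        snr[0, 3] = 2.0
        with pytest.warns(UserWarning, match="clamped"):
            wt = compute_weights(snr)
        assert (wt.weights[snr < 1] == 0.0).all()

    def test_reference_snr_at_most_one_is_fatal(self):
        snr = np.full((5, 4), 1.5)
        snr[0, 3] = 0.9
        with pytest.raises(WeightingError):
            compute_weights(snr)

    def test_auto_reference_picks_largest_cell(self):
        snr = np.full((5, 4), 1.1)
        snr[3, 2] = 3.0
        wt = compute_weights(snr, reference="auto")
        assert wt.reference == (SeedType.T2t7, RegionKind.CDS)
        assert wt.weights[3, 2] == 1.0 and wt.weights.max() == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_invariant_under_common_count_rescaling(self, scale):
        rng = np.random.default_rng(0)
        obs = CountMatrix(counts=rng.uniform(50, 150, (5, 4)))
        bg = CountMatrix(counts=rng.uniform(40, 80, (5, 4)))
        obs.counts[0, 3] = 4 * bg.counts[0, 3]  # healthy reference
        w1 = compute_weights(signal_to_noise(obs, bg)).weights
        obs2 = CountMatrix(counts=obs.counts * scale)
        bg2 = CountMatrix(counts=bg.counts * scale)
        w2 = compute_weights(signal_to_noise(obs2, bg2)).weights
        assert np.allclose(w1, w2)

    def test_round_trip_tsv(self, tmp_path):
        snr = np.full((5, 4), 1.5)
        snr[0, 3] = 2.5
        wt = compute_weights(snr)
        path = tmp_path / "w.tsv"
        wt.to_tsv(path)
        back = WeightTable.from_tsv(path)
        assert np.allclose(back.weights, wt.weights)


class TestProportions:
    def test_rows_sum_to_one(self):
        cm = CountMatrix(counts=np.arange(1, 21, dtype=float).reshape(5, 4))
        props = region_proportions(cm)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_single_nonzero_type(self):
        cm = CountMatrix()
        cm[SeedType.T2t8, RegionKind.CDS] = 7.0
        with pytest.warns(UserWarning):
            props = region_proportions(cm)
        assert props[2, 1] == 1.0

    def test_uniform_counts(self):
        cm = CountMatrix(counts=np.full((5, 4), 3.0))
        assert np.allclose(region_proportions(cm), 0.2)


def test_bundled_weight_table_is_complete():
    wt = load_bundled_weights()
    assert np.isfinite(wt.weights).all()
    assert wt.weights[0, 3] == 1.0  # reference: 2t8A1 in 3'UTRs
    assert wt.weight(SeedType.T2t8, RegionKind.UTR3) == pytest.approx(0.480)
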