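import numpy as np
import pytest

from vafphase.cbs import Segment
from vafphase.concordance import (
    PairContext,
    find_common_blocks,
    overall_discordance,
    pair_features,
    pairwise_discordance,
)
from vafphase.model import ExternalPhaseCall


def calls(block_specs, source="A"):
    """block_specs: {block_id: [(pos, hap), ...]} on chromosome 1."""
    out = []
    for block_id, members in block_specs.items():
        for pos, hap in members:
            out.append(ExternalPhaseCall("1", pos, "A", "G", source, block_id, hap))
    return out


class TestCommonBlocks:
    def test_intersection(self):
        a = calls({"a1": [(100, 0), (200, 0), (300, 1)]})
        b = calls({"b1": [(200, 0), (300, 1), (400, 1)]}, "B")
        (blk,) = find_common_blocks(a, b)
        assert [k[1] for k in blk.keys] == [200, 300]

    def test_single_shared_site_not_emitted(self):
        a = calls({"a1": [(100, 0), (200, 0)]})
        b = calls({"b1": [(200, 0), (400, 1)]}, "B")
        assert find_common_blocks(a, b) == []

    def test_disjoint(self):
        a = calls({"a1": [(100, 0), (200, 0)]})
        b = calls({"b1": [(900, 0), (950, 1)]}, "B")
        assert find_common_blocks(a, b) == []


FOUR = [(100, "A"), (200, "A"), (300, "A"), (400, "A")]


def four_variant_blocks(haps_a=(0, 0, 1, 1), haps_b=(0, 1, 1, 1)):
    a = calls({"a1": [(p, h) for (p, _), h in zip(FOUR, haps_a)]})
    b = calls({"b1": [(p, h) for (p, _), h in zip(FOUR, haps_b)]}, "B")
    return find_common_blocks(a, b)


class TestOverallDiscordance:
    def test_identical_phasings(self):
        blocks = four_variant_blocks((0, 1, 0, 1), (0, 1, 0, 1))
        assert overall_discordance(blocks) == 0.0

    def test_global_flip_invariance(self):
        blocks = four_variant_blocks((0, 1, 0, 1), (1, 0, 1, 0))
        assert overall_discordance(blocks) == 0.0

    def test_hand_enumerated_example(self):
        # anchored on the first shared variant: 3 of 4 concordant
        blocks = four_variant_blocks((0, 0, 1, 1), (0, 1, 1, 1))
        assert overall_discordance(blocks) == pytest.approx(0.25)

    def test_no_common_variants_undefined(self):
        with pytest.raises(ValueError):
            overall_discordance([])


class TestPairwiseDiscordance:
    def test_hand_enumerated_example(self):
        blocks = four_variant_blocks((0, 0, 1, 1), (0, 1, 1, 1))
        table = pairwise_discordance(blocks)
        assert table.n_pairs.sum() == 6
        assert table.n_discordant.sum() == 3  # the 3 pairs involving variant 2
        total = table.n_discordant.sum() / table.n_pairs.sum()
        assert total == pytest.approx(0.5)

    def test_identical_phasings_zero_everywhere(self):
        blocks = four_variant_blocks((0, 1, 0, 1), (0, 1, 0, 1))
        table = pairwise_discordance(blocks)
        assert (table.discordance == 0).all()

    def test_two_variant_agreeing_block(self):
        blocks = four_variant_blocks((0, 1, 0, 1), (1, 0, 1, 0))
        table = pairwise_discordance(blocks)
        assert (table.n_discordant <= table.n_pairs).all()
        assert (table.discordance == 0).all()

    def test_af_binning(self):
        blocks = four_variant_blocks((0, 0, 1, 1), (0, 1, 1, 1))
        af = {("1", p, "A", "G"): f for p, f in
              [(100, 0.0), (200, 0.0005), (300, 0.02), (400, 0.2)]}
        table = pairwise_discordance(blocks, allele_freq=af)
        assert set(table.af_bin) <= {"singleton", "<0.001", "<0.01", "<0.05", ">=0.05"}

    def test_empty_bins_rejected(self):
        blocks = four_variant_blocks()
        with pytest.raises(ValueError):
            pairwise_discordance(blocks, distance_bins=[])


class TestPairFeatures:
    def _context(self):
        k1, k2 = ("1", 1000, "A", "G"), ("1", 11000, "A", "G")
        seg = Segment(chrom="1", start=1000, end=11000, member_indices=np.array([0, 1]),
                      n_variants=2, mean_abs_dvaf=0.3, size_bp=10001, eligible=True)
        ctx = PairContext(depths={k1: 40, k2: 60},
                          segments={k1: seg, k2: seg},
                          dvaf={k1: 0.25, k2: -0.25},
                          allele_freq={k1: 0.01, k2: 0.002})
        return k1, k2, ctx

    def test_feature_values(self):
        k1, k2, ctx = self._context()
        pair = pair_features(k1, k2, "trans", "trans", ctx)
        assert pair.min_read_depth == 40
        assert pair.delta_dvaf == pytest.approx(0.5)
        assert pair.pair_distance_bp == 10000
        assert pair.segment_size_bp == 10001
        assert pair.min_allele_freq == pytest.approx(0.002)
        assert pair.delta_allele_freq == pytest.approx(0.008)
        assert not pair.discordant

    def test_missing_af_unavailable(self):
        k1, k2, ctx = self._context()
        ctx.allele_freq.pop(k2)
        pair = pair_features(k1, k2, "cis", "trans", ctx)
        assert pair.min_allele_freq is None and pair.discordant

    def test_cross_chromosome_rejected(self):
        k1, _, ctx = self._context()
        with pytest.raises(ValueError):
            pair_features(k1, ("2", 500, "A", "G"), "cis", "cis", ctx)


def random_phasings(rng, n_blocks=5, sites_per_block=6):
    a_spec, b_spec = {}, {}
    pos = 0
    for i in range(n_blocks):
        members = []
        for _ in range(sites_per_block):
            pos += int(rng.integers(100, 10_000))
            members.append(pos)
        a_spec[f"a{i}"] = [(p, int(rng.integers(0, 2))) for p in members]
        b_spec[f"b{i}"] = [(p, int(rng.integers(0, 2))) for p in members]
    return calls(a_spec), calls(b_spec, "B")


def flip_blocks(call_list, rng):
    flips = {}
    out = []
    for c in call_list:
        flips.setdefault(c.block_id, bool(rng.integers(0, 2)))
        h = c.hap ^ int(flips[c.block_id])
        out.append(ExternalPhaseCall(c.chrom, c.pos, c.ref, c.alt, c.source, c.block_id, h))
    return out


class TestMetricInvariances:
    def test_flip_invariance_and_symmetry(self, rng):
        for _ in range(10):
            a, b = random_phasings(rng)
            d_ab = overall_discordance(find_common_blocks(a, b))
            d_ba = overall_discordance(find_common_blocks(b, a))
            assert d_ab == pytest.approx(d_ba)
            d_flip = overall_discordance(find_common_blocks(flip_blocks(a, rng), b))
            assert d_flip == pytest.approx(d_ab)
            assert 0 <= d_ab <= 1
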