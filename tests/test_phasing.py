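import numpy as np
import pytest

from vafphase.cbs import Segment
from vafphase.delta import compute_delta_vaf
from vafphase.model import ExternalPhaseCall, ExternalSegment
from vafphase.phasing import (
    PhaseParams,
    assign_phase,
    merge_phase_sources,
    phase_sample,
)
from vafphase.simulate import SimConfig, simulate_pair

from conftest import make_site


def _results(counts):
    """DeltaVAFResults for a list of (pos, n_ref, n_alt, t_ref, t_alt)."""
    return [compute_delta_vaf(make_site(pos=p, n_ref=a, n_alt=b, t_ref=c, t_alt=d))
            for p, a, b, c, d in counts]


def _segment(n, start=100, end=100_000):
    return Segment(chrom="1", start=start, end=end, member_indices=np.arange(n),
                   n_variants=n, mean_abs_dvaf=0.25, size_bp=end - start + 1,
                   eligible=True, significant=True, null_model="hard_cutoff")


class TestAssignPhase:
    def test_opposite_shifts_phase_trans(self):
        res = _results([(100, 50, 50, 25, 75), (200, 50, 50, 75, 25)])
        block = assign_phase(_segment(2), res)
        assert [h for _, h in block.members] == [1, 0]

    def test_same_shift_phases_cis(self):
        res = _results([(100, 50, 50, 25, 75), (200, 50, 50, 25, 75)])
        block = assign_phase(_segment(2), res)
        assert [h for _, h in block.members] == [1, 1]

    def test_fewer_than_two_eligible_members(self):
        # second site has no VAF change: Fisher non-significant
        res = _results([(100, 50, 50, 25, 75), (200, 50, 50, 50, 50)])
        assert assign_phase(_segment(2), res) is None

    def test_non_het_sites_not_phased(self):
        res = _results([(100, 50, 50, 25, 75), (200, 50, 50, 75, 25)])
        import dataclasses
        site = dataclasses.replace(res[1].site, is_het=False)
        res[1] = dataclasses.replace(res[1], site=site)
        assert assign_phase(_segment(2), res) is None


class TestPhaseSample:
    def test_no_scna_no_blocks(self):
        cfg = SimConfig(chrom_lengths={"1": 20_000_000}, n_sites=60, events=[], seed=3)
        sites, _ = simulate_pair(cfg)
        result = phase_sample(sites, PhaseParams(cbs_n_permutations=200))
        assert result.blocks == []
        assert (result.audit.status != "phased").all()

    def test_empty_input(self):
        result = phase_sample([])
        assert result.blocks == [] and result.audit.empty

    def test_duplicate_sites_rejected(self):
        s = make_site()
        with pytest.raises(ValueError, match="duplicate"):
            phase_sample([s, s])

    def test_phased_sites_satisfy_criteria(self):
        """Every phased variant is het, Fisher-significant, and inside one
        significant segment."""
        sites, _ = simulate_pair(SimConfig(seed=21))
        result = phase_sample(sites, PhaseParams(cbs_n_permutations=300))
        audit = result.audit
        phased = audit[audit.status == "phased"]
        assert len(phased) > 0
        assert phased.is_het.all()
        assert (phased.p_value < 0.05).all()
        sig_segments = {s.segment_id for s in result.segments if s.significant}
        assert set(phased.segment).issubset(sig_segments)
        # each phased site lies in exactly one block
        keys = [k for b in result.blocks for k, _ in b.members]
        assert len(keys) == len(set(keys)) == len(phased)

    def test_fold_change_model_uses_external_segments(self):
        cfg = SimConfig(chrom_lengths={"1": 20_000_000}, n_sites=60,
                        events=[], seed=9)
        sites, _ = simulate_pair(cfg)
        ext = [ExternalSegment("1", 1, 10_000_000, fold_change=1.3),
               ExternalSegment("1", 10_000_001, 20_000_000, fold_change=1.0)]
        params = PhaseParams(null_model="fold_change", fisher_alpha=0.9)
        result = phase_sample(sites, params, external_segments=ext)
        assert {s.null_model for s in result.segments} == {"fold_change"}
        phased = result.audit[result.audit.status == "phased"]
        assert (phased.pos <= 10_000_000).all()

    def test_region_specific_requires_panel(self):
        with pytest.raises(ValueError, match="panel"):
            phase_sample([make_site()], PhaseParams(null_model="region_specific"))


def _call(pos, source, block, hap, chrom="1"):
    return ExternalPhaseCall(chrom, pos, "A", "G", source, block, hap)


class TestMergePhaseSources:
    def test_vaf_priority(self):
        vaf = [_call(100, "VAF", "v1", 0), _call(200, "VAF", "v1", 1)]
        hc = [_call(100, "HAPCUT2", "h1", 1), _call(300, "HAPCUT2", "h1", 0)]
        merged = merge_phase_sources(vaf, hc, [])
        assert merged.provenance[("1", 100, "A", "G")] == "VAF"
        assert merged.provenance[("1", 300, "A", "G")] == "HAPCUT2"

    def test_read_backed_agreement_kept_disagreement_dropped(self):
        # hc and phaser blocks share sites 100/200/300; phaser is globally
        # flipped (consistent) except site 300 disagrees.
        hc = [_call(100, "HAPCUT2", "h1", 0), _call(200, "HAPCUT2", "h1", 1),
              _call(300, "HAPCUT2", "h1", 1)]
        ph = [_call(100, "PHASER", "p1", 1), _call(200, "PHASER", "p1", 0),
              _call(300, "PHASER", "p1", 1)]
        merged = merge_phase_sources([], hc, ph)
        keys = set(merged.provenance)
        assert ("1", 100, "A", "G") in keys and ("1", 200, "A", "G") in keys
        assert ("1", 300, "A", "G") not in keys

    def test_single_source_site_retained(self):
        ph = [_call(500, "PHASER", "p1", 0), _call(600, "PHASER", "p1", 1)]
        merged = merge_phase_sources([], [], ph)
        assert merged.provenance[("1", 500, "A", "G")] == "PHASER"

    def test_conflicting_duplicates_rejected(self):
        hc = [_call(100, "HAPCUT2", "h1", 0), _call(100, "HAPCUT2", "h1", 1)]
        with pytest.raises(ValueError, match="100"):
            merge_phase_sources([], hc, [])

    def test_merge_flip_invariant(self):
        hc = [_call(100, "HAPCUT2", "h1", 0), _call(200, "HAPCUT2", "h1", 1)]
        ph = [_call(100, "PHASER", "p1", 0), _call(200, "PHASER", "p1", 1)]
        ph_flipped = [_call(100, "PHASER", "p1", 1), _call(200, "PHASER", "p1", 0)]
        a = merge_phase_sources([], hc, ph)
        b = merge_phase_sources([], hc, ph_flipped)
        assert set(a.provenance) == set(b.provenance)
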