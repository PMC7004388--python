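"""Anchoring, extension, gap assessment, clustering, variability, summaries."""

import numpy as np
import pytest

from conftest import make_map
from subtelomap.armcall import (GapAssessment, HaplotypeCall, Variability,
                                anchor_to_arm, assess_gap, call_arm,
                                classify_variability, cluster_haplotypes,
                                confirm_telomere, measure_extension,
                                round_extension, scan_inp, summarize_arm)
from subtelomap.assemble import assemble_arm
from subtelomap.core import GapInterval, PipelineParams, ReferenceArm, \
    child_seed
from subtelomap.scenarios import (extension_arm, insertion_arm, multi_arm,
                                  terminal_gap_arm)
from subtelomap.simulate import simulate_molecules


def _assembled(scenario, hap_name, params, seed, telomere=True):
    hap = scenario.haplotypes[hap_name]
    mols = simulate_molecules(hap, params, seed=seed,
                              telomere_labeling=telomere)
    res = assemble_arm([m.map for m in mols], params)
    contig = max(res.contigs, key=lambda c: c.n_molecules)
    return contig, mols


@pytest.fixture(scope="module")
def arms_and_contigs(params):
    scen = multi_arm(2)
    arms = [sc.reference for sc in scen.values()]
    contigs = {}
    for arm, sc in scen.items():
        contig, _ = _assembled(sc, f"{arm}_ref", params, child_seed(99, arm))
        contigs[arm] = contig
    return arms, contigs


class TestAnchoring:
    def test_planted_truth_assigned_correctly(self, arms_and_contigs,
                                              params):
        arms, contigs = arms_and_contigs
        for arm, contig in contigs.items():
            hit = anchor_to_arm(contig, arms, params)
            assert hit is not None and hit[0].arm == arm

    def test_shared_block_content_alone_is_ambiguous(self, arms_and_contigs,
                                                     params, library):
        """A contig made only of a shared block pattern anchors nowhere."""
        arms, _ = arms_and_contigs
        from subtelomap.simulate import HaplotypeSpec, compose_haplotype
        spec = HaplotypeSpec(name="blockonly", arm="zq",
                             onecopy_bp=100_000, anchor_seed=555,
                             block_order=(("B5", 1), ("B3", 1)))
        lmap, _ = compose_haplotype(spec, library)
        # keep only the shared-block portion (strip the private anchor)
        block_part = lmap.slice(100_000, lmap.length_bp, "blockonly")
        from subtelomap.assemble import ConsensusMap
        contig = ConsensusMap(map=block_part,
                              support=np.full(block_part.n_labels, 10),
                              n_molecules=10, coverage=10.0,
                              terminus_bp=float(block_part.length_bp))
        assert anchor_to_arm(contig, arms, params) is None


class TestExtension:
    def test_reference_identical_contig_is_zero(self, params):
        sc = extension_arm()
        contig, _ = _assembled(sc, "3q-like_ref", params, 1)
        arm = sc.reference
        hit = anchor_to_arm(contig, [arm], params)
        rounded, raw = measure_extension(contig, arm, hit[1], params)
        assert rounded == 0 and abs(raw) < params.gap_resolution_bp

    def test_sub_resolution_extension_reported_zero(self, params):
        assert round_extension(5_000, params) == 0
        assert round_extension(-9_999, params) == 0
        assert round_extension(43_800, params) == 45_000
        assert round_extension(-112_300, params) == -110_000

    def test_planted_130kb_extension_recovered(self, params):
        sc = extension_arm()
        contig, mols = _assembled(sc, "3q-like_ext130", params, 2)
        call = call_arm("g", contig, [sc.reference], params, molecules=mols)
        assert call.extension_bp == 130_000
        assert call.gap_assessment is GapAssessment.EXTEND


class TestGapAssessment:
    def _arm(self, gap_len):
        pos = np.arange(10_000, 380_000, 12_000)
        gaps = [GapInterval(500_000 - gap_len, 500_000)] if gap_len else []
        return ReferenceArm(arm="x", map=make_map(pos, length=500_000),
                            gaps=gaps, window_bp=500_000, tel_end_bp=500_000)

    def _contig(self):
        from subtelomap.assemble import ConsensusMap
        pos = np.arange(10_000, 380_000, 12_000)
        return ConsensusMap(map=make_map(pos, length=390_000),
                            support=np.full(len(pos), 30), n_molecules=30,
                            coverage=30.0, terminus_bp=390_000.0)

    def test_delete_when_contig_stops_at_gap_start(self, params):
        arm = self._arm(110_000)
        got = assess_gap(self._contig(), arm, -110_000, params=params)
        assert got is GapAssessment.DELETE

    def test_extend_when_past_reference_end(self, params):
        got = assess_gap(self._contig(), self._arm(0), 40_000, params=params)
        assert got is GapAssessment.EXTEND

    def test_supported_at_reference_end_or_inside_gap(self, params):
        assert assess_gap(self._contig(), self._arm(0), 0,
                          params=params) is GapAssessment.SUPPORTED
        assert assess_gap(self._contig(), self._arm(110_000), -50_000,
                          params=params) is GapAssessment.SUPPORTED

    def test_unanchored_call_carries_no_assessment(self):
        call = HaplotypeCall(genome_id="g", arm="NA", contig_id="c",
                             anchored=False)
        assert call.gap_assessment is GapAssessment.NO_CALL
        with pytest.raises(ValueError):
            HaplotypeCall(genome_id="g", arm="x", contig_id="c",
                          anchored=False,
                          gap_assessment=GapAssessment.DELETE)


class TestTelomereConfirmation:
    def test_confirmed_with_labeling_on(self, params):
        sc = terminal_gap_arm()
        contig, mols = _assembled(sc, "18q-like_true", params, 3)
        assert confirm_telomere(contig, mols, params)

    def test_false_with_labeling_off(self, params):
        sc = terminal_gap_arm()
        contig, mols = _assembled(sc, "18q-like_true", params, 3,
                                  telomere=False)
        assert not confirm_telomere(contig, mols, params)

    def test_false_for_truncated_contig(self, params):
        sc = terminal_gap_arm()
        contig, mols = _assembled(sc, "18q-like_true", params, 3)
        contig.terminus_bp -= 50_000  # pretend the contig stops early
        assert not confirm_telomere(contig, mols, params)


class TestInpScan:
    def test_same_strand_labels_give_nothing(self):
        m = make_map([1_000, 1_500, 9_000], strands=["+", "+", "+"])
        assert scan_inp(m, 1_000) == []

    def test_opposing_close_pair_found(self):
        m = make_map([10_000, 10_500], length=20_000, strands=["+", "-"])
        [site] = scan_inp(m, 1_000)
        assert site.position_bp == 10_250 and site.pair_distance_bp == 500

    def test_matches_brute_force_pair_scan(self, rng):
        pos = np.sort(rng.choice(100_000, 60, replace=False))
        strands = rng.choice(["+", "-"], 60)
        m = make_map(pos, length=100_000, strands=strands)
        got = {(s.position_bp, s.pair_distance_bp) for s in scan_inp(m, 2_000)}
        expected = set()
        for i in range(59):
            d = int(pos[i + 1] - pos[i])
            if strands[i] != strands[i + 1] and d <= 2_000:
                expected.add((int((pos[i] + pos[i + 1]) // 2), d))
        assert got == expected

    def test_requires_strand_annotation(self):
        with pytest.raises(ValueError, match="strand"):
            scan_inp(make_map([1_000]), 1_000)


@pytest.fixture(scope="module")
def cohort(params):
    sc = insertion_arm()
    calls, contigs = [], {}
    plan = [("g0", "2q-like_major"), ("g1", "2q-like_major"),
            ("g2", "2q-like_major"), ("g3", "2q-like_minor45")]
    for gid, hap_name in plan:
        contig, mols = _assembled(sc, hap_name, params, child_seed(1, gid))
        contig.map.id = f"{gid}:{contig.map.id}"
        contigs[contig.map.id] = contig
        calls.append(call_arm(gid, contig, [sc.reference], params,
                              molecules=mols))
    cluster_haplotypes(calls, contigs, params)
    return calls, contigs


class TestClustering:
    def test_same_haplotype_contigs_share_a_cluster(self, cohort):
        calls, _ = cohort
        majors = [c.cluster for c in calls if c.genome_id != "g3"]
        assert len(set(majors)) == 1 and majors[0] == 1

    def test_45kb_insertion_forms_second_cluster(self, cohort):
        calls, _ = cohort
        [minor] = [c for c in calls if c.genome_id == "g3"]
        assert minor.cluster == 2
        assert minor.extension_bp == 45_000

    def test_order_invariance(self, cohort, params):
        calls, contigs = cohort
        reordered = list(reversed([HaplotypeCall(**{
            "genome_id": c.genome_id, "arm": c.arm,
            "contig_id": c.contig_id, "anchored": c.anchored,
            "extension_bp": c.extension_bp,
            "extension_raw_bp": c.extension_raw_bp,
            "gap_assessment": c.gap_assessment,
            "telomere_confirmed": c.telomere_confirmed}) for c in calls]))
        cluster_haplotypes(reordered, contigs, params)
        by_contig = {c.contig_id: c.cluster for c in calls}
        for c in reordered:
            assert c.cluster == by_contig[c.contig_id]

    def test_sub_resolution_difference_stays_one_cluster(self, params):
        """Contigs whose raw extensions differ by 5 kb are one haplotype."""
        sc = insertion_arm()
        contig_a, _ = _assembled(sc, "2q-like_major", params, 51)
        contig_b, _ = _assembled(sc, "2q-like_major", params, 52)
        contig_b.map.id = "b:" + contig_b.map.id
        contig_b.terminus_bp += 5_000  # nudge below the resolution
        contigs = {c.map.id: c for c in (contig_a, contig_b)}
        calls = []
        for gid, contig in (("ga", contig_a), ("gb", contig_b)):
            calls.append(call_arm(gid, contig, [sc.reference], params))
        cluster_haplotypes(calls, contigs, params)
        assert calls[0].cluster == calls[1].cluster == 1


class TestVariability:
    def test_single_cluster_is_low(self):
        assert classify_variability([100]) is Variability.LOW

    def test_twelve_percent_minor_is_high(self):
        assert classify_variability([125, 17]) is Variability.HIGH

    def test_exactly_ten_percent_is_low(self):
        assert classify_variability([90, 10]) is Variability.LOW

    def test_just_above_threshold_is_high(self):
        assert classify_variability([899, 101]) is Variability.HIGH

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_variability([])


def _calls(arm, cluster_sizes, n_failed=0):
    out = []
    k = 0
    for cluster, size in enumerate(cluster_sizes, start=1):
        for _ in range(size):
            out.append(HaplotypeCall(
                genome_id=f"g{k}", arm=arm, contig_id=f"c{k}", anchored=True,
                extension_bp=0, extension_raw_bp=0.0,
                gap_assessment=GapAssessment.SUPPORTED, cluster=cluster))
            k += 1
    for _ in range(n_failed):
        out.append(HaplotypeCall(genome_id=f"g{k}", arm="NA",
                                 contig_id=f"c{k}", anchored=False))
        k += 1
    return out


class TestArmSummary:
    def test_no_calls(self):
        s = summarize_arm([], arm="9p")
        assert s.n_represented == 0 and s.variability is Variability.NA

    def test_counts_and_conservation(self):
        """Represented plus failed equals the cohort's contig opportunities."""
        calls = _calls("7q", [80, 30], n_failed=44)
        s = summarize_arm(calls)
        assert s.n_represented == 110 and s.n_failed == 44
        assert s.n_represented + s.n_failed == len(calls)
        assert s.n_represented == sum(s.cluster_sizes)

    @pytest.mark.parametrize("arm,sizes,failed,expected_represented", [
        ("1p", [96, 17], 41, 113),    # 96 + 17 = 113, + 41 failed = 154
        ("2q", [110, 20, 3], 21, 133),
        ("5q", [135, 15], 4, 150),
        ("16q", [73, 48], 33, 121),
        ("20p", [94, 41], 19, 135),
    ])
    def test_haplotype_counts_sum_to_arm_totals(self, arm, sizes, failed,
                                                expected_represented):
        """Per-arm haplotype tallies add up to the arm's represented total
        (and, with failures, to the cohort size)."""
        s = summarize_arm(_calls(arm, sizes, n_failed=failed))
        assert s.n_represented == expected_represented
        if arm == "1p":
            assert s.n_represented + s.n_failed == 154
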