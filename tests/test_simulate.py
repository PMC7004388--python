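"""Synthetic haplotypes, cohorts and error-bearing molecule simulation."""

import itertools

import numpy as np
import pytest

from subtelomap.align import align_fit
from subtelomap.blocks import block_detection_params, patterns_from_library
from subtelomap.core import PipelineParams
from subtelomap.simulate import (BlockSpec, HaplotypeSpec, PopulationSpec,
                                 compose_haplotype, default_block_library,
                                 read_bnx, reference_arm, sample_population,
                                 simulate_molecules, write_bnx,
                                 BnxParseError, DEFAULT_SUPERPOP_SIZES)


class TestBlockLibrary:
    def test_shipped_blocks_are_valid_and_labelled(self, library):
        assert len(library) == 8
        for b in library.values():
            assert 5 <= b.n_labels <= 9
            assert sum(b.label_spacings) < b.length_bp
            assert min(b.label_spacings) >= 3_000

    def test_no_pattern_cross_aligns(self, library, params):
        """No block pattern fit-aligns to another at detection thresholds."""
        ap = block_detection_params(params)
        maps = {p.name: p.to_map() for p in patterns_from_library(library)}
        sizes = {p.name: p.n_labels for p in patterns_from_library(library)}
        for a, b in itertools.permutations(maps, 2):
            aln = align_fit(maps[a], maps[b], ap)
            assert aln is None or aln.n_pairs / sizes[a] < 0.7, (a, b)

    def test_invalid_spacings_rejected(self):
        with pytest.raises(ValueError):
            BlockSpec("x", 10_000, (4_000, 7_000))  # exceeds length
        with pytest.raises(ValueError):
            BlockSpec("x", 10_000, (4_000, -1))


class TestComposeHaplotype:
    def test_empty_block_order_is_anchor_alone(self, library):
        spec = HaplotypeSpec(name="bare", arm="9q", onecopy_bp=200_000)
        lmap, truth = compose_haplotype(spec, library)
        assert lmap.length_bp == 200_000
        assert truth.telomere_bp == 200_000
        assert truth.block_intervals == []
        assert np.all(lmap.positions < 200_000)

    def test_block_spacings_concatenate(self, library):
        """Composed spacings equal the blocks' vectors plus junctions."""
        spec = HaplotypeSpec(name="h", arm="9q", onecopy_bp=200_000,
                             block_order=(("B1-2", 1), ("B3", 1)))
        lmap, truth = compose_haplotype(spec, library)
        spacings = set(np.diff(lmap.positions).tolist())
        for name in ("B1-2", "B3"):
            for s in library[name].label_spacings:
                assert s in spacings
        assert truth.block_intervals == [
            ("B1-2", 200_000, 245_000, 1), ("B3", 245_000, 275_000, 1)]
        assert lmap.length_bp == 275_000

    def test_reverse_orientation_mirrors_block_pattern(self, library):
        fwd = HaplotypeSpec(name="f", arm="9q", onecopy_bp=150_000,
                            block_order=(("B23", 1),))
        rev = HaplotypeSpec(name="r", arm="9q", onecopy_bp=150_000,
                            block_order=(("B23", -1),))
        mf, _ = compose_haplotype(fwd, library)
        mr, _ = compose_haplotype(rev, library)
        block_f = mf.positions[mf.positions >= 150_000] - 150_000
        block_r = mr.positions[mr.positions >= 150_000] - 150_000
        L = library["B23"].length_bp
        assert sorted(block_r.tolist()) == sorted((L - block_f).tolist())

    def test_planted_extension_versus_reference(self, library):
        """A haplotype with four extra blocks ends 130 kb past its
        reference rendering."""
        common = dict(arm="3q", onecopy_bp=375_000, anchor_seed=11)
        ref_spec = HaplotypeSpec(name="ref", block_order=(("B9", 1),),
                                 **common)
        ext_spec = HaplotypeSpec(
            name="ext", block_order=(("B9", 1), ("B1-2", 1), ("B3", 1),
                                     ("B4", 1), ("B5", 1)), **common)
        ref = reference_arm(ref_spec, library)
        ext, truth = compose_haplotype(ext_spec, library)
        assert truth.telomere_bp - ref.tel_end_bp == 130_000
        # identical anchor pattern across haplotypes of the arm
        ref_anchor = ref.map.positions[ref.map.positions < 375_000]
        ext_anchor = ext.positions[ext.positions < 375_000]
        assert np.array_equal(ref_anchor, ext_anchor)

    def test_unknown_block_rejected(self, library):
        spec = HaplotypeSpec(name="x", arm="1q", block_order=(("nope", 1),))
        with pytest.raises(KeyError):
            compose_haplotype(spec, library)

    def test_terminal_gap_goes_into_reference_only(self, library):
        spec = HaplotypeSpec(name="g", arm="18q", onecopy_bp=150_000,
                             terminal_gap_bp=110_000)
        ref = reference_arm(spec, library)
        assert ref.tel_end_bp == 260_000
        assert ref.terminal_gap().length == 110_000
        lmap, truth = compose_haplotype(spec, library)
        assert truth.telomere_bp == 150_000


class TestPopulation:
    def _pop(self, freqs, sizes=None, seed=0):
        return PopulationSpec(
            frequencies={"2q": {sp: dict(freqs) for sp in
                                (sizes or DEFAULT_SUPERPOP_SIZES)}},
            superpop_sizes=dict(sizes or DEFAULT_SUPERPOP_SIZES), seed=seed)

    def test_single_haplotype_everyone_homozygous(self):
        genomes = sample_population(self._pop({"h": 1.0}))
        assert all(g.haplotypes["2q"] == ("h", "h") for g in genomes)

    def test_default_sizes_give_154_genomes(self):
        genomes = sample_population(self._pop({"h": 1.0}))
        assert len(genomes) == 154
        by_pop = {sp: sum(g.superpop == sp for g in genomes)
                  for sp in DEFAULT_SUPERPOP_SIZES}
        assert by_pop == DEFAULT_SUPERPOP_SIZES

    def test_carrier_fraction_within_binomial_bound(self):
        genomes = sample_population(self._pop({"a": 0.5, "b": 0.5}, seed=3))
        n_draws = 2 * len(genomes)
        n_a = sum(g.haplotypes["2q"].count("a") for g in genomes)
        sd = np.sqrt(n_draws * 0.25)
        assert abs(n_a - n_draws * 0.5) <= 3 * sd

    def test_reproducible_under_seed(self):
        a = sample_population(self._pop({"a": 0.4, "b": 0.6}, seed=7))
        b = sample_population(self._pop({"a": 0.4, "b": 0.6}, seed=7))
        assert [g.haplotypes for g in a] == [g.haplotypes for g in b]

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to"):
            self._pop({"a": 0.5, "b": 0.6})


@pytest.fixture(scope="module")
def hap(library):
    spec = HaplotypeSpec(name="h", arm="5q", onecopy_bp=300_000,
                         block_order=(("B6-7-8", 1), ("B23", 1)))
    lmap, _ = compose_haplotype(spec, library)
    return lmap


class TestMolecules:
    def test_no_error_limit_reproduces_truth_exactly(self, hap):
        clean = PipelineParams(fp_rate=0.0, fn_rate=0.0, sizing_cv=0.0,
                               jitter_bp=1e-9)
        mols = simulate_molecules(hap, clean, seed=1)
        for m in mols[:40]:
            lo, hi = m.start_bp, m.start_bp + m.map.length_bp
            truth = hap.positions[(hap.positions >= lo)
                                  & (hap.positions < hi)] - lo
            assert np.array_equal(m.map.positions, truth)

    def test_coverage_and_length_floor(self, hap, params):
        mols = simulate_molecules(hap, params, seed=2)
        total = sum(m.map.length_bp for m in mols)
        assert total >= params.min_coverage * hap.length_bp
        assert all(m.map.length_bp >= params.min_molecule_bp for m in mols)

    def test_fn_fraction_within_three_sd(self, hap, params):
        """Observed false-negative fraction matches the 10% error model."""
        no_fp = params.with_(fp_rate=0.0, sizing_cv=0.0, jitter_bp=1e-9)
        mols = simulate_molecules(hap, no_fp, seed=3)
        n_expected = n_observed = 0
        for m in mols:
            lo, hi = m.start_bp, m.start_bp + m.map.length_bp
            n_expected += int(np.sum((hap.positions >= lo)
                                     & (hap.positions < hi)))
            n_observed += m.map.n_labels
        fn = 1 - n_observed / n_expected
        sd = np.sqrt(0.1 * 0.9 / n_expected)
        assert abs(fn - 0.10) <= 3 * sd

    def test_label_count_matches_error_model(self, hap, params):
        """E[observed] = n_true*(1-fn) + fp_rate*n_true per molecule set."""
        mols = simulate_molecules(hap, params, seed=4)
        n_true = n_obs = 0
        for m in mols:
            lo, hi = m.start_bp, m.start_bp + m.map.length_bp
            n_true += int(np.sum((hap.positions >= lo)
                                 & (hap.positions < hi)))
            n_obs += m.map.n_labels
        expected = n_true * (1 - params.fn_rate) + params.fp_rate * n_true
        # optical merging removes a few close labels; allow 5% slack
        assert n_obs == pytest.approx(expected, rel=0.05)

    def test_forced_inp_breakage_never_spans_site(self, hap, params):
        site = 350_000
        # no sizing noise so molecule coordinates are exact
        sure = params.with_(p_break_inp=1.0, sizing_cv=0.0, jitter_bp=1e-9)
        mols = simulate_molecules(hap, sure, inp_sites=[site], seed=5)
        for m in mols:
            assert not (m.start_bp < site
                        and m.start_bp + m.map.length_bp > site + 1_000)

    def test_telomere_flag_only_at_map_end(self, hap, params):
        mols = simulate_molecules(hap, params, seed=6, telomere_labeling=True)
        flagged = [m for m in mols if m.telomere_label]
        assert flagged
        for m in flagged:
            assert m.start_bp + m.map.length_bp >= hap.length_bp * 0.97

    def test_map_shorter_than_minimum_errors(self, params):
        from conftest import make_map
        tiny = make_map([10_000, 20_000], length=100_000)
        with pytest.raises(ValueError, match="coverage unreachable"):
            simulate_molecules(tiny, params, seed=0)


class TestBnx:
    def test_round_trip(self, tmp_path, hap_molecules=None, params=None):
        p = PipelineParams()
        from conftest import make_map
        src = make_map(np.arange(10_000, 400_000, 11_000), length=400_000)
        mols = simulate_molecules(src, p, seed=1, telomere_labeling=True)[:3]
        path = tmp_path / "m.bnx"
        write_bnx(mols, path)
        back = read_bnx(path)
        assert len(back) == 3
        for m0, m1 in zip(mols, back):
            assert m0.map.id == m1.map.id
            assert np.array_equal(m0.map.positions, m1.map.positions)
            assert m0.start_bp == m1.start_bp
            assert m0.telomere_label == m1.telomere_label

    def test_empty_list_is_header_only(self, tmp_path):
        path = tmp_path / "e.bnx"
        write_bnx([], path)
        assert read_bnx(path) == []

    def test_missing_label_line_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.bnx"
        path.write_text("0 mol1 100000\n0 mol2 100000\n1 5 10\n")
        with pytest.raises(BnxParseError, match="missing its label line"):
            read_bnx(path)
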