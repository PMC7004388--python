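"""Named simulation scenarios emulating the study's benchmark arms.

Each scenario bundles a synthetic reference arm, the true haplotypes
segregating on it, and the planted structural truth, so that the full
pipeline (simulate molecules -> assemble -> anchor -> call) can be run
against a known answer:

``extension_arm``
    an arm whose major haplotype carries 130 kb of extra
    segmental-duplication blocks beyond the reference end (the classic
    subtelomeric extension case);
``terminal_gap_arm``
    an arm whose reference ends in a 110-kb telomere-adjacent N-gap that
    the true sequence does not contain — the contig stops at the gap
    start, calling a −110 kb gap correction (DELETE);
``insertion_arm``
    a two-haplotype arm where the minor haplotype carries a 45-kb
    terminal insertion relative to the major one;
``divergent_pair_arm``
    two haplotypes whose distal block composition differs (substitution,
    not pure extension), the configuration that forces a heterozygous
    genome to assemble into two contigs;
``multi_arm``
    several arms with distinct 1-copy anchors and partly shared blocks,
    for anchoring specificity and population runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .core import LabelMap, ReferenceArm
from .simulate import (BlockSpec, HaplotypeSpec, HaplotypeTruth,
                       compose_haplotype, default_block_library,
                       reference_arm)

__all__ = ["ArmScenario", "extension_arm", "terminal_gap_arm",
           "insertion_arm", "divergent_pair_arm", "multi_arm"]


@dataclass
class ArmScenario:
    arm: str
    reference: ReferenceArm
    haplotypes: dict[str, LabelMap]
    truths: dict[str, HaplotypeTruth]
    library: Mapping[str, BlockSpec]
    # planted signed extension (bp) of each haplotype vs the reference end
    true_extension: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(cls, arm: str, ref_spec: HaplotypeSpec,
              hap_specs: list[HaplotypeSpec],
              library: Mapping[str, BlockSpec] | None = None
              ) -> "ArmScenario":
        lib = library or default_block_library()
        ref = reference_arm(ref_spec, lib)
        haps, truths, ext = {}, {}, {}
        for spec in hap_specs:
            lmap, truth = compose_haplotype(spec, lib)
            haps[spec.name] = lmap
            truths[spec.name] = truth
            ext[spec.name] = truth.telomere_bp - ref.tel_end_bp
        return cls(arm=arm, reference=ref, haplotypes=haps, truths=truths,
                   library=lib, true_extension=ext)


def extension_arm(anchor_seed: int = 11) -> ArmScenario:
    """Major haplotype extends 130 kb beyond the reference end.

    The reference window is anchor + three blocks (500 kb); the true
    haplotype appends four further blocks (45+30+20+35 = 130 kb), so its
    telomere lies 130 kb past the annotated reference end.
    """
    ref = HaplotypeSpec(
        name="3q-like_ref", arm="3q-like", onecopy_bp=375_000,
        block_order=(("B10-25-11-12", 1), ("B23", 1), ("B9", 1)),
        anchor_seed=anchor_seed)
    extended = HaplotypeSpec(
        name="3q-like_ext130", arm="3q-like", onecopy_bp=375_000,
        block_order=(("B10-25-11-12", 1), ("B23", 1), ("B9", 1),
                     ("B1-2", 1), ("B3", 1), ("B4", 1), ("B5", 1)),
        extension_bp=130_000, anchor_seed=anchor_seed)
    return ArmScenario.build("3q-like", ref, [ref, extended])


def terminal_gap_arm(anchor_seed: int = 18) -> ArmScenario:
    """Reference carries a 110-kb terminal N-gap absent from the arm.

    The true haplotype ends where the gap begins, so its contig stops
    110 kb short of the annotated reference end: the gap should be
    deleted and the correction is −110 kb.
    """
    ref = HaplotypeSpec(
        name="18q-like_ref", arm="18q-like", onecopy_bp=270_000,
        block_order=(("B6-7-8", 1), ("B9", 1), ("B23", 1)),
        terminal_gap_bp=110_000, anchor_seed=anchor_seed)
    true_hap = HaplotypeSpec(
        name="18q-like_true", arm="18q-like", onecopy_bp=270_000,
        block_order=(("B6-7-8", 1), ("B9", 1), ("B23", 1)),
        extension_bp=-110_000, anchor_seed=anchor_seed)
    return ArmScenario.build("18q-like", ref, [true_hap])


def insertion_arm(anchor_seed: int = 2) -> ArmScenario:
    """Minor haplotype carries a 45-kb terminal insertion vs the major."""
    ref = HaplotypeSpec(
        name="2q-like_ref", arm="2q-like", onecopy_bp=325_000,
        block_order=(("B6-7-8", 1), ("B23", 1), ("B10-25-11-12", 1)),
        anchor_seed=anchor_seed)
    major = HaplotypeSpec(
        name="2q-like_major", arm="2q-like", onecopy_bp=325_000,
        block_order=(("B6-7-8", 1), ("B23", 1), ("B10-25-11-12", 1)),
        anchor_seed=anchor_seed)
    minor = HaplotypeSpec(
        name="2q-like_minor45", arm="2q-like", onecopy_bp=325_000,
        block_order=(("B6-7-8", 1), ("B23", 1), ("B10-25-11-12", 1),
                     ("B1-2", 1)),
        extension_bp=45_000, anchor_seed=anchor_seed)
    return ArmScenario.build("2q-like", ref, [major, minor])


def divergent_pair_arm(anchor_seed: int = 7) -> ArmScenario:
    """Two haplotypes with different distal block composition.

    The distal ~100 kb of the two alleles carry different block patterns
    (and different total lengths), so molecules spanning the divergence
    conflict between haplotypes — a heterozygous genome must yield two
    consensus contigs.
    """
    ref = HaplotypeSpec(
        name="het-like_ref", arm="het-like", onecopy_bp=300_000,
        block_order=(("B6-7-8", 1), ("B23", 1)), anchor_seed=anchor_seed)
    hap_a = HaplotypeSpec(
        name="het-like_A", arm="het-like", onecopy_bp=300_000,
        block_order=(("B6-7-8", 1), ("B23", 1)), anchor_seed=anchor_seed)
    hap_b = HaplotypeSpec(
        name="het-like_B", arm="het-like", onecopy_bp=300_000,
        block_order=(("B6-7-8", 1), ("B5", 1), ("B3", 1), ("B9", 1)),
        anchor_seed=anchor_seed)
    return ArmScenario.build("het-like", ref, [hap_a, hap_b])


def multi_arm(n_arms: int = 3, anchor_seed: int = 100
              ) -> dict[str, ArmScenario]:
    """Arms with distinct 1-copy anchors but partly shared blocks."""
    lib = default_block_library()
    shared = [("B5", 1), ("B3", 1)]
    distinct = [[("B23", 1)], [("B10-25-11-12", 1)], [("B6-7-8", 1)],
                [("B9", 1)], [("B1-2", 1)]]
    out = {}
    for k in range(n_arms):
        arm = f"arm{k}q"
        spec = HaplotypeSpec(
            name=f"{arm}_ref", arm=arm, onecopy_bp=330_000,
            block_order=tuple(shared + distinct[k % len(distinct)]),
            anchor_seed=anchor_seed + k)
        alt = HaplotypeSpec(
            name=f"{arm}_noB5", arm=arm, onecopy_bp=330_000,
            block_order=tuple([("B3", 1)] + distinct[k % len(distinct)]),
            anchor_seed=anchor_seed + k)
        out[arm] = ArmScenario.build(arm, spec, [spec, alt], library=lib)
    return out
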