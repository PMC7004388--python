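"""Synthetic-data generator for subtelomere optical-mapping studies.

Builds block-structured subtelomeric haplotypes (an arm-specific 1-copy
anchor followed by named segmental-duplication "paralogy blocks", each
recognizable by its nick-label spacing pattern), samples a diploid cohort
with per-super-population haplotype frequencies, and simulates
error-bearing single-molecule label maps:

* molecule lengths follow a shifted exponential (minimum 150 kb, mean
  300 kb), truncated at the haplotype end;
* each true label is dropped with the false-negative rate; spurious labels
  arrive as a homogeneous Poisson process tuned so the expected
  false-positive fraction matches the false-positive rate;
* per-interval multiplicative sizing noise and additive label jitter;
* labels closer than the optical resolution merge into one;
* molecules spanning an inverted-nick-pair (INP) site break there with
  probability ``p_break_inp``;
* molecules reaching the haplotype end can carry a telomere end-label.

The cohort defaults mirror the study design: 154 diploid genomes across
five super-populations (42 AFR, 30 AMR, 30 EAS, 24 EUR, 28 SAS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (GapInterval, LabelMap, PipelineParams, ReferenceArm,
                   child_rng, child_seed)

__all__ = [
    "BlockSpec", "HaplotypeSpec", "PopulationSpec", "SimulatedGenome",
    "SimulatedMolecule", "HaplotypeTruth", "default_block_library",
    "compose_haplotype", "reference_arm", "sample_population",
    "simulate_molecules", "write_bnx", "read_bnx",
    "DEFAULT_SUPERPOP_SIZES",
]

DEFAULT_SUPERPOP_SIZES: dict[str, int] = {
    "AFR": 42, "AMR": 30, "EAS": 30, "EUR": 24, "SAS": 28,
}


@dataclass(frozen=True)
class BlockSpec:
    """A named paralogy block characterized by its nick-spacing pattern."""

    name: str
    length_bp: int
    label_spacings: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.label_spacings):
            raise ValueError("spacings must be positive")
        if sum(self.label_spacings) >= self.length_bp:
            raise ValueError(f"block {self.name}: spacings exceed its length")

    @property
    def n_labels(self) -> int:
        return len(self.label_spacings) + 1

    def label_offsets(self, orientation: int = 1) -> np.ndarray:
        """Label positions within the block; orientation -1 mirrors them."""
        lead = (self.length_bp - sum(self.label_spacings)) // 2
        offs = lead + np.concatenate(([0], np.cumsum(self.label_spacings)))
        if orientation < 0:
            offs = np.sort(self.length_bp - offs)
        return offs.astype(np.int64)


def default_block_library() -> dict[str, BlockSpec]:
    """The shipped library of eight blocks with distinct spacing patterns.

    Lengths echo the size range of subtelomeric duplicons (20-60 kb).
    The spacing vectors are fixed, with deliberately contrasting rhythms
    (each block mixes short and long intervals in a different order), so
    that no pattern fit-aligns to another — in either orientation — at the
    detection thresholds.  The collision property is asserted by the test
    suite.
    """
    design = [
        ("B1-2", 45_000, (5_000, 9_200, 8_200, 5_600, 5_100)),
        ("B3", 30_000, (3_400, 7_200, 9_300, 3_900)),
        ("B4", 20_000, (5_400, 3_300, 5_600, 3_000)),
        ("B5", 35_000, (5_500, 6_300, 6_700, 4_500, 6_700)),
        ("B6-7-8", 55_000, (6_900, 7_800, 3_700, 4_400, 8_200, 3_000, 9_900)),
        ("B9", 25_000, (5_300, 4_500, 5_500, 5_700)),
        ("B23", 40_000, (7_400, 6_600, 5_700, 3_000, 3_000, 6_800)),
        ("B10-25-11-12", 60_000,
         (4_400, 6_600, 10_100, 10_900, 3_300, 3_700, 3_000, 3_600)),
    ]
    return {name: BlockSpec(name, length, spacings)
            for name, length, spacings in design}


@dataclass(frozen=True)
class HaplotypeSpec:
    """One long-range subtelomeric haplotype of an arm.

    ``block_order`` lists (block name, orientation ±1) telomere-ward of the
    1-copy anchor.  ``terminal_gap_bp`` is appended as Ns only in the
    reference rendering of the haplotype; ``extension_bp`` documents the
    intended offset of the true telomere versus the reference end.
    """

    name: str
    arm: str
    block_order: tuple[tuple[str, int], ...] = ()
    onecopy_bp: int = 350_000
    terminal_gap_bp: int = 0
    extension_bp: int = 0
    anchor_seed: int = 0
    min_onecopy_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.onecopy_bp < self.min_onecopy_bp:
            raise ValueError(
                "the 1-copy anchor must out-reach molecule length for "
                f"anchoring to be meaningful (>= {self.min_onecopy_bp} bp)")


@dataclass
class HaplotypeTruth:
    """Ground-truth annotation of a composed haplotype, for evaluation."""

    telomere_bp: int
    onecopy: GapInterval
    block_intervals: list[tuple[str, int, int, int]]  # name, start, end, orient


def _anchor_positions(spec: HaplotypeSpec) -> np.ndarray:
    """Arm-specific 1-copy label pattern, shared by all haplotypes of the arm."""
    rng = child_rng(spec.anchor_seed, f"anchor:{spec.arm}")
    positions = []
    pos = int(rng.integers(5_000, 9_000))
    while pos < spec.onecopy_bp - 6_000:
        positions.append(pos)
        pos += int(rng.integers(8_000, 16_000))
    return np.array(positions, dtype=np.int64)


def compose_haplotype(spec: HaplotypeSpec, library: Mapping[str, BlockSpec]
                      ) -> tuple[LabelMap, HaplotypeTruth]:
    """Concatenate the 1-copy anchor and the ordered blocks into a label map."""
    positions = list(_anchor_positions(spec))
    truth_blocks = []
    cursor = spec.onecopy_bp
    for name, orientation in spec.block_order:
        if name not in library:
            raise KeyError(f"unknown block {name!r}")
        block = library[name]
        positions.extend(cursor + block.label_offsets(orientation))
        truth_blocks.append((name, cursor, cursor + block.length_bp,
                             orientation))
        cursor += block.length_bp
    lmap = LabelMap(id=spec.name, length_bp=cursor,
                    positions=np.array(positions, dtype=np.int64))
    truth = HaplotypeTruth(telomere_bp=cursor,
                           onecopy=GapInterval(0, spec.onecopy_bp),
                           block_intervals=truth_blocks)
    return lmap, truth


def reference_arm(spec: HaplotypeSpec, library: Mapping[str, BlockSpec]
                  ) -> ReferenceArm:
    """Render the haplotype as a reference arm window.

    ``terminal_gap_bp`` Ns are appended, so the annotated arm end
    (``tel_end_bp``) sits at the far side of the terminal gap — the same
    convention reference assemblies use for telomere-adjacent gaps.
    """
    lmap, truth = compose_haplotype(spec, library)
    gaps = []
    length = lmap.length_bp + spec.terminal_gap_bp
    if spec.terminal_gap_bp > 0:
        gaps.append(GapInterval(lmap.length_bp, length))
    ref_map = LabelMap(id=f"{spec.arm}_ref", length_bp=length,
                       positions=lmap.positions)
    return ReferenceArm(arm=spec.arm, map=ref_map, gaps=gaps,
                        window_bp=length, tel_end_bp=length,
                        onecopy_interval=truth.onecopy)


# ---------------------------------------------------------------------------
# population sampling

@dataclass
class PopulationSpec:
    """Cohort design: super-population sizes and per-arm haplotype frequencies.

    ``frequencies[arm][superpop]`` maps haplotype name -> frequency; the
    frequencies for each arm/super-population must sum to 1.
    """

    frequencies: dict[str, dict[str, dict[str, float]]]
    superpop_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUPERPOP_SIZES))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.superpop_sizes.values()):
            raise ValueError("super-population sizes must be positive")
        for arm, per_pop in self.frequencies.items():
            for pop, freqs in per_pop.items():
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{arm}/{pop}: frequencies sum to {total}, not 1")


@dataclass
class SimulatedGenome:
    genome_id: str
    superpop: str
    haplotypes: dict[str, tuple[str, str]]  # arm -> diploid pair of hap names


def sample_population(pop: PopulationSpec) -> list[SimulatedGenome]:
    """Draw the diploid cohort; two independent draws per genome per arm."""
    rng = child_rng(pop.seed, "population")
    genomes = []
    for superpop in sorted(pop.superpop_sizes):
        for k in range(pop.superpop_sizes[superpop]):
            haps = {}
            for arm in sorted(pop.frequencies):
                freqs = pop.frequencies[arm][superpop]
                names = sorted(freqs)
                p = np.array([freqs[n] for n in names])
                pair = rng.choice(names, size=2, p=p)
                haps[arm] = (str(pair[0]), str(pair[1]))
            genomes.append(SimulatedGenome(
                genome_id=f"{superpop}{k:03d}", superpop=superpop,
                haplotypes=haps))
    return genomes


# ---------------------------------------------------------------------------
# molecule simulation

@dataclass
class SimulatedMolecule:
    map: LabelMap
    source: str
    start_bp: int
    telomere_label: bool = False
    broken_at_inp: bool = False


_MIN_FRAGMENT_BP = 50_000  # INP fragments shorter than this carry no signal


def simulate_molecules(
    genome_map: LabelMap,
    params: PipelineParams,
    inp_sites: Sequence[int] = (),
    seed: int = 0,
    telomere_labeling: bool = False,
    source: str | None = None,
    coverage: float | None = None,
) -> list[SimulatedMolecule]:
    """Draw error-bearing molecules until mean coverage reaches the target."""
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    L = genome_map.length_bp
    if L <= params.min_molecule_bp:
        raise ValueError(
            f"map {genome_map.id!r} ({L} bp) shorter than the minimum "
            f"molecule length; coverage unreachable")
    truth = genome_map.positions.astype(np.int64)
    density = truth.size / L
    target_bp = (coverage if coverage is not None else params.min_coverage) * L
    src = source or genome_map.id
    out: list[SimulatedMolecule] = []
    covered = 0.0
    idx = 0
    while covered < target_bp:
        length = int(params.min_molecule_bp + rng.exponential(
            params.mean_molecule_bp - params.min_molecule_bp))
        # the window is the terminal segment of a chromosome: molecules may
        # extend proximally beyond it (clipped at 0, still >= the minimum
        # length inside the window) but nothing lies beyond the telomere
        start = int(rng.integers(-(length - params.min_molecule_bp),
                                 L - params.min_molecule_bp + 1))
        end = min(start + length, L)
        start = max(start, 0)
        at_end = end == L
        segments = _apply_inp_breaks(start, end, inp_sites, params, rng)
        for si, (s, e) in enumerate(segments):
            if e - s < _MIN_FRAGMENT_BP:
                continue
            broken = len(segments) > 1
            mol = _materialize(truth, density, s, e, params, rng,
                               mol_id=f"{src}.m{idx}")
            idx += 1
            covered += mol.length_bp
            out.append(SimulatedMolecule(
                map=mol, source=src, start_bp=s,
                telomere_label=(telomere_labeling and at_end and e == end),
                broken_at_inp=broken))
    return out


def _apply_inp_breaks(start: int, end: int, inp_sites: Sequence[int],
                      params: PipelineParams, rng) -> list[tuple[int, int]]:
    cuts = [start]
    for site in sorted(inp_sites):
        if start < site < end and rng.random() < params.p_break_inp:
            cuts.append(int(site))
    cuts.append(end)
    return list(zip(cuts, cuts[1:]))


def _materialize(truth: np.ndarray, density: float, s: int, e: int,
                 params: PipelineParams, rng, mol_id: str) -> LabelMap:
    lo, hi = np.searchsorted(truth, [s, e])
    labels = truth[lo:hi].astype(np.float64) - s
    if params.fn_rate > 0 and labels.size:
        labels = labels[rng.random(labels.size) >= params.fn_rate]
    if params.fp_rate > 0:
        n_fp = rng.poisson(params.fp_rate * density * (e - s))
        if n_fp:
            labels = np.concatenate([labels, rng.uniform(0, e - s, n_fp)])
    labels = np.sort(labels)
    seg_len = float(e - s)
    if params.sizing_cv > 0 and labels.size:
        knots = np.concatenate(([0.0], labels, [seg_len]))
        intervals = np.diff(knots)
        factors = np.clip(1.0 + rng.normal(0, params.sizing_cv,
                                           intervals.size), 0.5, 1.5)
        scaled = np.cumsum(intervals * factors)
        labels = scaled[:-1]
        seg_len = float(scaled[-1])
    if params.jitter_bp > 0 and labels.size:
        labels = labels + rng.normal(0, params.jitter_bp, labels.size)
        labels = np.sort(labels)
    labels = _merge_close(labels, params.optical_resolution_bp)
    length = int(round(seg_len))
    pos = np.unique(np.clip(np.round(labels), 0, length - 1).astype(np.int64))
    return LabelMap(id=mol_id, length_bp=length, positions=pos)


def _merge_close(labels: np.ndarray, resolution_bp: float) -> np.ndarray:
    """Labels closer than the optical resolution collapse to their mean."""
    if labels.size < 2:
        return labels
    out = []
    cluster = [labels[0]]
    for p in labels[1:]:
        if p - cluster[-1] < resolution_bp:
            cluster.append(p)
        else:
            out.append(float(np.mean(cluster)))
            cluster = [p]
    out.append(float(np.mean(cluster)))
    return np.array(out)


def simulate_diploid_arm(
    hap_pair: tuple[LabelMap, LabelMap],
    params: PipelineParams,
    seed: int,
    inp_sites: Sequence[int] = (),
    telomere_labeling: bool = False,
    source_prefix: str = "",
) -> list[SimulatedMolecule]:
    """Molecules for one genome on one arm: each allele at half coverage
    (full coverage when homozygous)."""
    h1, h2 = hap_pair
    if h1.id == h2.id:
        return simulate_molecules(
            h1, params, inp_sites=inp_sites, seed=child_seed(seed, "hom"),
            telomere_labeling=telomere_labeling,
            source=f"{source_prefix}{h1.id}")
    out = []
    for k, h in enumerate((h1, h2)):
        out.extend(simulate_molecules(
            h, params, inp_sites=inp_sites,
            seed=child_seed(seed, f"allele{k}"),
            telomere_labeling=telomere_labeling,
            source=f"{source_prefix}{h.id}.a{k}",
            coverage=params.min_coverage / 2))
    return out


# ---------------------------------------------------------------------------
# simplified BNX dialect

def write_bnx(molecules: Iterable[SimulatedMolecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# subtelomap simplified BNX\n")
        fh.write("# 0 <id> <length_bp> / 1 <label positions> / # truth ...\n")
        for m in molecules:
            fh.write(f"0 {m.map.id} {m.map.length_bp}\n")
            fh.write("1 " + " ".join(str(int(p)) for p in m.map.positions)
                     + "\n")
            fh.write(f"# truth source={m.source} start={m.start_bp} "
                     f"telomere={int(m.telomere_label)} "
                     f"inp={int(m.broken_at_inp)}\n")


class BnxParseError(ValueError):
    pass


def read_bnx(path: str | Path) -> list[SimulatedMolecule]:
    out: list[SimulatedMolecule] = []
    pending: tuple[str, int] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("# truth "):
                if not out or pending is not None:
                    raise BnxParseError(f"{path}:{lineno}: stray truth line")
                fields = dict(tok.split("=", 1)
                              for tok in line[len("# truth "):].split())
                m = out[-1]
                m.source = fields.get("source", m.source)
                m.start_bp = int(fields.get("start", m.start_bp))
                m.telomere_label = bool(int(fields.get("telomere", 0)))
                m.broken_at_inp = bool(int(fields.get("inp", 0)))
                continue
            if line.startswith("#"):
                continue
            if line.startswith("0 "):
                if pending is not None:
                    raise BnxParseError(
                        f"{path}:{lineno}: molecule {pending[0]!r} is missing "
                        "its label line")
                try:
                    _, mol_id, length = line.split()
                    pending = (mol_id, int(length))
                except ValueError as exc:
                    raise BnxParseError(f"{path}:{lineno}: {exc}") from exc
            elif line.startswith("1"):
                if pending is None:
                    raise BnxParseError(
                        f"{path}:{lineno}: label line without a molecule")
                toks = line.split()[1:]
                try:
                    pos = np.array([int(t) for t in toks], dtype=np.int64)
                except ValueError as exc:
                    raise BnxParseError(f"{path}:{lineno}: {exc}") from exc
                mol_id, length = pending
                out.append(SimulatedMolecule(
                    map=LabelMap(id=mol_id, length_bp=length, positions=pos),
                    source=mol_id, start_bp=0))
                pending = None
            else:
                raise BnxParseError(f"{path}:{lineno}: unrecognized line")
    if pending is not None:
        raise BnxParseError(f"{path}: molecule {pending[0]!r} is missing its "
                            "label line")
    return out
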