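"""Anchoring, extension measurement, gap assessment and haplotype calling.

A consensus contig is assigned to a chromosome arm by fit-aligning it to
every reference arm and requiring enough matched labels inside the arm's
1-copy anchor interval plus a clear score margin over the runner-up arm
(segmental-duplication blocks are shared between arms, the 1-copy DNA is
not).  The contig's telomeric terminus is then projected into reference
coordinates through an affine fit of the alignment, and the signed
difference from the annotated arm end is the extension: negative values
mean the reference over-estimates the arm (excess telomere-adjacent gap),
positive values mean the arm carries DNA beyond the reference end.
Differences below the reporting resolution (10 kb) are called 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, AlignmentParams, align_fit
from .assemble import ConsensusMap
from .core import LabelMap, PipelineParams, ReferenceArm
from .simulate import SimulatedMolecule

__all__ = ["GapAssessment", "Variability", "HaplotypeCall", "INPSite",
           "ArmSummary", "anchor_to_arm", "measure_extension", "assess_gap",
           "confirm_telomere", "scan_inp", "cluster_haplotypes",
           "classify_variability", "summarize_arm", "call_arm"]


class GapAssessment(str, enum.Enum):
    SUPPORTED = "SUPPORTED"
    DELETE = "DELETE"
    EXTEND = "EXTEND"
    INACCURATE = "INACCURATE"
    NO_CALL = "NO_CALL"


class Variability(str, enum.Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    NA = "NA"


@dataclass
class HaplotypeCall:
    genome_id: str
    arm: str
    contig_id: str
    anchored: bool
    extension_bp: int | None = None  # rounded at the reporting resolution
    extension_raw_bp: float | None = None
    gap_assessment: GapAssessment = GapAssessment.NO_CALL
    telomere_confirmed: bool = False
    cluster: int | None = None

    def __post_init__(self) -> None:
        if not self.anchored and self.gap_assessment != GapAssessment.NO_CALL:
            raise ValueError("unanchored calls carry no gap assessment")


@dataclass(frozen=True)
class INPSite:
    """Two nick sites close together on opposing strands: a fragile site."""

    position_bp: int
    pair_distance_bp: int


@dataclass
class ArmSummary:
    arm: str
    n_represented: int
    n_failed: int
    cluster_sizes: list[int]
    variability: Variability
    extension_range_kb: tuple[float, float] | None
    gap_assessments: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------

def anchor_to_arm(contig: ConsensusMap, arms: list[ReferenceArm],
                  params: PipelineParams,
                  align_params: AlignmentParams | None = None,
                  score_margin: float = 1.2
                  ) -> tuple[ReferenceArm, Alignment] | None:
    """Assign a contig to the unique arm whose 1-copy anchor it matches.

    Requires ``min_aligned_labels`` matched pairs inside the arm's 1-copy
    interval and the best arm's score to exceed the runner-up by the
    margin factor; otherwise the contig is ambiguous/unanchored.
    """
    ap = align_params or AlignmentParams.from_pipeline(params)
    scored: list[tuple[float, ReferenceArm, Alignment]] = []
    for arm in arms:
        aln = align_fit(contig.map, arm.map, ap)
        if aln is None:
            continue
        if arm.onecopy_interval is not None:
            lo, hi = arm.onecopy_interval
            in_anchor = sum(
                1 for _, j in aln.pairs if lo <= arm.map.positions[j] < hi)
            if in_anchor < ap.min_aligned_labels:
                continue
        scored.append((aln.score, arm, aln))
    if not scored:
        return None
    scored.sort(key=lambda t: -t[0])
    if len(scored) > 1 and scored[0][0] < score_margin * max(scored[1][0], 0.0):
        return None
    _, arm, aln = scored[0]
    return arm, aln


def _affine_fit(aln: Alignment, contig_map: LabelMap,
                ref_map: LabelMap) -> tuple[float, float] | None:
    """Least-squares contig->reference coordinate fit over matched pairs."""
    if aln.n_pairs < 3:
        return None
    x = np.array([contig_map.positions[i] for i, _ in aln.pairs], dtype=float)
    y = np.array([ref_map.positions[j] for _, j in aln.pairs], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def round_extension(raw_bp: float, params: PipelineParams,
                    grid_bp: int = 5_000) -> int:
    """Snap to the reporting grid; differences below the resolution are 0.

    Length differences under the gap resolution (10 kb) cannot be
    distinguished and are called 0; larger ones are reported on a 5-kb
    grid, the granularity of the arm summaries.
    """
    if abs(raw_bp) < params.gap_resolution_bp:
        return 0
    return int(round(raw_bp / grid_bp) * grid_bp)


def measure_extension(contig: ConsensusMap, arm: ReferenceArm,
                      alignment: Alignment, params: PipelineParams
                      ) -> tuple[int, float] | None:
    """Signed extension of the contig terminus past the annotated arm end.

    Returns (rounded, raw) bp, or ``None`` when the alignment is too short
    to support the affine projection (a NO_CALL).
    """
    fit = _affine_fit(alignment, contig.map, arm.map)
    if fit is None:
        return None
    slope, intercept = fit
    projected = slope * contig.terminus_bp + intercept
    raw = projected - arm.tel_end_bp
    return round_extension(raw, params), float(raw)


def assess_gap(contig: ConsensusMap, arm: ReferenceArm, extension_bp: int,
               alignment: Alignment | None = None,
               params: PipelineParams | None = None) -> GapAssessment:
    """Judge the arm's telomere-adjacent gap from the rounded extension.

    EXTEND: the arm carries DNA beyond the annotated end.  DELETE: the
    contig stops at or before the gap start, so the gap length in the
    reference is excessive.  SUPPORTED: the terminus lands at the end or
    inside the gap.  INACCURATE: the 1-copy anchor aligns but the distal
    reference pattern conflicts with the contig.
    """
    p = params or PipelineParams()
    gap = arm.terminal_gap()
    gap_len = gap.length if gap else 0
    if alignment is not None and _distal_conflict(contig, arm, alignment):
        return GapAssessment.INACCURATE
    if extension_bp > 0:
        return GapAssessment.EXTEND
    if extension_bp == 0:
        return GapAssessment.SUPPORTED
    if extension_bp <= -gap_len + p.gap_resolution_bp:
        return GapAssessment.DELETE if gap_len else GapAssessment.INACCURATE
    return GapAssessment.SUPPORTED  # terminus inside the gap


def _distal_conflict(contig: ConsensusMap, arm: ReferenceArm,
                     alignment: Alignment, threshold: float = 0.5) -> bool:
    """True when the reference pattern distal of the 1-copy anchor is
    mostly unmatched although the contig covers it."""
    if arm.onecopy_interval is None:
        return False
    lo = arm.onecopy_interval.end
    hi = min(arm.tel_end_bp, alignment.target_interval[1])
    distal = (arm.map.positions >= lo) & (arm.map.positions < hi)
    n_distal = int(np.sum(distal))
    if n_distal < 4:
        return False
    matched = sum(1 for _, j in alignment.pairs
                  if lo <= arm.map.positions[j] < hi)
    return matched / n_distal < threshold


def confirm_telomere(contig: ConsensusMap,
                     molecules: list[SimulatedMolecule],
                     params: PipelineParams, min_molecules: int = 3) -> bool:
    """True when enough telomere-labeled molecule ends sit at the terminus."""
    tol = max(2 * params.optical_resolution_bp, 3_000)
    n = 0
    for m in molecules:
        if not m.telomere_label:
            continue
        placement = contig.placements.get(m.map.id)
        if placement is None:
            continue
        _, placed_end = placement
        if abs(placed_end - contig.terminus_bp) <= tol:
            n += 1
    return n >= min_molecules


def scan_inp(ref_map: LabelMap, inp_distance_bp: int = 1_000) -> list[INPSite]:
    """Adjacent labels on opposing strands closer than the INP distance."""
    if ref_map.strands is None:
        raise ValueError("scan_inp needs per-label strand annotation")
    out = []
    pos = ref_map.positions
    strands = ref_map.strands
    for k in range(len(pos) - 1):
        d = int(pos[k + 1] - pos[k])
        if strands[k] != strands[k + 1] and d <= inp_distance_bp:
            out.append(INPSite(position_bp=int((pos[k] + pos[k + 1]) // 2),
                               pair_distance_bp=d))
    return out


# ---------------------------------------------------------------------------
# haplotype clustering and arm summaries

def cluster_haplotypes(calls: list[HaplotypeCall],
                       contigs: dict[str, ConsensusMap],
                       params: PipelineParams,
                       align_params: AlignmentParams | None = None
                       ) -> list[HaplotypeCall]:
    """Single-linkage clustering of anchored contigs into haplotypes.

    Two contigs link when they fit-align with high per-label agreement on
    both maps and their terminal lengths (raw extensions) differ by less
    than the reporting resolution; cluster 1 is the largest.  The input
    order does not affect the result.
    """
    ap = align_params or AlignmentParams.from_pipeline(params)
    anchored = sorted((c for c in calls if c.anchored and c.contig_id in contigs),
                      key=lambda c: c.contig_id)
    n = len(anchored)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _same_haplotype(anchored[i], anchored[j], contigs, params, ap):
                parent[find(i)] = find(j)
    groups: dict[int, list[HaplotypeCall]] = {}
    for k, call in enumerate(anchored):
        groups.setdefault(find(k), []).append(call)
    ordered = sorted(groups.values(),
                     key=lambda g: (-len(g), min(c.contig_id for c in g)))
    for cluster_id, group in enumerate(ordered, start=1):
        for call in group:
            call.cluster = cluster_id
    return calls


def _same_haplotype(a: HaplotypeCall, b: HaplotypeCall,
                    contigs: dict[str, ConsensusMap], params: PipelineParams,
                    ap: AlignmentParams) -> bool:
    if a.extension_raw_bp is None or b.extension_raw_bp is None:
        return False
    if abs(a.extension_raw_bp - b.extension_raw_bp) >= params.gap_resolution_bp:
        return False
    ca, cb = contigs[a.contig_id], contigs[b.contig_id]
    query, target = (ca, cb) if ca.map.n_labels <= cb.map.n_labels else (cb, ca)
    aln = align_fit(query.map, target.map, ap)
    if aln is None or aln.orientation != "+":
        return False
    lo, hi = aln.target_interval
    in_span = int(np.sum((target.map.positions >= lo)
                         & (target.map.positions <= hi)))
    return (aln.n_pairs / query.map.n_labels >= 0.7
            and (in_span == 0 or aln.n_pairs / in_span >= 0.7))


def classify_variability(cluster_sizes: list[int],
                         threshold: float = 0.10) -> Variability:
    """HIGH when minor haplotypes exceed the threshold share of the arm.

    The boundary is strict: a minor share of exactly the threshold is LOW
    (minor haplotypes "less than or equal to" the threshold do not make an
    arm variable; they must exceed it).
    """
    if not cluster_sizes:
        raise ValueError("need at least one cluster")
    total = sum(cluster_sizes)
    minor = total - max(cluster_sizes)
    return Variability.HIGH if minor / total > threshold else Variability.LOW


def summarize_arm(calls: list[HaplotypeCall], arm: str | None = None,
                  variability_threshold: float = 0.10) -> ArmSummary:
    """Aggregate per-arm calls into a summary row (arm-table analog)."""
    if arm is None and calls:
        arm = calls[0].arm
    anchored = [c for c in calls if c.anchored]
    failed = [c for c in calls if not c.anchored]
    sizes: dict[int, int] = {}
    for c in anchored:
        if c.cluster is not None:
            sizes[c.cluster] = sizes.get(c.cluster, 0) + 1
    cluster_sizes = [sizes[k] for k in sorted(sizes)]
    if cluster_sizes:
        variability = classify_variability(cluster_sizes,
                                           variability_threshold)
    else:
        variability = Variability.NA
    exts = [c.extension_bp for c in anchored if c.extension_bp is not None]
    ext_range = (min(exts) / 1e3, max(exts) / 1e3) if exts else None
    gap_counts: dict[str, int] = {}
    for c in anchored:
        gap_counts[c.gap_assessment.value] = \
            gap_counts.get(c.gap_assessment.value, 0) + 1
    return ArmSummary(arm=arm or "NA", n_represented=len(anchored),
                      n_failed=len(failed), cluster_sizes=cluster_sizes,
                      variability=variability, extension_range_kb=ext_range,
                      gap_assessments=gap_counts)


# ---------------------------------------------------------------------------

def call_arm(genome_id: str, contig: ConsensusMap,
             arms: list[ReferenceArm], params: PipelineParams,
             molecules: list[SimulatedMolecule] | None = None,
             align_params: AlignmentParams | None = None) -> HaplotypeCall:
    """One contig through anchoring, extension, gap and telomere calls."""
    hit = anchor_to_arm(contig, arms, params, align_params)
    if hit is None:
        return HaplotypeCall(genome_id=genome_id, arm="NA",
                             contig_id=contig.map.id, anchored=False)
    arm, aln = hit
    measured = measure_extension(contig, arm, aln, params)
    if measured is None:
        return HaplotypeCall(genome_id=genome_id, arm=arm.arm,
                             contig_id=contig.map.id, anchored=True,
                             gap_assessment=GapAssessment.NO_CALL)
    rounded, raw = measured
    assessment = assess_gap(contig, arm, rounded, aln, params)
    confirmed = (confirm_telomere(contig, molecules, params)
                 if molecules else False)
    return HaplotypeCall(genome_id=genome_id, arm=arm.arm,
                         contig_id=contig.map.id, anchored=True,
                         extension_bp=rounded, extension_raw_bp=raw,
                         gap_assessment=assessment,
                         telomere_confirmed=confirmed)
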