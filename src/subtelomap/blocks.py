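"""Paralogy-block detection on consensus maps by nick-pattern matching.

A block pattern is a short label-spacing vector; detection fit-aligns the
pattern against a map in both orientations, keeps candidate hits whose
matched-label fraction and score clear the thresholds, and selects
non-overlapping hits greedily by score.  Presence calls per genome/arm
feed the population-frequency analysis; small blocks that lack enough nick
sites to stand alone are only usable through fixed, named groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentParams, align_fit
from .core import LabelMap, PipelineParams
from .simulate import BlockSpec

__all__ = ["BlockPattern", "BlockHit", "detect_blocks", "presence_matrix",
           "block_order_signature", "patterns_from_library",
           "block_detection_params"]


@dataclass(frozen=True)
class BlockPattern:
    """A block's spacing pattern plus its (possibly multi-member) group."""

    name: str
    spacings: tuple[int, ...]
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.spacings) < 2:
            raise ValueError(
                f"pattern {self.name!r}: needs >= 3 labels to be detectable "
                "on its own; smaller blocks are only usable through groups")
        if any(s <= 0 for s in self.spacings):
            raise ValueError("spacings must be positive")

    @property
    def n_labels(self) -> int:
        return len(self.spacings) + 1

    def to_map(self) -> LabelMap:
        pos = np.concatenate(([0], np.cumsum(self.spacings))).astype(np.int64)
        return LabelMap(id=f"pattern:{self.name}", length_bp=int(pos[-1]) + 1,
                        positions=pos)


def patterns_from_library(library: Mapping[str, BlockSpec]
                          ) -> list[BlockPattern]:
    return [BlockPattern(name=b.name, spacings=b.label_spacings, group=b.name)
            for b in library.values()]


@dataclass
class BlockHit:
    block: str
    map_id: str
    start_bp: int
    end_bp: int
    orientation: str
    score: float
    matched_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.matched_fraction <= 1.0:
            raise ValueError("matched fraction must lie in [0, 1]")
        if self.start_bp >= self.end_bp:
            raise ValueError("hit interval is empty")


def block_detection_params(params: PipelineParams) -> AlignmentParams:
    """Fit-alignment thresholds for short patterns (3+ labels)."""
    return AlignmentParams.from_pipeline(
        params, min_aligned_labels=3, min_score=6.0, max_skip=2)


def detect_blocks(lmap: LabelMap, patterns: Sequence[BlockPattern],
                  params: PipelineParams,
                  min_fraction: float = 0.75) -> list[BlockHit]:
    """Non-overlapping block hits on one map, greedy by score."""
    if lmap.n_labels == 0:
        return []
    ap = block_detection_params(params)
    candidates: list[BlockHit] = []
    for pattern in patterns:
        pmap = pattern.to_map()
        candidates.extend(
            _scan_pattern(lmap, pattern, pmap, ap, min_fraction,
                          0, lmap.length_bp))
    candidates.sort(key=lambda h: (-h.score, h.start_bp, h.block))
    chosen: list[BlockHit] = []
    for hit in candidates:
        if all(hit.end_bp <= c.start_bp or hit.start_bp >= c.end_bp
               for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: h.start_bp)
    return chosen


def _scan_pattern(lmap: LabelMap, pattern: BlockPattern, pmap: LabelMap,
                  ap: AlignmentParams, min_fraction: float,
                  lo: int, hi: int) -> list[BlockHit]:
    """Best hit in [lo, hi), then recurse left and right of it."""
    if hi - lo < int(pmap.length_bp * 0.5):
        return []
    segment = lmap.slice(lo, hi, new_id=lmap.id)
    if segment.n_labels < 3:
        return []
    aln = align_fit(pmap, segment, ap)
    if aln is None:
        return []
    fraction = aln.n_pairs / pattern.n_labels
    if fraction < min_fraction:
        return []
    t0, t1 = aln.target_interval
    hit = BlockHit(block=pattern.name, map_id=lmap.id,
                   start_bp=lo + t0, end_bp=lo + t1 + 1,
                   orientation=aln.orientation, score=aln.score,
                   matched_fraction=fraction)
    out = [hit]
    out.extend(_scan_pattern(lmap, pattern, pmap, ap, min_fraction,
                             lo, hit.start_bp))
    out.extend(_scan_pattern(lmap, pattern, pmap, ap, min_fraction,
                             hit.end_bp, hi))
    return out


def block_order_signature(hits: Iterable[BlockHit]) -> str:
    """Ordered block annotation string, e.g. ``"B1-2(+),B3(-)"``."""
    ordered = sorted(hits, key=lambda h: h.start_bp)
    return ",".join(f"{h.block}({h.orientation})" for h in ordered)


def presence_matrix(
    hits_by_genome_arm: Mapping[tuple[str, str], Sequence[BlockHit]],
    patterns: Sequence[BlockPattern],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Genome x (arm, block-group) boolean presence matrix.

    ``hits_by_genome_arm`` maps (genome, arm) -> hits over all anchored
    contigs of that genome-arm; a missing key means the arm had no
    anchored contig (NaN in the output).  A group is present when any of
    its member blocks has a hit.
    """
    if groups is None:
        groups = {}
        for p in patterns:
            groups.setdefault(p.group or p.name, [])
        for p in patterns:
            groups[p.group or p.name].append(p.name)
    genomes = sorted({g for g, _ in hits_by_genome_arm})
    arms = sorted({a for _, a in hits_by_genome_arm})
    columns = pd.MultiIndex.from_tuples(
        [(arm, group) for arm in arms for group in sorted(groups)],
        names=["arm", "block"])
    mat = pd.DataFrame(np.nan, index=pd.Index(genomes, name="genome"),
                       columns=columns, dtype=object)
    for (genome, arm), hits in hits_by_genome_arm.items():
        present_blocks = {h.block for h in hits}
        for group, members in groups.items():
            mat.loc[genome, (arm, group)] = bool(
                present_blocks & set(members))
    return mat
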