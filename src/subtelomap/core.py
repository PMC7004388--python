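"""Core domain types shared by every stage of the pipeline.

The universal currency is the :class:`LabelMap`: an ordered set of
fluorescent-label positions (base pairs) along a stretch of DNA, as produced
by nick-labeling with a site-specific nicking endonuclease and imaged on a
nanochannel instrument.  Reference arms, single molecules and assembled
consensus maps are all label maps with extra metadata.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "NickMotif",
    "LabelMap",
    "GapInterval",
    "ReferenceArm",
    "PipelineParams",
    "child_rng",
    "child_seed",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class NickMotif:
    """Recognition site of a nicking endonuclease.

    ``label_offset`` is the distance (bp) from the motif start to the
    reported label position on the forward strand.
    """

    name: str
    recognition: str
    label_offset: int = 0

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 5:
            raise ValueError(f"recognition sequence too short: {rec!r}")
        if not set(rec) <= _DNA:
            raise ValueError(f"recognition must be unambiguous A/C/G/T: {rec!r}")
        if self.label_offset < 0:
            raise ValueError("label_offset must be >= 0")


# Nt.BspQI, the nicking enzyme used for labeling throughout; the label is
# reported at the motif start.
NT_BSPQI = NickMotif("Nt.BspQI", "GCTCTTC", 0)


@dataclass
class LabelMap:
    """Ordered label positions along a DNA segment.

    positions are 0-based bp coordinates, strictly increasing, all within
    ``[0, length_bp)``.  ``strands`` is only populated for in-silico digests
    of sequence (one of ``'+'``/``'-'`` per label).
    """

    id: str
    length_bp: int
    positions: np.ndarray
    strands: np.ndarray | None = None
    channel: int = 1

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        self.positions = pos
        if self.length_bp < 0:
            raise ValueError("length_bp must be non-negative")
        if pos.size:
            if pos[0] < 0 or pos[-1] >= self.length_bp:
                raise ValueError(
                    f"map {self.id!r}: positions must lie in [0, {self.length_bp})"
                )
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"map {self.id!r}: positions must be strictly increasing")
        if self.strands is not None:
            strands = np.asarray(self.strands)
            if strands.shape != pos.shape:
                raise ValueError("strands must have one entry per label")
            self.strands = strands

    @property
    def n_labels(self) -> int:
        return int(self.positions.size)

    def spacings(self) -> np.ndarray:
        """Inter-label distances in bp."""
        return np.diff(self.positions)

    def slice(self, start: int, end: int, new_id: str | None = None) -> "LabelMap":
        """Labels within ``[start, end)`` re-coordinated to the slice origin."""
        if not 0 <= start < end:
            raise ValueError("need 0 <= start < end")
        sel = (self.positions >= start) & (self.positions < end)
        return LabelMap(
            id=new_id or f"{self.id}[{start}:{end}]",
            length_bp=int(end - start),
            positions=self.positions[sel] - start,
            strands=None if self.strands is None else self.strands[sel],
            channel=self.channel,
        )

    def reversed(self, new_id: str | None = None) -> "LabelMap":
        """Mirror image of the map (other strand, telomere convention flip)."""
        pos = (self.length_bp - 1) - self.positions[::-1]
        strands = None
        if self.strands is not None:
            flip = {"+": "-", "-": "+"}
            strands = np.array([flip[s] for s in self.strands[::-1]])
        return LabelMap(
            id=new_id or f"{self.id}(rev)",
            length_bp=self.length_bp,
            positions=pos,
            strands=strands,
            channel=self.channel,
        )


class GapInterval(NamedTuple):
    """A run of unknown bases (Ns), 0-based half-open."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_gaps(gaps: Sequence[GapInterval], length_bp: int) -> list[GapInterval]:
    out = [GapInterval(int(s), int(e)) for s, e in gaps]
    prev_end = -1
    for g in out:
        if not (0 <= g.start < g.end <= length_bp):
            raise ValueError(f"gap {g} outside [0, {length_bp}]")
        if g.start <= prev_end:
            raise ValueError("gap intervals must be sorted and disjoint")
        prev_end = g.end
    return out


@dataclass
class ReferenceArm:
    """A subtelomere window of one chromosome arm.

    The map is oriented so that coordinates increase toward the telomere
    (p arms are mirrored), and ``tel_end_bp`` is the annotated end of the
    arm within the window — including any terminal run of Ns, so that map
    extensions beyond it carry the sign convention of the arm summaries
    (negative = the reference over-estimates the arm, positive = the arm is
    longer than the reference).  ``onecopy_interval`` marks arm-specific
    1-copy DNA used for unambiguous anchoring; it lies centromeric
    (proximal) of all segmental-duplication annotation.
    """

    arm: str
    map: LabelMap
    gaps: list[GapInterval] = field(default_factory=list)
    window_bp: int = 500_000
    tel_end_bp: int | None = None
    onecopy_interval: GapInterval | None = None

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        self.gaps = _check_gaps(self.gaps, self.map.length_bp)
        if self.tel_end_bp is None:
            self.tel_end_bp = self.map.length_bp
        if self.tel_end_bp > self.map.length_bp:
            raise ValueError("tel_end_bp beyond the window")

    def terminal_gap(self) -> GapInterval | None:
        """The N-gap adjacent to the annotated arm end, if any."""
        if self.gaps and self.gaps[-1].end >= self.tel_end_bp:
            return self.gaps[-1]
        return None


@dataclass(frozen=True)
class PipelineParams:
    """Study-level knobs shared across stages.

    Defaults reproduce the study conditions: 10% false-positive and 10%
    false-negative label error, molecules longer than 150 kb at a mean of
    300 kb, at least 60x coverage per genome, 500-kb subtelomere windows,
    a 10-kb reporting resolution for length differences and a 10% minor
    haplotype share separating High from Low variability arms.
    """

    fp_rate: float = 0.10
    fn_rate: float = 0.10
    min_molecule_bp: int = 150_000
    mean_molecule_bp: int = 300_000
    min_coverage: float = 60.0
    window_bp: int = 500_000
    gap_resolution_bp: int = 10_000
    variability_threshold: float = 0.10
    # single-label resolving power of the instrument: labels closer than
    # this merge into one spot
    optical_resolution_bp: int = 1_500
    inp_distance_bp: int = 1_000
    sizing_cv: float = 0.02
    jitter_bp: float = 300.0
    p_break_inp: float = 0.9
    support_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate", "variability_threshold", "p_break_inp",
                     "support_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("min_molecule_bp", "mean_molecule_bp", "window_bp",
                     "gap_resolution_bp", "optical_resolution_bp", "inp_distance_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_coverage <= 0:
            raise ValueError("min_coverage must be positive")

    def with_(self, **kwargs) -> "PipelineParams":
        return replace(self, **kwargs)


def child_seed(seed: int, label: str) -> int:
    """Derive a per-stage seed from the global one.

    Stable across runs and platforms: the child is a CRC32 mix of the stage
    label folded into the global seed, kept below 2**31 so it can be passed
    anywhere a small seed is expected.
    """
    return (int(seed) * 2_654_435_761 + zlib.crc32(label.encode())) % (2**31 - 1)


def child_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label))
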