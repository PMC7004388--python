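"""In-silico reference maps: digestion, gap annotation, subtelomere windows.

A reference arm map is obtained by scanning the arm's sequence for the
nicking-enzyme recognition site on both strands (an in-silico digest),
recording runs of unknown bases (Ns) as gap intervals, and cutting out the
distal window re-oriented so coordinates increase toward the telomere.

File dialects: a simplified single-channel CMAP for label maps and BED for
gap intervals.  The CMAP dialect is tab-separated with ``#`` header lines,
columns ``CMapId ContigLength NumSites SiteID LabelChannel Position`` and a
terminal channel-0 pseudo-site whose position is the map length.  It is not
byte-compatible with vendor files; the reader tolerates extra columns.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .core import GapInterval, LabelMap, NickMotif, ReferenceArm, NT_BSPQI

__all__ = [
    "in_silico_digest",
    "find_gap_intervals",
    "extract_subtelomere_window",
    "digest_fasta",
    "read_cmap",
    "write_cmap",
    "read_bed",
    "write_bed",
    "NT_BSPQI",
]

_VALID = re.compile(r"^[ACGTNacgtn]*$")


def _validate_sequence(sequence: str) -> str:
    if not _VALID.match(sequence):
        bad = sorted(set(sequence) - set("ACGTNacgtn"))
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    return sequence.upper()


def in_silico_digest(sequence: str, motif: NickMotif = NT_BSPQI,
                     map_id: str = "digest") -> LabelMap:
    """Scan both strands for ``motif`` and return the resulting label map.

    Forward-strand occurrences label at ``start + label_offset``; reverse
    occurrences at ``end - 1 - label_offset``.  Occurrences never overlap N
    runs (the recognition site is unambiguous).  When a forward and a
    reverse label coincide a single label is kept, ``'+'`` preferred.
    """
    seq = _validate_sequence(sequence)
    rec = motif.recognition
    k = len(rec)
    hits: dict[int, str] = {}
    rc = str(Seq(rec).reverse_complement())
    # overlapping occurrences via lookahead
    for m in re.finditer(f"(?={re.escape(rc)})", seq):
        s = m.start()
        hits[s + k - 1 - motif.label_offset] = "-"
    for m in re.finditer(f"(?={re.escape(rec)})", seq):
        hits[m.start() + motif.label_offset] = "+"  # '+' wins coincidences
    pos = np.array(sorted(hits), dtype=np.int64)
    strands = np.array([hits[p] for p in pos]) if pos.size else np.empty(0, dtype="<U1")
    return LabelMap(id=map_id, length_bp=len(seq), positions=pos, strands=strands)


def find_gap_intervals(sequence: str) -> list[GapInterval]:
    """Maximal runs of N as sorted 0-based half-open intervals."""
    seq = _validate_sequence(sequence)
    return [GapInterval(m.start(), m.end()) for m in re.finditer(r"N+", seq)]


def extract_subtelomere_window(
    chrom_map: LabelMap,
    gaps: Sequence[GapInterval],
    arm: str,
    window_bp: int = 500_000,
    onecopy_interval: GapInterval | None = None,
) -> ReferenceArm:
    """Cut the distal ``window_bp`` of an arm, telomere-distal-increasing.

    For q arms this is the last ``window_bp`` of the chromosome shifted to
    the origin; for p arms the first ``window_bp`` mirrored, so that in both
    cases position increases toward the telomere and the annotated arm end
    sits at the window end.  Applying the p-arm mirror twice restores the
    input.  Gap intervals are re-coordinated the same way.
    """
    if not arm or arm[-1] not in "pq":
        raise ValueError(f"arm must end in 'p' or 'q': {arm!r}")
    L = chrom_map.length_bp
    w = window_bp
    if L < window_bp:
        warnings.warn(
            f"{arm}: chromosome ({L} bp) shorter than window ({window_bp} bp); "
            "using the full length", stacklevel=2)
        w = L
    if arm[-1] == "q":
        win = chrom_map.slice(L - w, L, new_id=arm)
        win_gaps = [
            GapInterval(max(g.start, L - w) - (L - w), g.end - (L - w))
            for g in gaps if g.end > L - w
        ]
    else:
        win = chrom_map.slice(0, w, new_id=arm).reversed(new_id=arm)
        win_gaps = sorted(
            GapInterval(w - min(g.end, w), w - g.start)
            for g in gaps if g.start < w
        )
    return ReferenceArm(arm=arm, map=win, gaps=win_gaps, window_bp=w,
                        tel_end_bp=w, onecopy_interval=onecopy_interval)


def digest_fasta(path: str | Path, motif: NickMotif = NT_BSPQI
                 ) -> list[tuple[LabelMap, list[GapInterval]]]:
    """Digest every record of a FASTA file; returns (map, gaps) per record."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        out.append((in_silico_digest(seq, motif, map_id=rec.id),
                    find_gap_intervals(seq)))
    return out


# ---------------------------------------------------------------------------
# simplified CMAP dialect

_CMAP_COLUMNS = ["CMapId", "ContigLength", "NumSites", "SiteID",
                 "LabelChannel", "Position"]


def write_cmap(maps: Iterable[LabelMap], path: str | Path,
               comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("# subtelomap simplified CMAP\n")
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("#h " + "\t".join(_CMAP_COLUMNS) + "\n")
        for m in maps:
            n = m.n_labels
            for i, p in enumerate(m.positions, start=1):
                fh.write(f"{m.id}\t{m.length_bp}\t{n}\t{i}\t{m.channel}\t{int(p)}\n")
            # terminal pseudo-site marks the map length
            fh.write(f"{m.id}\t{m.length_bp}\t{n}\t{n + 1}\t0\t{m.length_bp}\n")


class CmapParseError(ValueError):
    pass


def read_cmap(path: str | Path) -> list[LabelMap]:
    """Read the simplified CMAP dialect; extra columns are tolerated."""
    header: list[str] | None = None
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#h "):
                    header = line[3:].split("\t")
                continue
            cols = header or _CMAP_COLUMNS
            fields = line.split("\t")
            if len(fields) < len(_CMAP_COLUMNS):
                raise CmapParseError(f"{path}:{lineno}: expected at least "
                                     f"{len(_CMAP_COLUMNS)} columns")
            try:
                rec = dict(zip(cols, fields))
                map_id = rec["CMapId"]
                length = int(float(rec["ContigLength"]))
                channel = int(rec["LabelChannel"])
                position = int(float(rec["Position"]))
            except (KeyError, ValueError) as exc:
                raise CmapParseError(f"{path}:{lineno}: {exc}") from exc
            if map_id not in rows:
                rows[map_id] = {"length": length, "positions": [], "channel": 1}
                order.append(map_id)
            if channel == 0:
                if position != rows[map_id]["length"]:
                    raise CmapParseError(
                        f"{path}:{lineno}: terminal pseudo-site position "
                        f"{position} != contig length {rows[map_id]['length']}")
            else:
                rows[map_id]["positions"].append(position)
                rows[map_id]["channel"] = channel
    out = []
    for map_id in order:
        rec = rows[map_id]
        pos = rec["positions"]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise CmapParseError(
                f"{path}: map {map_id!r} has unsorted or duplicate positions")
        out.append(LabelMap(id=map_id, length_bp=rec["length"],
                            positions=np.array(pos, dtype=np.int64),
                            channel=rec["channel"]))
    return out


# ---------------------------------------------------------------------------
# BED (0-based half-open) for gap intervals

def write_bed(intervals: Iterable[tuple[str, GapInterval]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, g in intervals:
            fh.write(f"{name}\t{g.start}\t{g.end}\n")


def read_bed(path: str | Path) -> dict[str, list[GapInterval]]:
    out: dict[str, list[GapInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs 3 columns")
            out.setdefault(fields[0], []).append(
                GapInterval(int(fields[1]), int(fields[2])))
    for name in out:
        out[name].sort()
    return out
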