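"""Overlap-layout-consensus assembly of single-molecule label maps.

All molecules are compared pairwise with dovetail alignments; edges that
pass the score threshold form the overlap graph.  Spurious edges (offset
triangles that do not close) and transitively redundant edges are removed,
leaving a DAG per connected component.  The heaviest path (by summed edge
score) defines the layout; a consensus map is derived from the labels of
the path molecules, then refined by re-fitting every molecule to the
consensus, recomputing label positions as per-cluster medians and growing
the ends from labels that hang beyond them.  Molecules that repeatedly
fail to fit the consensus (the signature of a second haplotype with a
divergent distal pattern) are re-assembled in a second pass, which is how
heterozygous arms yield two contigs.  Overlapping consensus maps whose
telomeric termini agree are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .align import Alignment, AlignmentParams, align_fit, align_overlap
from .core import LabelMap, PipelineParams

__all__ = ["ConsensusMap", "AssemblyResult", "build_overlap_graph",
           "layout_and_consensus", "refine_and_extend", "merge_consensus",
           "assemble_arm"]


@dataclass
class ConsensusMap:
    """An assembled consensus label map with per-label molecule support."""

    map: LabelMap
    support: np.ndarray
    n_molecules: int
    coverage: float
    # molecule id -> (offset of its origin in consensus coords, placed end)
    placements: dict[str, tuple[float, float]] = field(default_factory=dict)
    terminus_bp: float = 0.0
    unplaced: list[str] = field(default_factory=list)
    # placed molecules showing an interior run of consecutive unmatched
    # labels: the local signature of a second haplotype
    divergent: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.support.shape[0] != self.map.n_labels:
            raise ValueError("one support count per consensus label")
        if np.any(self.support > self.n_molecules):
            raise ValueError("support cannot exceed the number of molecules")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")

    def placed_ends(self) -> np.ndarray:
        return np.array([end for _, end in self.placements.values()])

    def end_is_anchored(self, tol_bp: float = 5_000.0, min_ends: int = 5) -> bool:
        """True when molecule ends pile up at the terminus.

        A pile of placed molecule ends at the terminus means the molecules
        themselves stop there (a telomere or a fragile site), as opposed to
        a mere coverage boundary where ends are scattered.
        """
        ends = self.placed_ends()
        return int(np.sum(np.abs(ends - self.terminus_bp) <= tol_bp)) >= min_ends


@dataclass
class AssemblyResult:
    contigs: list[ConsensusMap]
    failed_molecules: list[str]
    n_molecules: int


# ---------------------------------------------------------------------------
# overlap graph

def build_overlap_graph(molecules: list[LabelMap], params: PipelineParams,
                        align_params: AlignmentParams | None = None) -> nx.DiGraph:
    """All-vs-all dovetail comparison, then spurious-edge and transitive pruning.

    Edge u->v means v starts at ``offset`` bp to the right of u.  Reverse-
    orientation dovetails are treated as spurious: molecules enter this
    pipeline strand-resolved.
    """
    if not molecules:
        raise ValueError("need at least one molecule")
    ap = align_params or AlignmentParams.from_pipeline(params)
    g = nx.DiGraph()
    by_id = {}
    for m in molecules:
        if m.id in by_id:
            raise ValueError(f"duplicate molecule id {m.id!r}")
        by_id[m.id] = m
        g.add_node(m.id, length=m.length_bp)
    for i, a in enumerate(molecules):
        for b in molecules[i + 1:]:
            aln = align_overlap(a, b, ap)
            if aln is None or aln.orientation != "+":
                continue
            off = float(aln.offset_bp)
            if off >= 0:
                g.add_edge(a.id, b.id, offset=off, score=aln.score,
                           orientation="+", n_pairs=aln.n_pairs)
            else:
                g.add_edge(b.id, a.id, offset=-off, score=aln.score,
                           orientation="+", n_pairs=aln.n_pairs)
    _prune_inconsistent_triangles(g, tol_bp=4 * params.optical_resolution_bp)
    _break_cycles(g)
    g = _transitive_reduction(g)
    return g


def _prune_inconsistent_triangles(g: nx.DiGraph, tol_bp: float) -> None:
    doomed = set()
    for u in g:
        for v in g.successors(u):
            for w in g.successors(v):
                if not g.has_edge(u, w):
                    continue
                gap = abs(g[u][v]["offset"] + g[v][w]["offset"]
                          - g[u][w]["offset"])
                if gap > tol_bp:
                    trio = [(u, v), (v, w), (u, w)]
                    doomed.add(min(trio, key=lambda e: g[e[0]][e[1]]["score"]))
    g.remove_edges_from(doomed)


def _break_cycles(g: nx.DiGraph) -> None:
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        weakest = min(cycle, key=lambda e: g[e[0]][e[1]]["score"])
        g.remove_edge(weakest[0], weakest[1])


def _transitive_reduction(g: nx.DiGraph) -> nx.DiGraph:
    tr = nx.transitive_reduction(g)
    tr.add_nodes_from(g.nodes(data=True))
    tr.add_edges_from((u, v, g[u][v]) for u, v in tr.edges())
    return tr


# ---------------------------------------------------------------------------
# layout + consensus

def _cluster_labels(placed: list[tuple[float, str]], width: float,
                    depth_fn) -> tuple[np.ndarray, np.ndarray]:
    """Greedy 1-D clustering of placed labels.

    ``placed`` is (position, molecule id); a new cluster starts when the
    next label lies more than ``width`` from the cluster's first label.
    Returns (median positions, distinct-molecule support) for clusters
    whose support reaches ``depth_fn`` of the local depth.
    """
    if not placed:
        return np.empty(0), np.empty(0, dtype=int)
    placed = sorted(placed)
    clusters: list[list[tuple[float, str]]] = [[placed[0]]]
    for item in placed[1:]:
        if item[0] - clusters[-1][0][0] > width:
            clusters.append([item])
        else:
            clusters[-1].append(item)
    pos_out, sup_out = [], []
    for cl in clusters:
        center = float(np.median([p for p, _ in cl]))
        support = len({mid for _, mid in cl})
        if support >= depth_fn(center):
            pos_out.append(center)
            sup_out.append(support)
    return np.array(pos_out), np.array(sup_out, dtype=int)


def _consensus_from_placements(
    placements: dict[str, float],
    by_id: dict[str, LabelMap],
    params: PipelineParams,
    consensus_id: str,
) -> ConsensusMap | None:
    placed_labels: list[tuple[float, str]] = []
    spans: list[tuple[float, float]] = []
    for mid, off in placements.items():
        m = by_id[mid]
        spans.append((off, off + m.length_bp))
        placed_labels.extend((off + float(p), mid) for p in m.positions)
    starts = np.array([s for s, _ in spans])
    ends = np.array([e for _, e in spans])

    def local_depth(center: float) -> int:
        depth = int(np.sum((starts <= center) & (ends >= center)))
        floor = max(2, int(np.ceil(params.support_fraction * depth)))
        return min(floor, len(placements))

    pos, sup = _cluster_labels(placed_labels, params.optical_resolution_bp,
                               local_depth)
    if pos.size == 0:
        return None
    origin = float(starts.min())
    pos = pos - origin
    ends_sh = ends - origin
    starts_sh = starts - origin
    # the terminus is the median of the distal pile of molecule ends
    emax = float(ends_sh.max())
    pile = ends_sh[ends_sh >= emax - 5_000.0]
    terminus = float(np.median(pile))
    length = int(np.ceil(emax)) + 1
    ipos = np.round(pos).astype(np.int64)
    keep = np.concatenate(([True], np.diff(ipos) > 0))
    ipos, sup = ipos[keep], sup[keep]
    span_bp = max(length, 1)
    coverage = float(np.sum(ends_sh - starts_sh)) / span_bp
    cmap = LabelMap(id=consensus_id, length_bp=length, positions=ipos)
    return ConsensusMap(
        map=cmap, support=sup, n_molecules=len(placements), coverage=coverage,
        placements={mid: (off - origin, off - origin + by_id[mid].length_bp)
                    for mid, off in placements.items()},
        terminus_bp=terminus,
    )


def layout_and_consensus(graph: nx.DiGraph, molecules: list[LabelMap],
                         params: PipelineParams,
                         min_component: int = 3) -> list[ConsensusMap]:
    """Heaviest path per component -> molecule placements -> draft consensus.

    Components smaller than ``min_component`` molecules are reported as
    failed to assemble (they are simply absent from the output).
    """
    by_id = {m.id: m for m in molecules}
    out = []
    for k, comp in enumerate(nx.weakly_connected_components(graph)):
        if len(comp) < min_component:
            continue
        sub = graph.subgraph(comp)
        path = nx.dag_longest_path(sub, weight="score")
        placements: dict[str, float] = {path[0]: 0.0}
        for u, v in zip(path, path[1:]):
            placements[v] = placements[u] + sub[u][v]["offset"]
        cons = _consensus_from_placements(placements, by_id, params,
                                          consensus_id=f"contig_{k}")
        if cons is not None:
            out.append(cons)
    return out


# ---------------------------------------------------------------------------
# refinement

def _placement_from_alignment(aln: Alignment, mol: LabelMap,
                              target_positions: np.ndarray) -> float:
    deltas = [float(target_positions[j]) - float(mol.positions[i])
              for i, j in aln.pairs]
    return float(np.median(deltas))


def _fits(aln: Alignment | None, mol: LabelMap, cons_map: LabelMap,
          min_query_frac: float = 0.65, min_target_frac: float = 0.60) -> bool:
    """Agreement criterion for counting a molecule as placed.

    Both sides matter: the molecule's own labels must mostly match the
    consensus (query fraction) and the consensus labels inside the
    molecule's span must mostly be matched back (target fraction) — a
    molecule from a divergent haplotype fails one side or the other.
    """
    if aln is None or aln.orientation != "+":
        return False
    if aln.n_pairs / mol.n_labels < min_query_frac:
        return False
    lo, hi = aln.target_interval
    in_span = int(np.sum((cons_map.positions >= lo) & (cons_map.positions <= hi)))
    return in_span == 0 or aln.n_pairs / in_span >= min_target_frac


def refine_and_extend(consensus: ConsensusMap, molecules: list[LabelMap],
                      params: PipelineParams,
                      align_params: AlignmentParams | None = None,
                      max_rounds: int = 5) -> ConsensusMap:
    """Re-fit every molecule, recompute label positions, grow the ends.

    Each round re-fit-aligns every molecule to the consensus.  A consensus
    label's position is recomputed as the median of the molecule labels the
    alignments match to it (so cluster identity comes from the sizing-aware
    DP match, not from re-clustering noisy placements), and it is kept only
    while its matched support clears the support fraction of the local
    depth.  Unmatched molecule labels — including those hanging beyond
    either end — are pooled, clustered, and promoted to new consensus
    labels when they reach the same support away from existing labels.
    Iterates to a fixed point (no label added or removed and no label
    moving more than 100 bp) or for ``max_rounds`` rounds.  Molecules that
    do not fit the final consensus end up in ``unplaced``.
    """
    ap = align_params or AlignmentParams.from_pipeline(params)
    current = consensus
    for _ in range(max_rounds):
        new = _refine_round(current, molecules, params, ap)
        if new is None:
            return current
        done = _converged(current.map, new.map)
        current = new
        if done:
            break
    return current


def _refine_round(current: ConsensusMap, molecules: list[LabelMap],
                  params: PipelineParams,
                  ap: AlignmentParams) -> ConsensusMap | None:
    res = params.optical_resolution_bp
    by_id = {m.id: m for m in molecules}
    n_cons = current.map.n_labels
    matched: list[list[float]] = [[] for _ in range(n_cons)]
    matched_mols: list[set[str]] = [set() for _ in range(n_cons)]
    pool: list[tuple[float, str]] = []
    placements: dict[str, float] = {}
    spans: list[tuple[float, float]] = []
    unplaced: list[str] = []
    divergent: list[str] = []
    cons_first = float(current.map.positions[0])
    cons_last = float(current.map.positions[-1])
    for m in molecules:
        aln = align_fit(m, current.map, ap)
        if not _fits(aln, m, current.map):
            unplaced.append(m.id)
            continue
        off = _placement_from_alignment(aln, m, current.map.positions)
        placements[m.id] = off
        paired_q = set()
        for i, j in aln.pairs:
            matched[j].append(off + float(m.positions[i]))
            matched_mols[j].add(m.id)
            paired_q.add(i)
        unmatched = [i for i in range(m.n_labels) if i not in paired_q]
        if _interior_run(unmatched, m, off, cons_first + res,
                         cons_last - res) >= 3:
            # a second-haplotype molecule: its matched (shared) span still
            # supports this consensus, but its unmatched labels and its
            # overhang beyond the matched region must not shape it
            divergent.append(m.id)
            qlo, qhi = aln.query_interval
            spans.append((off + float(qlo), off + float(qhi)))
        else:
            spans.append((off, off + m.length_bp))
            pool.extend((off + float(m.positions[i]), m.id)
                        for i in unmatched)
    if len(placements) < 2:
        return None
    starts = np.array([s for s, _ in spans])
    ends = np.array([e for _, e in spans])

    def min_support(center: float) -> int:
        depth = int(np.sum((starts <= center) & (ends >= center)))
        floor = max(2, int(np.ceil(params.support_fraction * depth)))
        return min(floor, len(placements))

    labels: list[tuple[float, int]] = []
    for j in range(n_cons):
        if not matched[j]:
            continue
        pos = float(np.median(matched[j]))
        if len(matched_mols[j]) >= min_support(pos):
            labels.append((pos, len(matched_mols[j])))
    # grow the ends: well-supported clusters of unmatched labels hanging
    # beyond the consensus are appended (FP labels stay below the support
    # floor).  Interior insertions are not allowed — interior unmatched
    # labels are the signature of a second haplotype, not of a consensus
    # defect, and belong in the second-pass assembly.
    kept_pos = np.array(sorted(p for p, _ in labels))
    cand_pos, cand_sup = _cluster_labels(pool, res, min_support)
    for p, s in zip(cand_pos, cand_sup):
        beyond = (kept_pos.size == 0
                  or p < kept_pos[0] - res or p > kept_pos[-1] + res)
        if beyond:
            labels.append((float(p), int(s)))
    if not labels:
        return None
    labels = _merge_consensus_labels(sorted(labels), res)
    origin = float(starts.min())
    pos = np.round(np.array([p for p, _ in labels]) - origin).astype(np.int64)
    sup = np.array([s for _, s in labels], dtype=int)
    keep = np.concatenate(([True], np.diff(pos) > 0))
    pos, sup = pos[keep], sup[keep]
    ends_sh = ends - origin
    emax = float(ends_sh.max())
    pile = ends_sh[ends_sh >= emax - 5_000.0]
    length = int(np.ceil(emax)) + 1
    cmap = LabelMap(id=current.map.id, length_bp=length, positions=pos)
    coverage = float(np.sum(ends_sh - (starts - origin))) / max(length, 1)
    return ConsensusMap(
        map=cmap, support=sup, n_molecules=len(placements),
        coverage=coverage,
        placements={mid: (off - origin, off - origin + by_id[mid].length_bp)
                    for mid, off in placements.items()},
        terminus_bp=float(np.median(pile)), unplaced=unplaced,
        divergent=divergent)


def _interior_run(unmatched: list[int], m: LabelMap, offset: float,
                  lo: float, hi: float) -> int:
    """Longest run of consecutive unmatched labels projecting inside
    [lo, hi] of the consensus (labels hanging beyond the ends are the
    normal extension signal, not divergence)."""
    best = run = 0
    prev = None
    for i in unmatched:
        p = offset + float(m.positions[i])
        if not lo <= p <= hi:
            prev = None
            continue
        run = run + 1 if prev == i - 1 else 1
        best = max(best, run)
        prev = i
    return best


def _merge_consensus_labels(labels: list[tuple[float, int]],
                            resolution_bp: float) -> list[tuple[float, int]]:
    """Collapse consensus labels closer than the optical resolution."""
    out: list[tuple[float, int]] = []
    for pos, sup in labels:
        if out and pos - out[-1][0] < resolution_bp:
            p0, s0 = out[-1]
            total = s0 + sup
            out[-1] = ((p0 * s0 + pos * sup) / total, max(s0, sup))
        else:
            out.append((pos, sup))
    return out


def _converged(a: LabelMap, b: LabelMap, move_tol: float = 100.0) -> bool:
    if a.n_labels != b.n_labels:
        return False
    return bool(np.all(np.abs(a.positions - b.positions) <= move_tol))


def _het_split_pool(contig: ConsensusMap, molecules: list[LabelMap],
                    params: PipelineParams, ap: AlignmentParams,
                    min_window: int = 3, min_depth: int = 8,
                    frac_threshold: float = 0.7) -> list[str]:
    """Molecules forming the minority haplotype of a mixed consensus.

    A consensus built over a heterozygous region shows a run of labels
    whose support is only a fraction of the local depth (each haplotype's
    molecules support only its own labels).  When such a window exists,
    the molecules covering it are partitioned into two groups by the
    pattern of window labels they match (2-medoid clustering on the match
    vectors), and the smaller group is returned for re-assembly.
    """
    pos = contig.map.positions.astype(float)
    starts = np.array([s for s, _ in contig.placements.values()])
    ends = np.array([e for _, e in contig.placements.values()])
    depth = np.array([np.sum((starts <= p) & (ends >= p)) for p in pos])
    frac = np.where(depth > 0, contig.support / np.maximum(depth, 1), 1.0)
    low = (frac < frac_threshold) & (depth >= min_depth)
    window = _longest_true_run(low)
    if window is None or window[1] - window[0] + 1 < min_window:
        return []
    w_lo, w_hi = pos[window[0]], pos[window[1]]
    by_id = {m.id: m for m in molecules}
    rows, row_ids = [], []
    for mid, (off, end) in contig.placements.items():
        if off > w_lo - 5_000 or end < w_hi + 5_000:
            continue  # must span the whole window to vote
        m = by_id.get(mid)
        if m is None:
            continue
        aln = align_fit(m, contig.map, ap)
        if aln is None:
            continue
        matched_j = {j for _, j in aln.pairs}
        rows.append([1.0 if j in matched_j else 0.0
                     for j in range(window[0], window[1] + 1)])
        row_ids.append(mid)
    if len(rows) < 6:
        return []
    groups = _two_medoid_split(np.array(rows))
    sizes = [int(np.sum(groups == g)) for g in (0, 1)]
    if min(sizes) < 3:
        return []
    minority = int(np.argmin(sizes))
    return [row_ids[i] for i in range(len(row_ids)) if groups[i] == minority]


def _end_pile_pool(contig: ConsensusMap, params: PipelineParams,
                   pile_tol_bp: float = 4_000.0,
                   min_pile: int = 6) -> list[str]:
    """Molecules whose ends pile up at an interior position of the contig.

    Molecule ends pile up where molecules physically stop — at a telomere
    or a fragile site.  A pile well inside the contig (more than the
    reporting resolution short of the terminus) while coverage continues
    beyond it is the signature of a shorter co-assembled haplotype; the
    molecules ending in the pile are returned for separate assembly.
    """
    items = list(contig.placements.items())
    ends = np.array([e for _, (_, e) in items])
    starts = np.array([s for _, (s, _) in items])
    lo = float(starts.min()) + params.min_molecule_bp / 2
    hi = contig.terminus_bp - 2 * params.gap_resolution_bp
    best: tuple[int, float] | None = None
    for e in ends:
        if not lo <= e <= hi:
            continue
        n = int(np.sum(np.abs(ends - e) <= pile_tol_bp))
        depth = int(np.sum((starts <= e) & (ends >= e)))
        if n >= max(min_pile, int(0.2 * depth)) \
                and (best is None or n > best[0]):
            best = (n, float(e))
    if best is None:
        return []
    center = float(np.median(ends[np.abs(ends - best[1]) <= pile_tol_bp]))
    return [mid for mid, (_, e) in items if abs(e - center) <= pile_tol_bp]


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    best = None
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if best is None or i - start > best[1] - best[0] + 1:
                best = (start, i - 1)
            start = None
    if start is not None and (best is None
                              or len(mask) - start > best[1] - best[0] + 1):
        best = (start, len(mask) - 1)
    return best


def _two_medoid_split(rows: np.ndarray, iters: int = 8) -> np.ndarray:
    """Partition match vectors into two groups (Hamming 2-medoid)."""
    n = rows.shape[0]
    d = np.abs(rows[:, None, :] - rows[None, :, :]).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    medoids = [i, j]
    assign = np.zeros(n, dtype=int)
    for _ in range(iters):
        assign = np.where(d[:, medoids[0]] <= d[:, medoids[1]], 0, 1)
        new = []
        for g in (0, 1):
            members = np.flatnonzero(assign == g)
            if members.size == 0:
                return assign
            within = d[np.ix_(members, members)].sum(axis=1)
            new.append(int(members[np.argmin(within)]))
        if new == medoids:
            break
        medoids = new
    return assign


def _competitive_refine(contigs: list[ConsensusMap], molecules: list[LabelMap],
                        params: PipelineParams, ap: AlignmentParams,
                        rounds: int = 2,
                        score_margin: float = 3.0) -> list[ConsensusMap]:
    """Joint refinement of co-existing haplotype contigs.

    Each round, every molecule is fit-aligned to every contig and assigned
    to the contig(s) within ``score_margin`` of its best score; each contig
    is then refined using only its supporters.  Molecules from the shared
    (1-copy) portion of the arm tie and support all contigs; molecules
    spanning a divergent region score clearly higher on their own
    haplotype, which keeps each consensus pure.
    """
    for _ in range(rounds):
        scores: dict[str, dict[int, float]] = {}
        for m in molecules:
            per: dict[int, float] = {}
            for k, c in enumerate(contigs):
                aln = align_fit(m, c.map, ap)
                if _fits(aln, m, c.map):
                    per[k] = aln.score
            scores[m.id] = per
        new_contigs = []
        for k, c in enumerate(contigs):
            supporters = [m for m in molecules
                          if k in scores[m.id]
                          and scores[m.id][k] >= max(scores[m.id].values())
                          - score_margin]
            if len(supporters) < 3:
                continue
            refined = _refine_round(c, supporters, params, ap)
            new_contigs.append(refined if refined is not None else c)
        contigs = new_contigs
        if len(contigs) < 2:
            break
    return contigs


# ---------------------------------------------------------------------------
# merging

def merge_consensus(contigs: list[ConsensusMap], molecules: list[LabelMap],
                    params: PipelineParams,
                    align_params: AlignmentParams | None = None
                    ) -> list[ConsensusMap]:
    """Merge overlapping consensus maps of the same haplotype; idempotent.

    Two maps merge when their dovetail alignment is strong and their
    telomeric (distal) termini are compatible: either the termini agree
    within the reporting resolution, or the map that stops short does so at
    a plain coverage boundary rather than at a pile of molecule ends.  Two
    haplotypes that differ by a terminal insertion keep distinct,
    end-anchored termini and are therefore never merged.
    """
    ap = align_params or AlignmentParams.from_pipeline(params)
    by_id = {m.id: m for m in molecules}
    work = list(contigs)
    merged_any = True
    while merged_any and len(work) > 1:
        merged_any = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                a, b = work[i], work[j]
                if _mergeable(a, b, params, ap):
                    union = dict(a.placements)
                    union.update(b.placements)
                    seed = _consensus_from_placements(
                        {mid: off for mid, (off, _) in union.items()
                         if mid in by_id},
                        by_id, params, consensus_id=a.map.id)
                    if seed is None:
                        continue
                    pool = [by_id[mid] for mid in union if mid in by_id]
                    new = refine_and_extend(seed, pool, params, ap)
                    work = [c for k, c in enumerate(work) if k not in (i, j)]
                    work.append(new)
                    merged_any = True
                    break
            if merged_any:
                break
    return work


def _mergeable(a: ConsensusMap, b: ConsensusMap, params: PipelineParams,
               ap: AlignmentParams) -> bool:
    aln = align_overlap(a.map, b.map, ap)
    if aln is None or aln.orientation != "+":
        return False
    # agreement over the shared span, on both maps
    lo_a, hi_a = aln.target_interval
    lo_b, hi_b = aln.query_interval
    n_a = int(np.sum((a.map.positions >= lo_a) & (a.map.positions <= hi_a)))
    n_b = int(np.sum((b.map.positions >= lo_b) & (b.map.positions <= hi_b)))
    if min(n_a, n_b) == 0 or aln.n_pairs / max(n_a, 1) < 0.75 \
            or aln.n_pairs / max(n_b, 1) < 0.75:
        return False
    off = float(aln.offset_bp)
    end_a = a.terminus_bp
    end_b = b.terminus_bp + off
    if abs(end_a - end_b) < params.gap_resolution_bp:
        return True
    short, _long = (a, b) if end_a < end_b else (b, a)
    return not short.end_is_anchored()


# ---------------------------------------------------------------------------
# driver

def assemble_arm(molecules: list[LabelMap], params: PipelineParams,
                 align_params: AlignmentParams | None = None) -> AssemblyResult:
    """Full per-arm assembly: graph, layout, refinement, haplotype second
    pass, merging.

    Only molecules at least ``min_molecule_bp`` long enter the assembly —
    the study's length filter; fragments from fragile-site (INP) breakage
    mostly fall below it, which is why INP arms struggle to reach the
    telomere.
    """
    ap = align_params or AlignmentParams.from_pipeline(params)
    all_ids = [m.id for m in molecules]
    molecules = [m for m in molecules if m.length_bp >= params.min_molecule_bp]
    if not molecules:
        return AssemblyResult(contigs=[], failed_molecules=all_ids,
                              n_molecules=len(all_ids))
    graph = build_overlap_graph(molecules, params, ap)
    drafts = layout_and_consensus(graph, molecules, params)
    contigs = [refine_and_extend(d, molecules, params, ap) for d in drafts]
    contigs = [c for c in contigs if c.map.n_labels >= 3]
    # molecules placed on no contig, plus placed molecules carrying an
    # interior divergence signature, may belong to a second haplotype
    placed: set[str] = set()
    flagged: set[str] = set()
    for c in contigs:
        placed.update(c.placements)
        flagged.update(c.divergent)
        flagged.update(_het_split_pool(c, molecules, params, ap))
        flagged.update(_end_pile_pool(c, params))
    misfits = [m for m in molecules if m.id not in placed or m.id in flagged]
    if len(misfits) >= 3:
        sub_graph = build_overlap_graph(misfits, params, ap)
        sub_drafts = layout_and_consensus(sub_graph, misfits, params)
        for k, d in enumerate(sub_drafts):
            d.map.id = f"{d.map.id}_alt{k}"
            # consolidate against the founding molecules only, then let the
            # competitive round hand it every molecule that prefers it
            refined = refine_and_extend(d, misfits, params, ap)
            if refined.map.n_labels >= 3 and refined.n_molecules >= 3:
                contigs.append(refined)
    if len(contigs) > 1:
        contigs = _competitive_refine(contigs, molecules, params, ap)
    contigs = merge_consensus(contigs, molecules, params, ap)
    placed = set()
    for c in contigs:
        placed.update(c.placements)
    failed = [mid for mid in all_ids if mid not in placed]
    return AssemblyResult(contigs=contigs, failed_molecules=failed,
                          n_molecules=len(all_ids))
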