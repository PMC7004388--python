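"""Pairwise alignment of label maps by dynamic programming.

Scoring follows the standard likelihood formulation for restriction/nick
map alignment (Valouev-style): matched intervals are rewarded and charged a
Gaussian sizing-error term, while unmatched labels are charged per-event
penalties derived from the labeling false-positive and false-negative
rates.  A *chunk* is one matched label pair together with the labels
skipped since the previous matched pair:

    chunk = reward - (dq - dr)^2 / (2 * (cv^2 * dr^2 + 2 * jitter^2))
            - nq_skipped * fp_penalty - nr_skipped * fn_penalty

where ``dq``/``dr`` are the query/reference interval lengths and the
variance combines multiplicative sizing error on the interval with
additive position jitter at both flanking labels.

Two alignment modes are provided:

``align_fit``
    global in the query, local in the target — used to place a molecule or
    a pattern on a longer map.  Leading/trailing unmatched query labels pay
    the false-positive penalty.
``align_overlap``
    dovetail (suffix-prefix, including containment) — used for the
    all-vs-all molecule comparison of the assembler.  At each end the side
    with fewer outstanding labels is treated as lying inside the overlap
    and pays per-label penalties; the other side's overhang is free.

Both search the two orientations and break ties deterministically (lowest
target offset, then '+').
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import LabelMap, PipelineParams

__all__ = ["AlignmentParams", "Alignment", "chunk_score", "align_fit",
           "align_overlap", "estimate_null_scores"]

_EPS = 1e-9
_NEG = -1e18


@dataclass(frozen=True)
class AlignmentParams:
    sizing_cv: float = 0.02
    jitter_bp: float = 300.0
    fp_penalty: float = -math.log(0.10)
    fn_penalty: float = -math.log(0.10)
    match_reward: float = 3.0
    min_aligned_labels: int = 9
    # calibrated on the random-map null (estimate_null_scores): the best
    # dovetail score between unrelated maps stays below ~10.5, so 12 keeps
    # the random-map false-discovery rate under 1%
    min_score: float = 12.0
    max_skip: int = 3

    def __post_init__(self) -> None:
        if self.fp_penalty < 0 or self.fn_penalty < 0:
            raise ValueError("penalties must be >= 0")
        if self.max_skip < 1:
            raise ValueError("max_skip must be >= 1")

    @classmethod
    def from_pipeline(cls, params: PipelineParams, **overrides) -> "AlignmentParams":
        kw = dict(
            sizing_cv=params.sizing_cv,
            jitter_bp=params.jitter_bp,
            fp_penalty=-math.log(max(params.fp_rate, 1e-6)),
            fn_penalty=-math.log(max(params.fn_rate, 1e-6)),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class Alignment:
    query_id: str
    target_id: str
    orientation: str  # '+' or '-'
    pairs: list[tuple[int, int]]  # (query label index, target label index)
    score: float
    query_interval: tuple[int, int] = (0, 0)  # aligned bp span in query coords
    target_interval: tuple[int, int] = (0, 0)
    offset_bp: float | None = None  # dovetail: query origin in target coords

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("alignment score must be finite")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def chunk_score(dq: float, dr: float, nq_skipped: int, nr_skipped: int,
                params: AlignmentParams) -> float:
    """Score of one matched chunk; see the module docstring for the model."""
    if dq <= 0 or dr <= 0:
        raise ValueError("interval lengths must be positive")
    var = params.sizing_cv**2 * dr**2 + 2.0 * params.jitter_bp**2
    return (params.match_reward
            - (dq - dr) ** 2 / (2.0 * var)
            - nq_skipped * params.fp_penalty
            - nr_skipped * params.fn_penalty)


# ---------------------------------------------------------------------------
# DP kernel.  mode 0 = fit (global-in-query / local-in-target),
# mode 1 = dovetail overlap.  Returns (best, end_i, end_j, back_i, back_j).

@njit(cache=True)
def _dp(q, t, cv, jit, fp_pen, fn_pen, reward, max_skip, mode):
    nq = q.shape[0]
    nt = t.shape[0]
    S = np.full((nq, nt), _NEG)
    back_i = np.full((nq, nt), -1, dtype=np.int32)
    back_j = np.full((nq, nt), -1, dtype=np.int32)
    two_j2 = 2.0 * jit * jit
    for i in range(nq):
        for j in range(nt):
            if mode == 0:
                best = reward - fp_pen * i
            else:
                a = fp_pen * i
                b = fn_pen * j
                best = reward - (a if a < b else b)
            bi = -1
            bj = -1
            di_max = i if i < max_skip + 1 else max_skip + 1
            dj_max = j if j < max_skip + 1 else max_skip + 1
            for di in range(1, di_max + 1):
                dq = q[i] - q[i - di]
                for dj in range(1, dj_max + 1):
                    prev = S[i - di, j - dj]
                    if prev <= _NEG / 2:
                        continue
                    dr = t[j] - t[j - dj]
                    var = cv * cv * dr * dr + two_j2
                    cand = (prev + reward
                            - (dq - dr) * (dq - dr) / (2.0 * var)
                            - (di - 1) * fp_pen - (dj - 1) * fn_pen)
                    if cand > best + _EPS:
                        best = cand
                        bi = i - di
                        bj = j - dj
            S[i, j] = best
            back_i[i, j] = bi
            back_j[i, j] = bj
    # closing penalties
    best_total = _NEG
    end_i = -1
    end_j = -1
    for i in range(nq):
        for j in range(nt):
            if mode == 0:
                total = S[i, j] - fp_pen * (nq - 1 - i)
            else:
                a = fp_pen * (nq - 1 - i)
                b = fn_pen * (nt - 1 - j)
                total = S[i, j] - (a if a < b else b)
            if total > best_total + _EPS:
                best_total = total
                end_i = i
                end_j = j
    return best_total, end_i, end_j, back_i, back_j


def _traceback(end_i, end_j, back_i, back_j):
    pairs = []
    i, j = end_i, end_j
    while i >= 0:
        pairs.append((i, j))
        i, j = back_i[i, j], back_j[i, j]
        if i < 0:
            break
    pairs.reverse()
    return pairs


def _mirror(m: LabelMap) -> np.ndarray:
    """Positions of the mirrored map, ascending (differences are mirrored)."""
    p = m.positions.astype(np.float64)
    return (p[0] + p[-1]) - p[::-1]


def _run(query: LabelMap, target: LabelMap, params: AlignmentParams,
         mode: int) -> Alignment | None:
    if query.n_labels == 0 or target.n_labels == 0:
        return None
    t = target.positions.astype(np.float64)
    candidates = []
    for orientation in ("+", "-"):
        if orientation == "+":
            qpos = query.positions.astype(np.float64)
        else:
            if query.n_labels < 2:
                continue
            qpos = _mirror(query)
        score, ei, ej, bi, bj = _dp(
            qpos, t, params.sizing_cv, params.jitter_bp, params.fp_penalty,
            params.fn_penalty, params.match_reward, params.max_skip, mode)
        if ei < 0:
            continue
        pairs = _traceback(ei, ej, bi, bj)
        if orientation == "-":
            n = query.n_labels
            pairs = [(n - 1 - i, j) for i, j in pairs]
        candidates.append((round(score, 9), orientation, pairs))
    if not candidates:
        return None
    # higher score wins; ties prefer lower target offset, then '+'
    def key(c):
        score, orientation, pairs = c
        return (-score, pairs[0][1], orientation != "+")
    score, orientation, pairs = min(candidates, key=key)
    if score < params.min_score or len(pairs) < params.min_aligned_labels:
        return None
    qi = [query.positions[i] for i, _ in pairs]
    ti = [target.positions[j] for _, j in pairs]
    aln = Alignment(
        query_id=query.id, target_id=target.id, orientation=orientation,
        pairs=pairs, score=float(score),
        query_interval=(int(min(qi)), int(max(qi))),
        target_interval=(int(min(ti)), int(max(ti))),
    )
    return aln


def align_fit(query: LabelMap, target: LabelMap,
              params: AlignmentParams) -> Alignment | None:
    """Best global-in-query, local-in-target alignment, or ``None``."""
    return _run(query, target, params, mode=0)


def align_overlap(a: LabelMap, b: LabelMap,
                  params: AlignmentParams) -> Alignment | None:
    """Best dovetail alignment of ``b`` against ``a``, or ``None``.

    ``offset_bp`` is the signed position of ``b``'s origin in ``a``'s
    coordinates (for '+' orientation), estimated as the median over matched
    pairs.
    """
    aln = _run(b, a, params, mode=1)
    if aln is None:
        return None
    if aln.orientation == "+":
        deltas = [float(a.positions[j]) - float(b.positions[i])
                  for i, j in aln.pairs]
    else:
        deltas = [float(a.positions[j]) - float(b.length_bp - b.positions[i])
                  for i, j in aln.pairs]
    aln.offset_bp = float(np.median(deltas))
    return aln


def estimate_null_scores(params: AlignmentParams, n_pairs: int = 200,
                         n_labels: int = 28, span_bp: int = 300_000,
                         seed: int = 0) -> np.ndarray:
    """Best dovetail scores between unrelated random maps.

    Used to calibrate ``min_score``/``min_aligned_labels`` so that the
    random-map false-discovery rate stays below 1%: run once, inspect the
    upper tail, keep the thresholds above it.
    """
    rng = np.random.default_rng(seed)
    loose = AlignmentParams(**{**params.__dict__, "min_score": -1e9,
                               "min_aligned_labels": 2})
    out = np.empty(n_pairs)
    for k in range(n_pairs):
        maps = []
        for side in range(2):
            pos = np.sort(rng.choice(span_bp, size=n_labels, replace=False))
            pos = np.unique(pos)
            maps.append(LabelMap(id=f"null{k}_{side}", length_bp=span_bp,
                                 positions=pos))
        aln = align_overlap(maps[0], maps[1], loose)
        out[k] = _NEG if aln is None else aln.score
    return out
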