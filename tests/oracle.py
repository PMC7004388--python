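"""Independent brute-force oracles used by the test suite.

The alignment oracle enumerates every monotone pairing (with the bounded
per-chunk skip rule) recursively and scores it directly from the chunk
formula — no dynamic programming, no shared code with the implementation.
"""

from __future__ import annotations

import re

import numpy as np

from subtelomap.align import AlignmentParams


def chunk_score_ref(dq, dr, nq_sk, nr_sk, p: AlignmentParams) -> float:
    var = p.sizing_cv**2 * dr**2 + 2.0 * p.jitter_bp**2
    return (p.match_reward - (dq - dr) ** 2 / (2.0 * var)
            - nq_sk * p.fp_penalty - nr_sk * p.fn_penalty)


def _enumerate(q, t, p: AlignmentParams, mode: str):
    """Yield (score, pairs) for every admissible monotone pairing."""
    nq, nt = len(q), len(t)

    def extend(pairs, score):
        i, j = pairs[-1]
        yield score, pairs
        for di in range(1, p.max_skip + 2):
            for dj in range(1, p.max_skip + 2):
                ni, nj = i + di, j + dj
                if ni >= nq or nj >= nt:
                    continue
                c = chunk_score_ref(q[ni] - q[i], t[nj] - t[j],
                                    di - 1, dj - 1, p)
                yield from extend(pairs + [(ni, nj)], score + c)

    for i0 in range(nq):
        for j0 in range(nt):
            if mode == "fit":
                start = p.match_reward - p.fp_penalty * i0
            else:
                start = p.match_reward - min(p.fp_penalty * i0,
                                             p.fn_penalty * j0)
            yield from extend([(i0, j0)], start)


def best_alignment_ref(q, t, p: AlignmentParams, mode: str):
    """Best score over both orientations with closing penalties applied."""
    q = np.asarray(q, dtype=float)
    t = np.asarray(t, dtype=float)
    nq, nt = len(q), len(t)
    best = None
    for orientation in ("+", "-"):
        qq = q if orientation == "+" else (q[0] + q[-1]) - q[::-1]
        if orientation == "-" and nq < 2:
            continue
        for score, pairs in _enumerate(qq, t, p, mode):
            i, j = pairs[-1]
            if mode == "fit":
                total = score - p.fp_penalty * (nq - 1 - i)
            else:
                total = score - min(p.fp_penalty * (nq - 1 - i),
                                    p.fn_penalty * (nt - 1 - j))
            if best is None or total > best[0] + 1e-9:
                best = (total, len(pairs), orientation)
    return best


def regex_digest_ref(seq: str, recognition: str, label_offset: int,
                     rc: str) -> set[tuple[int, str]]:
    """Both-strand motif scan with the '+'-wins coincidence rule."""
    k = len(recognition)
    found: dict[int, str] = {}
    for m in re.finditer(f"(?={rc})", seq):
        found[m.start() + k - 1 - label_offset] = "-"
    for m in re.finditer(f"(?={recognition})", seq):
        found[m.start() + label_offset] = "+"
    return set(found.items())
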