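import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracle.py

from subtelomap.core import LabelMap, PipelineParams
from subtelomap.simulate import default_block_library


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams()


@pytest.fixture(scope="session")
def library():
    return default_block_library()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_2409)


def make_map(positions, length=None, map_id="m", strands=None) -> LabelMap:
    positions = np.asarray(positions, dtype=np.int64)
    if length is None:
        length = int(positions[-1]) + 1_000 if positions.size else 0
    return LabelMap(id=map_id, length_bp=length, positions=positions,
                    strands=None if strands is None else np.asarray(strands))


def label_recovery(consensus: LabelMap, truth: LabelMap,
                   tol_bp: float = 1_500.0):
    """(missed fraction, spurious fraction) of a consensus versus truth.

    Labels are paired by fit alignment; matched pairs must agree within
    ``tol_bp`` after removing the locally-registered offset (a rolling
    median over neighbouring pairs), so smooth coordinate drift from
    sizing noise does not count against pattern recovery.
    """
    import dataclasses

    from subtelomap.align import AlignmentParams, align_fit

    loose = dataclasses.replace(AlignmentParams(), min_score=-1e9)
    aln = align_fit(consensus, truth, loose)
    assert aln is not None and aln.orientation == "+"
    resid = np.array([float(consensus.positions[i]) - float(truth.positions[j])
                      for i, j in aln.pairs])
    good = 0
    for k in range(len(resid)):
        window = resid[max(0, k - 3):k + 4]
        if abs(resid[k] - np.median(window)) <= tol_bp:
            good += 1
    matched_t = {j for _, j in aln.pairs}
    matched_c = {i for i, _ in aln.pairs}
    missed = (truth.n_labels - len(matched_t)) + (len(resid) - good)
    spurious = consensus.n_labels - len(matched_c)
    return missed / truth.n_labels, spurious / consensus.n_labels
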