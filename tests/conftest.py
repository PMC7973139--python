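import numpy as np
import pytest

from clampkit.core import Condition, Segment, SegmentAnnotation, Trace


@pytest.fixture
def constants():
    from clampkit.core import PhysConstants

    return PhysConstants()


def make_step_trace(levels, seg_len=10.0, dt=0.1, conditions=None, units="nA"):
    """Piecewise-constant trace with one segment per level."""
    n_per = int(round(seg_len / dt))
    current = np.concatenate([np.full(n_per, lv) for lv in levels])
    segments = []
    if conditions is not None:
        for k, cond in enumerate(conditions):
            segments.append(Segment(k * seg_len, (k + 1) * seg_len, cond))
    return Trace(dt, current, units=units), SegmentAnnotation(segments)


@pytest.fixture
def ami_washout_trace():
    """Amiloride plateau -100 nA, washout plateau -600 nA."""
    return make_step_trace(
        [-100.0, -600.0, -100.0],
        conditions=[Condition.AMILORIDE, Condition.WASHOUT, Condition.AMILORIDE],
    )
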