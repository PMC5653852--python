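import numpy as np
import pandas as pd
import pytest

from reciprome.nanostring import MirnaCountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_count_matrix(
    endo: dict[str, list[int]],
    pos: dict[str, list[int]],
    neg: dict[str, list[int]] | None = None,
    groups: dict[str, str] | None = None,
) -> MirnaCountMatrix:
    """Small literal count matrix; dict values are per-sample counts.

    Sample names default to S1..Sn, all in one group unless ``groups`` given.
    """
    n = len(next(iter(endo.values())))
    samples = [f"S{i + 1}" for i in range(n)]
    frames, classes = [], {}
    for block, cls in ((endo, "endogenous"), (pos, "positive_control"), (neg or {}, "negative_control")):
        for probe, counts in block.items():
            classes[probe] = cls
        if block:
            frames.append(pd.DataFrame(block, index=samples).T)
    counts = pd.concat(frames)
    groups = groups or {s: "G" for s in samples}
    return MirnaCountMatrix(
        counts=counts,
        probe_class=pd.Series(classes),
        sample_groups=pd.Series(groups),
    )
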