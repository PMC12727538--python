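import numpy as np
import pandas as pd
import pytest

from retainkit.intervals import GenomeLayout, IntervalSet


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout.from_dict({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_interval_set(
    rng: np.random.Generator, layout: GenomeLayout, n: int, max_width: int = 500
) -> IntervalSet:
    """Random intervals on a layout (shared helper for oracle-based tests)."""
    chroms, starts, ends = [], [], []
    names, lengths = layout.names, layout.lengths
    for _ in range(n):
        ci = int(rng.integers(len(names)))
        w = int(rng.integers(1, max_width + 1))
        s = int(rng.integers(0, max(1, lengths[ci] - w)))
        chroms.append(names[ci])
        starts.append(s)
        ends.append(s + w)
    return IntervalSet(pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}))


def coverage_mask_oracle(layout: GenomeLayout, iset: IntervalSet) -> dict[str, np.ndarray]:
    """Per-base boolean occupancy — the brute-force union oracle."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in layout.sizes.items()}
    for c, s, e in zip(iset.chroms, iset.starts, iset.ends):
        masks[c][s:e] = True
    return masks
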