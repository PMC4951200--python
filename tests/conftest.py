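import numpy as np
import pandas as pd
import pytest

from chipdiff import CoverageTrack, GenomeTable


@pytest.fixture
def genome():
    return GenomeTable((("chrI", 10_000), ("chrII", 5_000)))


@pytest.fixture
def big_genome():
    return GenomeTable((("chrI", 100_000),))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(genome, values=None, normalized=True, fill=0.0):
    """Build a CoverageTrack from explicit per-chromosome vectors."""
    data = {}
    values = values or {}
    for name, length in genome:
        if name in values:
            arr = np.asarray(values[name], dtype=np.float64 if normalized else np.int64)
            assert len(arr) == length
        else:
            dtype = np.float64 if normalized else np.int64
            arr = np.full(length, fill, dtype=dtype)
        data[name] = arr
    return CoverageTrack(genome=genome, data=data, normalized=normalized)


def scores_frame(y_a, y_b, chrom="chrI", width=500, step=250):
    """Window-score table from explicit per-window totals (contiguous tiling)."""
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    n = len(y_a)
    starts = np.arange(n) * step
    mean = 0.5 * (y_a + y_b)
    defined = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(defined, (y_a - y_b) / mean, np.nan)
        a = np.where(defined, np.log(np.where(defined, mean, 1.0)), np.nan)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + width,
            "y_a": y_a,
            "y_b": y_b,
            "D": d,
            "A": a,
            "defined": defined,
        }
    )
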