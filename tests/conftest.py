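import numpy as np
import pandas as pd
import pytest

from meioxo.caller import MarkerTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_marker_table(rows, library_reads=None):
    """Build a MarkerTable from (individual, chrom, pos, ref, alt, qual) tuples."""
    df = pd.DataFrame(
        rows, columns=["individual", "chrom", "pos", "ref_count", "alt_count", "quality"]
    )
    if library_reads is None:
        library_reads = {ind: 1_000_000 for ind in df["individual"].unique()}
    return MarkerTable(df, pd.Series(library_reads, name="library_reads"))


@pytest.fixture
def marker_table_factory():
    return make_marker_table
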