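import numpy as np
import pandas as pd
import pytest

from xbp1flux.io_formats import CountMatrix


@pytest.fixture
def sj_lines():
    """Three STAR-dialect junction lines, focal XBP1s junction first."""
    return (
        "chr22\t28796122\t28796147\t1\t1\t1\t250\t10\t50\n"
        "chr1\t1000\t2000\t2\t2\t0\t750\t0\t40\n"
        "chr2\t500\t900\t0\t0\t1\t100\t5\t30\n"
    )


@pytest.fixture
def sj_file(tmp_path, sj_lines):
    path = tmp_path / "sample1.SJ.out.tab"
    path.write_text(sj_lines)
    return path


@pytest.fixture
def small_counts():
    """4 genes x 4 samples, two groups, with simple structure."""
    counts = pd.DataFrame(
        {
            "s1": [10, 100, 6, 0],
            "s2": [20, 110, 0, 0],
            "s3": [10, 95, 0, 7],
            "s4": [20, 105, 0, 6],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    design = pd.Series(["A", "A", "B", "B"], index=["s1", "s2", "s3", "s4"])
    return CountMatrix(counts=counts, design=design)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
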