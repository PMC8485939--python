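import numpy as np
import pytest

from hlpatterns.io import CountMatrix

SAMPLES = ("BEC0W", "BEC20W", "BEC40W", "BEC60W")


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 genes x 4 samples with one clear HHLL gene, one LLHH, one flat."""
    return CountMatrix(
        ("g_hhll", "g_llhh", "g_flat"),
        SAMPLES,
        np.array(
            [
                [400, 400, 100, 100],
                [50, 50, 200, 200],
                [120, 120, 120, 120],
            ]
        ),
    )


@pytest.fixture
def counts_tsv(tmp_path, small_counts):
    path = tmp_path / "counts.tsv"
    from hlpatterns.io import write_count_matrix

    write_count_matrix(small_counts, path)
    return path
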