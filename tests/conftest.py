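import numpy as np
import pytest

from mdgkit.marker_catalog import MISSING, GenotypeMatrix, MarkerDef


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """4 samples x 3 diploid markers with a sprinkling of missing calls."""
    calls = np.array(
        [
            [0, 1, 2],
            [1, MISSING, 2],
            [2, 0, MISSING],
            [MISSING, 1, 0],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        marker_ids=["m1", "m2", "m3"],
        calls=calls,
        ploidy_scale=np.array([2, 2, 2]),
        chromosomes=["Arahy.01", "Arahy.01", "Arahy.02"],
        positions=np.array([100, 5000, 300]),
        alleles=["A/G", "C/T", "A/T"],
    )


def make_marker(mid, chrom="Arahy.01", pos=100, **kw) -> MarkerDef:
    return MarkerDef(marker_id=mid, chromosome=chrom, position=pos, **kw)
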