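import numpy as np
import pytest

from embryomosaic import BinGrid, ReferenceTracks


@pytest.fixture(scope="session")
def mini_grid() -> BinGrid:
    """Small genome (six chromosomes incl. a chr21-sized one) for fast tests."""
    sizes_mb = {"chr1": 60, "chr2": 60, "chr3": 60, "chr4": 50, "chr5": 50, "chr21": 47}
    return BinGrid.from_chrom_sizes({c: mb * 1_000_000 for c, mb in sizes_mb.items()})


@pytest.fixture(scope="session")
def flat_tracks(mini_grid) -> ReferenceTracks:
    return ReferenceTracks(np.full(mini_grid.n_bins, 0.45),
                           np.ones(mini_grid.n_bins))
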