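import numpy as np
import pandas as pd
import pytest

from capcontact.fragmap import FragmentMap, Viewpoint


@pytest.fixture
def small_map():
    """10 kb chromosome tiled by 10 x 1 kb fragments."""
    fmap = FragmentMap()
    starts = list(range(0, 10_000, 1_000))
    ends = list(range(1_000, 11_000, 1_000))
    fmap.add_chromosome("chr1", starts, ends)
    return fmap


@pytest.fixture
def vp_small(small_map):
    """Viewpoint on the first fragment of the small map."""
    return Viewpoint(name="vpA", chrom="chr1", start=100, end=200)


def make_table(fmap, vp_name, counts, condition="control", replicate="r1"):
    """Long-format raw interaction rows for every fragment of one chromosome.

    ``counts`` maps fragment ordinal -> raw count (missing = 0).
    """
    chrom = fmap.chroms[0]
    rows = []
    for i, fid in enumerate(fmap.fragment_ids(chrom)):
        _, s, e = fmap.fragment_bounds(fid)
        rows.append(
            {
                "viewpoint": vp_name,
                "fragment_id": fid,
                "chrom": chrom,
                "start": s,
                "end": e,
                "replicate": replicate,
                "condition": condition,
                "raw_count": int(counts.get(i, 0)),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
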