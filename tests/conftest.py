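import numpy as np
import pandas as pd
import pytest

from fec.io import CountTable, SampleMetadata, Taxonomy, UNASSIGNED, RANKS


@pytest.fixture
def tiny_ct() -> CountTable:
    return CountTable(
        ["t1", "t2", "t3"],
        ["s1", "s2"],
        np.array([[4, 0], [1, 2], [0, 7]]),
    )


def make_taxonomy(rows: dict[str, tuple]) -> Taxonomy:
    """rows: taxon_id -> tuple of up to 7 rank names; missing -> UNASSIGNED."""
    recs = {}
    for tid, ranks in rows.items():
        full = list(ranks) + [UNASSIGNED] * (len(RANKS) - len(ranks))
        recs[tid] = dict(zip(RANKS, full))
    return Taxonomy(pd.DataFrame.from_dict(recs, orient="index"))


def make_metadata(assign: dict[str, tuple[str, str]]) -> SampleMetadata:
    df = pd.DataFrame.from_dict(assign, orient="index", columns=["host", "site"])
    df.index.name = "sample_id"
    return SampleMetadata(df)
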