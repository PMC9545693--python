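import numpy as np
import pytest
from hypothesis import settings

from ddi_concordance.ingest import (
    CanonicalPair,
    DIRTable,
    NormalizedDDI,
    canonicalize_pair,
)

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


def make_table(
    dir_id: str,
    entries: dict[tuple[str, str], tuple[int | None, str | None]],
) -> DIRTable:
    """Build a DIRTable from {(name_a, name_b): (severity_rank, evidence)}."""
    records: dict[CanonicalPair, NormalizedDDI] = {}
    for (a, b), (severity, evidence) in entries.items():
        pair = canonicalize_pair(a, b)
        records[pair] = NormalizedDDI(
            pair=pair,
            severity_set=frozenset() if severity is None else frozenset({severity}),
            severity=severity,
            evidence=evidence,
            advice_texts=(),
            provenance=(f"{dir_id}:{a}:{b}",),
        )
    return DIRTable(dir_id=dir_id, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(20200901)
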