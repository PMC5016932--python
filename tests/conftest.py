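"""Shared fixtures: toy libraries and fold-change tables built in memory."""

import numpy as np
import pandas as pd
import pytest

from dropoutscreen.io import (
    SampleMeta,
    ScreenCounts,
    SgRnaLibrary,
    SgRnaRecord,
)
from dropoutscreen.normalize import FoldChangeTable


def make_library(gene_guides: dict[str, int], n_controls: int = 0,
                 tags: dict[str, set[str]] | None = None) -> SgRnaLibrary:
    """Library with the given guides-per-gene map plus controls; spacers are
    deterministic unique 20-mers."""
    rng = np.random.default_rng(12345)
    bases = np.array(list("ACGT"))
    records = []
    used = set()

    def spacer():
        while True:
            s = "".join(bases[rng.integers(0, 4, 20)])
            if s not in used:
                used.add(s)
                return s

    for gene, n in gene_guides.items():
        for j in range(n):
            records.append(SgRnaRecord(f"{gene}_g{j+1}", spacer(), gene, False))
    for c in range(n_controls):
        records.append(SgRnaRecord(f"CTRL_{c+1:03d}", spacer(), "", True))
    lib = SgRnaLibrary(records)
    if tags:
        lib = lib.with_tags(tags)
    return lib


def make_fc(library: SgRnaLibrary, values: dict[str, list[float]],
            baseline: str = "d0") -> FoldChangeTable:
    """FoldChangeTable from per-timepoint value lists aligned to library order."""
    log2fc = pd.DataFrame(values, index=library.sgrna_ids)
    means = log2fc.copy()
    means.insert(0, baseline, 1.0)
    return FoldChangeTable(library, baseline, log2fc, means)


def make_counts(library: SgRnaLibrary, columns: dict[str, list],
                timepoints: dict[str, str], baseline: str,
                scale: str = "raw") -> ScreenCounts:
    """ScreenCounts from explicit columns; ``timepoints`` maps sample -> tp."""
    samples = []
    rep_counter: dict[str, int] = {}
    for sid in columns:
        tp = timepoints[sid]
        rep_counter[tp] = rep_counter.get(tp, 0) + 1
        samples.append(SampleMeta(sid, tp, rep_counter[tp], tp == baseline))
    values = pd.DataFrame(columns, index=library.sgrna_ids)
    return ScreenCounts(library, samples, values, scale=scale)


@pytest.fixture(scope="session")
def toy_library() -> SgRnaLibrary:
    return make_library({"GENE1": 3, "GENE2": 3, "GENE3": 2}, n_controls=2,
                        tags={"kinase": {"GENE1", "GENE3"}})
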