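"""sgRNA-level hit calling and downstream candidate filtering.

The screen's cutoff rule: among all guides with negative log2 fold change at
a timepoint (the depleted set D), the cutoff is the nearest-rank 5th
percentile — the m-th smallest value with m = ceil(fraction * |D|) — and the
hit set is every guide at or below it.  Ties at the cutoff are all included,
erring toward sensitivity.

Downstream helpers build top-k depletion tables (optionally restricted to an
annotation tag such as "kinase"), cross-check hit genes against expression to
estimate the off-target fraction, accumulate per-gene fold changes across
timepoints with essentiality/pan-lethal/expression filters, and correlate
gene depletion with drug-response viability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dropoutscreen.io import ExpressionTable
from dropoutscreen.normalize import FoldChangeTable

logger = logging.getLogger(__name__)


@dataclass
class HitCallResult:
    timepoint: str
    cutoff: float
    hits: set[str]
    n_depleted: int
    fraction: float

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def call_hits(
    fc: FoldChangeTable, timepoint: str, fraction: float = 0.05
) -> HitCallResult:
    """Nearest-rank top-``fraction`` most-depleted guides among depleted guides."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    col = fc.log2fc[timepoint]
    depleted = col[col < 0]
    if depleted.empty:
        raise ValueError(f"no depleted sgRNAs at timepoint {timepoint!r}")
    m = math.ceil(fraction * len(depleted))
    cutoff = float(np.sort(depleted.to_numpy())[m - 1])
    hits = set(col.index[col <= cutoff])
    return HitCallResult(timepoint, cutoff, hits, len(depleted), fraction)


def hit_genes(fc: FoldChangeTable, result: HitCallResult) -> set[str]:
    """Genes owning at least one guide in the hit set (controls excluded)."""
    genes = fc.genes
    return {genes[i] for i in result.hits if genes[i]}


def ranked_table(
    fc: FoldChangeTable,
    timepoint: str,
    tag: str | None = None,
    k: int = 20,
) -> pd.DataFrame:
    """Top-k most-depleted guides, optionally restricted to an annotation tag.

    Sorted ascending by log2fc, ties broken by sgrna_id so the table is
    deterministic.  Asking for more rows than there are tagged guides returns
    the full tagged list.
    """
    col = fc.log2fc[timepoint]
    ids: Sequence[str] = list(col.index)
    if tag is not None:
        if tag not in fc.library.all_tags:
            raise KeyError(f"unknown annotation tag {tag!r}")
        tagged = set(fc.library.ids_with_tag(tag))
        ids = [i for i in ids if i in tagged]
    ordered = sorted(ids, key=lambda i: (col[i], i))[:k]
    genes = fc.genes
    return pd.DataFrame(
        {
            "sgrna_id": ordered,
            "gene": [genes[i] for i in ordered],
            "log2fc": [float(col[i]) for i in ordered],
        }
    )


def expression_crosscheck(
    hit_gene_set: Iterable[str], expr: ExpressionTable
) -> tuple[float, dict[str, list[str]]]:
    """Fraction of hit genes not expressed, among those the table measures.

    Genes absent from the expression table are reported separately under
    ``"unmeasured"`` and excluded from the denominator.  Returns
    ``(fraction_not_expressed, {"not_expressed": ..., "expressed": ...,
    "unmeasured": ...})``.
    """
    genes = sorted(set(hit_gene_set))
    if not genes:
        raise ValueError("empty hit gene set")
    measured = [g for g in genes if g in expr]
    unmeasured = [g for g in genes if g not in expr]
    if len(measured) < 0.5 * len(genes):
        logger.warning(
            "expression table covers only %d of %d hit genes",
            len(measured),
            len(genes),
        )
    if not measured:
        raise ValueError("no hit gene is covered by the expression table")
    not_expressed = [g for g in measured if not expr.expressed(g)]
    expressed = [g for g in measured if expr.expressed(g)]
    fraction = len(not_expressed) / len(measured)
    return fraction, {
        "not_expressed": not_expressed,
        "expressed": expressed,
        "unmeasured": unmeasured,
    }


def _most_depleted(values: np.ndarray) -> float:
    return float(np.min(values))


def cumulative_score(
    fc: FoldChangeTable,
    summarizer: Callable[[np.ndarray], float] = _most_depleted,
    essential_genes: Iterable[str] = (),
    other_screen_hits: Iterable[str] = (),
    expr: ExpressionTable | None = None,
) -> pd.Series:
    """Per-gene summarized log2fc summed over all post-baseline timepoints.

    The default summarizer takes a gene's most-depleted guide per timepoint —
    single-guide analysis carries the signal here.  Genes on the published
    essential list, genes hit in another screen (pan-lethal), and genes not
    expressed are removed.  Output is ranked ascending (strongest cumulative
    depletion first).
    """
    essential = set(essential_genes)
    pan_lethal = set(other_screen_hits)
    totals: dict[str, float] = {}
    for tp in fc.timepoints:
        for gene, vals in fc.gene_values(tp).items():
            totals[gene] = totals.get(gene, 0.0) + summarizer(vals)
    kept = {
        gene: score
        for gene, score in totals.items()
        if gene not in essential
        and gene not in pan_lethal
        and (expr is None or (gene in expr and expr.expressed(gene)))
    }
    out = pd.Series(kept, name="cumulative_score")
    return out.sort_values(kind="mergesort")


def depletion_viability_correlation(
    gene_fc: Sequence[float], viability_decrease: Sequence[float]
) -> float:
    """Pearson correlation between per-gene depletion and drug response.

    The caller pairs observations explicitly (gene/cell-line summarized
    log2fc against the matched inhibitor's viability decrease); at least
    three pairs are required.
    """
    x = np.asarray(list(gene_fc), dtype=float)
    y = np.asarray(list(viability_decrease), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    return float(stats.pearsonr(x, y).statistic)
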