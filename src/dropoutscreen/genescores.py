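"""Gene-level statistics: the Q1 score and the RSA-down rank statistic.

Q1 is the mean of a gene's two lowest guide log2 fold changes — a simple
summary that demands two concordant guides rather than one outlier.

RSA-down (redundant sgRNA activity, depletion side) ranks all targeting
guides ascending by log2 fold change (rank 1 = most depleted, ties broken by
sgrna_id) and asks, for each gene with guides at ranks r_1 < … < r_k out of N,
how surprising it is to find at least j of its k guides within the top r_j,
for every j: p_j = P(X >= j) under the hypergeometric null of drawing r_j
guides without replacement from N containing k of the gene's.  The score is
log10 of the minimal p_j; smaller (more negative) is stronger depletion.
Non-targeting controls are excluded from the ranking universe by default —
genes are being scored and controls would dilute N asymmetrically.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from dropoutscreen.normalize import FoldChangeTable


def q1_score(values) -> float:
    """Mean of the two smallest values; NaN (flagged upstream) for fewer than 2.

    With exactly two guides measured it is their mean; with one the score is
    undefined and the gene must be flagged, not silently dropped.
    """
    vals = sorted(float(v) for v in values)
    if len(vals) < 2:
        return float("nan")
    return (vals[0] + vals[1]) / 2.0


def rsa_down(
    fc: FoldChangeTable,
    timepoint: str,
    include_controls: bool = False,
) -> pd.DataFrame:
    """RSA-down score per gene at one timepoint.

    Returns a DataFrame indexed by gene with columns ``n_guides``, ``q1``,
    ``q1_flag`` (True when fewer than 2 guides made Q1 undefined),
    ``rsa_logp``, ``best_rank``, ``n_ranked`` and ``fc_min`` (the gene's most
    depleted guide log2fc, the default per-gene summary elsewhere).
    """
    if timepoint not in fc.log2fc.columns:
        raise KeyError(f"unknown timepoint {timepoint!r}")
    col = fc.log2fc[timepoint]
    is_control = fc.is_control
    if not include_controls:
        col = col[~is_control]
    # global ascending ranking; ties broken by sgrna_id for determinism
    order = sorted(col.index, key=lambda i: (col[i], i))
    rank_of = {sgrna_id: r for r, sgrna_id in enumerate(order, start=1)}
    N = len(order)

    rows = []
    for gene, ids in fc.library.gene_index.items():
        ids = [i for i in ids if i in rank_of]
        if not ids:
            continue
        k = len(ids)
        ranks = sorted(rank_of[i] for i in ids)
        best_logp = 0.0
        best_rank = ranks[-1]
        for j, r in enumerate(ranks, start=1):
            # P(X >= j) with X ~ Hypergeom(N, k, r)
            p = float(hypergeom.sf(j - 1, N, k, r))
            logp = math.log10(p) if p > 0 else -np.inf
            if logp < best_logp:
                best_logp = logp
                best_rank = r
        values = fc.log2fc.loc[ids, timepoint]
        rows.append(
            {
                "gene": gene,
                "n_guides": k,
                "q1": q1_score(values),
                "q1_flag": k < 2,
                "rsa_logp": best_logp,
                "best_rank": best_rank,
                "n_ranked": N,
                "fc_min": float(values.min()),
            }
        )
    df = pd.DataFrame(rows).set_index("gene")
    return df.sort_index()


def gene_scores(
    fc: FoldChangeTable, timepoint: str, include_controls: bool = False
) -> pd.DataFrame:
    """RSA-down + Q1 table ranked as candidates (ascending RSA-down)."""
    return rank_candidates(rsa_down(fc, timepoint, include_controls))


def rank_candidates(scores: pd.DataFrame) -> pd.DataFrame:
    """Order genes ascending by RSA-down log10 p (most significant first).

    Ties break by Q1 ascending (undefined Q1 last), then gene symbol.
    """
    key = scores.assign(
        _q1=scores["q1"].fillna(np.inf), _gene=scores.index
    )
    ordered = key.sort_values(["rsa_logp", "_q1", "_gene"], kind="mergesort")
    return ordered.drop(columns=["_q1", "_gene"])
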