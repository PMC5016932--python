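"""Gene-set enrichment via one-tailed two-sample Kolmogorov-Smirnov tests.

Per gene the screen is summarized by the guide log2 fold change of maximal
absolute value (the most extreme guide, sign preserved).  Each gene set is
then compared with the complement of measured genes by a one-sided KS test
in both directions: ``neg`` asks whether the set is shifted toward depletion
(F_set above F_background), ``pos`` the reverse.  The one-sided p-value is
the classical asymptotic exponential bound exp(-2 D^2 mn/(m+n)) capped at 1;
an exact-permutation mode is available for small sets as an oracle.
Benjamini-Hochberg adjustment is applied separately to the negative and
positive families, matching the two separately ranked tails.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from dropoutscreen.io import GeneSetCollection
from dropoutscreen.normalize import FoldChangeTable


def summarize_gene(values) -> float:
    """The signed value of maximal absolute magnitude; ties go negative."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("summarize_gene needs at least one value")
    best = vals[0]
    for v in vals[1:]:
        if abs(v) > abs(best) or (abs(v) == abs(best) and v < best):
            best = v
    return best


def summarize_gene_values(fc: FoldChangeTable, timepoint: str) -> pd.Series:
    """Per-gene max-absolute guide log2fc at one timepoint (targeting genes only)."""
    out = {
        gene: summarize_gene(vals)
        for gene, vals in fc.gene_values(timepoint).items()
        if len(vals)
    }
    return pd.Series(out, name=timepoint).sort_index()


def _sup_ecdf_diff(a: np.ndarray, b: np.ndarray) -> float:
    """sup_x (F_a(x) - F_b(x)) over the pooled support, floored at 0."""
    a = np.sort(a)
    b = np.sort(b)
    xs = np.concatenate([a, b])
    fa = np.searchsorted(a, xs, side="right") / len(a)
    fb = np.searchsorted(b, xs, side="right") / len(b)
    return float(max(0.0, np.max(fa - fb)))


def _asymptotic_p(d: float, m: int, n: int) -> float:
    # floored far below any decision threshold so downstream -log10 and BH
    # arithmetic stay finite even when the exponential underflows
    exponent = -2.0 * d * d * m * n / (m + n)
    return min(1.0, max(math.exp(max(exponent, -690.0)), 1e-300))


def ks_one_tailed(
    set_values,
    background_values,
    direction: str,
    method: str = "asymptotic",
) -> tuple[float, float]:
    """One-sided two-sample KS test.

    direction="neg": D = sup(F_set - F_bg), sensitive to the set sitting at
    more negative values than the background; direction="pos" swaps roles.
    method="permutation" computes the exact permutation p by enumerating all
    splits of the pooled sample (sets of at most 10 genes only).
    """
    a = np.asarray(list(set_values), dtype=float)
    b = np.asarray(list(background_values), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if direction not in ("neg", "pos"):
        raise ValueError("direction must be 'neg' or 'pos'")
    if direction == "neg":
        d = _sup_ecdf_diff(a, b)
    else:
        d = _sup_ecdf_diff(b, a)
    m, n = a.size, b.size
    if method == "asymptotic":
        return d, _asymptotic_p(d, m, n)
    if method != "permutation":
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    if m > 10:
        raise ValueError("exact permutation p is limited to sets of <= 10 genes")
    pooled = np.concatenate([a, b])
    total = math.comb(m + n, m)
    if total > 2_000_000:
        raise ValueError(
            f"exact permutation space too large ({total} splits); reduce n"
        )
    at_least = 0
    idx = np.arange(m + n)
    for chosen in combinations(idx, m):
        sel = np.zeros(m + n, dtype=bool)
        sel[list(chosen)] = True
        if direction == "neg":
            d_star = _sup_ecdf_diff(pooled[sel], pooled[~sel])
        else:
            d_star = _sup_ecdf_diff(pooled[~sel], pooled[sel])
        if d_star >= d - 1e-12:
            at_least += 1
    return d, at_least / total


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in (0, 1])."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    values: pd.Series,
    sets: GeneSetCollection,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Both one-sided KS tests for every retained gene set.

    ``values`` maps measured genes to their summarized log2 fold change.
    Unmeasured genes are dropped from each set, then the collection's size
    bounds are applied to the intersection; the background of each test is
    the measured genes *not* in the set.  Returns one row per retained set
    with BH-adjusted q-values per direction and the larger ``neglog10p`` of
    the two tails with its direction label.
    """
    measured = set(values.index)
    retained = sets.filtered(measured)
    if not retained:
        raise ValueError("no gene set within size bounds after intersection "
                         "with the measured genes")
    rows = []
    for name in sorted(retained):
        genes = retained[name]
        in_set = values.loc[sorted(genes)].to_numpy()
        bg = values.loc[sorted(measured - genes)].to_numpy()
        d_neg, p_neg = ks_one_tailed(in_set, bg, "neg", method=method)
        d_pos, p_pos = ks_one_tailed(in_set, bg, "pos", method=method)
        rows.append(
            {
                "set": name,
                "m": len(in_set),
                "n": len(bg),
                "d_neg": d_neg,
                "p_neg": p_neg,
                "d_pos": d_pos,
                "p_pos": p_pos,
            }
        )
    df = pd.DataFrame(rows).set_index("set")
    df["q_neg"] = bh_adjust(df["p_neg"])
    df["q_pos"] = bh_adjust(df["p_pos"])
    neg_nl = -np.log10(df["p_neg"])
    pos_nl = -np.log10(df["p_pos"])
    df["neglog10p"] = np.maximum(neg_nl, pos_nl)
    df["direction"] = np.where(neg_nl >= pos_nl, "neg", "pos")
    return df


def select_top_sets(
    rows: pd.DataFrame, k: int = 20, threshold: float = 7.0
) -> dict[str, pd.DataFrame]:
    """Per direction, sets strictly above the -log10 p threshold, best first.

    Returns ``{"neg": ..., "pos": ...}``; either table may be empty.
    """
    out = {}
    for direction, pcol in (("neg", "p_neg"), ("pos", "p_pos")):
        nl = -np.log10(rows[pcol])
        sel = rows[nl > threshold].copy()
        sel["neglog10p_dir"] = nl[nl > threshold]
        sel = sel.sort_values(
            ["neglog10p_dir"], ascending=False, kind="mergesort"
        ).head(k)
        out[direction] = sel
    return out
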