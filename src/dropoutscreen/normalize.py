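"""Count normalization, pseudocounting, log2 fold changes, and screen QC.

Normalization is upper-quartile based: every sample is scaled so its 75th
percentile matches the mean 75th percentile across samples, then one global
constant brings the mean per-sample total to 10^6 so values live on a
counts-per-million magnitude and the 0.1-CPM pseudocount has its stated unit.
This preserves between-sample upper-quartile ratios.  Percentiles of counts
use the linear-interpolation quantile definition throughout.

Fold changes average replicates arithmetically on the pseudocounted
normalized scale (not on logs) before dividing by the baseline mean and
taking log2; the pseudocount guarantees every entry is finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from dropoutscreen.io import ScreenCounts, SgRnaLibrary


@dataclass
class NormalizationResult:
    normalized: ScreenCounts
    per_sample_uq: pd.Series  # sample -> 75th-percentile raw count
    target: float  # common upper-quartile scale value
    pseudocount: float | None = None  # set by add_pseudocount


@dataclass
class FoldChangeTable:
    """Replicate-averaged log2 fold changes versus the baseline time point.

    ``log2fc`` is indexed by sgrna_id (library order) with one column per
    non-baseline timepoint.  ``timepoint_means`` includes the baseline column.
    """

    library: SgRnaLibrary
    baseline: str
    log2fc: pd.DataFrame
    timepoint_means: pd.DataFrame

    @property
    def timepoints(self) -> list[str]:
        return list(self.log2fc.columns)

    @property
    def genes(self) -> pd.Series:
        return self.library.genes

    @property
    def is_control(self) -> pd.Series:
        return self.library.is_control

    def gene_values(self, timepoint: str) -> dict[str, np.ndarray]:
        """Targeting-guide log2fc values grouped by gene at one timepoint."""
        col = self.log2fc[timepoint]
        return {
            gene: col.loc[ids].to_numpy()
            for gene, ids in self.library.gene_index.items()
        }


@dataclass
class QcReport:
    fraction_covered: pd.Series  # sample -> fraction of sgRNAs with >= k reads
    coverage_threshold: int
    replicate_correlations: pd.DataFrame  # sample_a, sample_b, timepoint, rho
    cumulative_curves: dict[str, pd.DataFrame]  # sample -> (count, cum_fraction)


def _upper_quartile(col: np.ndarray) -> float:
    return float(np.percentile(col, 75))


def normalize(counts: ScreenCounts) -> NormalizationResult:
    """Upper-quartile normalize raw counts onto a counts-per-million magnitude.

    value(i, s) = raw(i, s) * g * target / UQ_s, with UQ_s the sample's 75th
    percentile raw count, target the mean of the UQ_s, and g one global
    constant making the mean per-sample total equal 10^6.
    """
    if counts.scale != "raw":
        raise ValueError("normalize expects raw counts")
    raw = counts.values.to_numpy(dtype=float)
    uq = np.array([_upper_quartile(raw[:, j]) for j in range(raw.shape[1])])
    zero = [s.sample_id for s, u in zip(counts.samples, uq) if u == 0]
    if zero:
        raise ValueError(
            f"sample(s) with zero 75th-percentile count cannot be normalized: {zero}"
        )
    target = float(np.mean(uq))
    scaled = raw * (target / uq)[np.newaxis, :]
    g = 1e6 / float(np.mean(scaled.sum(axis=0)))
    values = pd.DataFrame(
        scaled * g, index=counts.values.index, columns=counts.values.columns
    )
    normalized = ScreenCounts(counts.library, counts.samples, values, scale="normalized")
    return NormalizationResult(
        normalized,
        pd.Series(uq, index=counts.values.columns, name="uq75"),
        target,
    )


def add_pseudocount(
    normalized: ScreenCounts | NormalizationResult, pc: float = 0.1
) -> ScreenCounts:
    """Add a small constant (default 0.1 CPM) so zero-count guides stay finite."""
    if pc <= 0:
        raise ValueError("pseudocount must be > 0")
    if isinstance(normalized, NormalizationResult):
        normalized.pseudocount = pc
        normalized = normalized.normalized
    if normalized.scale != "normalized":
        raise ValueError("add_pseudocount expects normalized counts")
    return ScreenCounts(
        normalized.library,
        normalized.samples,
        normalized.values + pc,
        scale="normalized",
    )


def log2_fold_change(counts: ScreenCounts) -> FoldChangeTable:
    """Replicate-averaged log2 fold change of each timepoint versus baseline."""
    if counts.scale != "normalized":
        raise ValueError("log2_fold_change expects normalized (pseudocounted) counts")
    if (counts.values.to_numpy() <= 0).any():
        raise ValueError(
            "counts must be strictly positive; apply add_pseudocount first"
        )
    baseline = counts.baseline_timepoint
    non_baseline = [tp for tp in counts.timepoints if tp != baseline]
    if not non_baseline:
        raise ValueError("need at least one non-baseline timepoint")
    means = {}
    for tp in counts.timepoints:
        cols = [s.sample_id for s in counts.samples_at(tp)]
        means[tp] = counts.values[cols].mean(axis=1)
    timepoint_means = pd.DataFrame(means)
    log2fc = pd.DataFrame(
        {
            tp: np.log2(timepoint_means[tp] / timepoint_means[baseline])
            for tp in non_baseline
        }
    )
    return FoldChangeTable(counts.library, baseline, log2fc, timepoint_means)


def qc_report(
    counts: ScreenCounts,
    k: int = 100,
    cross_pairs: list[tuple[str, str]] | None = None,
) -> QcReport:
    """Coverage, replicate concordance, and cumulative-frequency QC.

    Per sample: fraction of guides with at least ``k`` raw reads and the
    cumulative frequency curve of sorted abundance.  Spearman rank
    correlation (average ranks on ties) for every replicate pair within a
    timepoint, plus any caller-designated cross-sample pairs.
    """
    values = counts.values
    frac = (values >= k).mean(axis=0)
    frac.name = f"fraction_ge_{k}"

    pairs: list[tuple[str, str, str]] = []
    for tp in counts.timepoints:
        ids = [s.sample_id for s in counts.samples_at(tp)]
        for a, b in combinations(ids, 2):
            pairs.append((a, b, tp))
    for a, b in cross_pairs or []:
        pairs.append((a, b, "cross"))
    rows = []
    for a, b, label in pairs:
        rho = stats.spearmanr(values[a], values[b]).statistic
        rows.append({"sample_a": a, "sample_b": b, "timepoint": label, "rho": rho})
    correlations = pd.DataFrame(rows, columns=["sample_a", "sample_b", "timepoint", "rho"])

    curves = {}
    for sid in values.columns:
        sorted_counts = np.sort(values[sid].to_numpy())
        cum = np.arange(1, len(sorted_counts) + 1) / len(sorted_counts)
        curves[sid] = pd.DataFrame({"count": sorted_counts, "cum_fraction": cum})
    return QcReport(frac, k, correlations, curves)
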