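"""Synthetic dropout screens with known ground truth, plus design arithmetic.

The generative model: guide i of gene g has baseline log-abundance
a_i ~ Normal(mu0, sigma0^2) and efficacy e_i drawn from a two-component Beta
mixture (a high component near 1 with probability pi_eff, else a low
component near 0) that emulates the observed guide-to-guide heterogeneity —
some guides of a real gene knock it out, others are duds.  The expected
relative abundance at elapsed time t (days since the baseline harvest) is

    w_i(t)  proportional to  exp(a_i + delta_g * e_i * t),

where delta_g is the gene's per-day fitness effect (negative = depletion,
zero for neutral genes and all non-targeting controls).  Each replicate is
an independent multinomial draw of ``depth`` reads from w(t) — pooled
sequencing is compositional, so per-sample totals are conserved exactly —
optionally with a per-replicate gamma perturbation of w (shape 1/phi) when
the overdispersion phi is positive.  Under this model a guide's expected
log2 fold change is delta * e * t / ln 2.

The design calculators reproduce the coverage arithmetic used to size a
pooled transduction: cells needed for an X-fold representation, and the
larger number that must be infected when only a fraction (MOI) integrates a
guide and part of the pool is harvested at baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from dropoutscreen.io import SampleMeta, ScreenCounts, SgRnaLibrary, SgRnaRecord
from dropoutscreen.hits import HitCallResult

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneClassSpec:
    """A gene class planted in the simulation: ``count`` genes with per-day
    fitness effect ``delta`` (days^-1; negative depletes)."""

    label: str
    count: int
    delta: float


def _default_classes() -> list[GeneClassSpec]:
    return [
        GeneClassSpec("core_essential", 20, -0.3),
        GeneClassSpec("driver", 5, -0.25),
    ]


@dataclass
class SimConfig:
    n_genes: int = 1000
    guides_per_gene: int = 3
    n_controls: int = 1000
    gene_classes: list[GeneClassSpec] = field(default_factory=_default_classes)
    pi_eff: float = 0.7
    beta_high: tuple[float, float] = (8.0, 2.0)
    beta_low: tuple[float, float] = (2.0, 8.0)
    mu0: float = 0.0
    sigma0: float = 1.0
    timepoints: Sequence[float] = (0.0, 24.0, 31.0, 38.0)
    replicates: int = 2
    depth: int = 5_000_000
    phi: float = 0.0
    seed: int = 0
    spacer_length: int = 20

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if sum(c.count for c in self.gene_classes) > self.n_genes:
            raise ValueError("gene class counts exceed n_genes")
        if not 0 <= self.pi_eff <= 1:
            raise ValueError("pi_eff must be in [0, 1]")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if 0.0 not in [float(t) for t in self.timepoints]:
            raise ValueError("timepoints must include the baseline at 0")


@dataclass
class SyntheticTruth:
    """Ground truth aligned with the emitted library.

    ``genes``: per-gene class label and delta.  ``guides``: per-guide gene,
    delta, efficacy, whether the efficacy came from the high mixture
    component, and baseline log-abundance.
    """

    genes: pd.DataFrame
    guides: pd.DataFrame


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    spacers: set[str] = set()
    while len(spacers) < n:
        block = rng.integers(0, 4, size=(n - len(spacers), length))
        for row in block:
            spacers.add("".join(_BASES[row]))
    return sorted(spacers)[:n]


def _timepoint_label(t: float) -> str:
    return f"d{int(round(t))}"


def simulate_screen(
    cfg: SimConfig,
) -> tuple[SgRnaLibrary, ScreenCounts, SyntheticTruth]:
    """Generate a library, raw count matrix, and aligned ground truth.

    Reproducible bit-for-bit under a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    gene_names = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]

    labels = []
    deltas = []
    for spec in cfg.gene_classes:
        labels += [spec.label] * spec.count
        deltas += [spec.delta] * spec.count
    n_neutral = cfg.n_genes - len(labels)
    labels += ["neutral"] * n_neutral
    deltas += [0.0] * n_neutral
    genes = pd.DataFrame({"class": labels, "delta": deltas}, index=gene_names)
    genes.index.name = "gene"

    n_targeting = cfg.n_genes * cfg.guides_per_gene
    n_total = n_targeting + cfg.n_controls
    spacers = _random_spacers(rng, n_total, cfg.spacer_length)

    records = []
    guide_rows = []
    for gi, gene in enumerate(gene_names):
        for j in range(cfg.guides_per_gene):
            sid = f"{gene}_g{j + 1}"
            records.append(
                SgRnaRecord(sid, spacers[gi * cfg.guides_per_gene + j], gene, False)
            )
            guide_rows.append({"sgrna_id": sid, "gene": gene})
    for c in range(cfg.n_controls):
        sid = f"CTRL_{c + 1:0{width}d}"
        records.append(SgRnaRecord(sid, spacers[n_targeting + c], "", True))
        guide_rows.append({"sgrna_id": sid, "gene": ""})
    library = SgRnaLibrary(records)

    guides = pd.DataFrame(guide_rows).set_index("sgrna_id")
    delta_per_guide = np.array(
        [genes.loc[g, "delta"] if g else 0.0 for g in guides["gene"]]
    )
    high = rng.random(n_total) < cfg.pi_eff
    eff = np.where(
        high,
        rng.beta(*cfg.beta_high, size=n_total),
        rng.beta(*cfg.beta_low, size=n_total),
    )
    log_abund = rng.normal(cfg.mu0, cfg.sigma0, size=n_total)
    is_control = guides["gene"].to_numpy() == ""
    guides["class"] = [
        genes.loc[g, "class"] if g else "control" for g in guides["gene"]
    ]
    guides["delta"] = delta_per_guide
    guides["efficacy"] = eff
    guides["high_efficacy"] = high
    guides["log_abundance"] = log_abund
    guides.loc[is_control, "delta"] = 0.0

    samples = []
    columns = {}
    for t in cfg.timepoints:
        tp = _timepoint_label(t)
        log_w = log_abund + guides["delta"].to_numpy() * eff * float(t)
        w = np.exp(log_w - log_w.max())  # shift-invariant, avoids overflow
        for rep in range(1, cfg.replicates + 1):
            sid = f"{tp}_r{rep}"
            samples.append(SampleMeta(sid, tp, rep, is_baseline=(float(t) == 0.0)))
            w_rep = w
            if cfg.phi > 0:
                w_rep = w * rng.gamma(1.0 / cfg.phi, cfg.phi, size=n_total)
            p = w_rep / w_rep.sum()
            columns[sid] = rng.multinomial(cfg.depth, p)
    values = pd.DataFrame(columns, index=library.sgrna_ids)
    counts = ScreenCounts(library, samples, values, scale="raw")
    return library, counts, SyntheticTruth(genes, guides)


@dataclass
class RecoveryReport:
    recall_by_class: dict[str, float | None]
    planted_ranks: pd.DataFrame  # gene, class, rank, in_top, all_low_efficacy
    control_fpr: float
    top_cut: int  # rank cutoff used (genes)


def recovery_report(
    scores: pd.DataFrame,
    hit_result: HitCallResult,
    truth: SyntheticTruth,
    library: SgRnaLibrary,
    top_fraction: float = 0.05,
) -> RecoveryReport:
    """Measure how well the pipeline recovers the planted effects.

    A planted depleted gene counts as recovered when its RSA-down rank falls
    within the top ``top_fraction`` of scored genes.  The control false
    positive rate is the fraction of non-targeting guides in the sgRNA hit
    set.  Planted genes whose guides all drew the low-efficacy component are
    flagged: the model allows them to be missed.
    """
    missing = set(truth.genes.index) - set(scores.index)
    if missing - set(truth.genes.index[truth.genes["delta"] == 0]):
        raise ValueError(f"truth/scores misaligned; planted genes unscored: "
                         f"{sorted(missing)[:5]}")
    ordered = scores.sort_values(
        ["rsa_logp", "q1"], kind="mergesort"
    )
    rank = pd.Series(
        np.arange(1, len(ordered) + 1), index=ordered.index, name="rank"
    )
    top_cut = math.ceil(top_fraction * len(ordered))

    planted = truth.genes[truth.genes["delta"] < 0]
    rows = []
    for gene, row in planted.iterrows():
        g_guides = truth.guides[truth.guides["gene"] == gene]
        r = int(rank[gene]) if gene in rank.index else None
        rows.append(
            {
                "gene": gene,
                "class": row["class"],
                "rank": r,
                "in_top": bool(r is not None and r <= top_cut),
                "n_high_efficacy": int(g_guides["high_efficacy"].sum()),
                "all_low_efficacy": bool(~g_guides["high_efficacy"].any()),
            }
        )
    planted_ranks = pd.DataFrame(
        rows,
        columns=["gene", "class", "rank", "in_top", "n_high_efficacy",
                 "all_low_efficacy"],
    )

    recall: dict[str, float | None] = {}
    for label in planted["class"].unique():
        sub = planted_ranks[planted_ranks["class"] == label]
        recall[label] = float(sub["in_top"].mean()) if len(sub) else None
    if planted.empty:
        recall["planted"] = None

    control_ids = {r.sgrna_id for r in library.records if r.is_control}
    n_controls = len(control_ids)
    control_fpr = (
        len(control_ids & hit_result.hits) / n_controls if n_controls else 0.0
    )
    return RecoveryReport(recall, planted_ranks, control_fpr, top_cut)


def required_cells(n_sgrna: int, representation: int) -> int:
    """Cells needed for an X-fold library representation (n_sgrna * X)."""
    if n_sgrna <= 0 or representation <= 0:
        raise ValueError("n_sgrna and representation must be positive")
    return n_sgrna * representation


def required_infected_cells(
    n_sgrna: int,
    representation: int,
    moi: float,
    retained_fraction: float,
) -> int:
    """Cells to infect when only ``moi`` integrate a guide and only
    ``retained_fraction`` of the pool continues past the baseline harvest.

    Ceiling, not rounding: the arithmetic is a lower bound on a cell count.
    """
    base = required_cells(n_sgrna, representation)
    if not 0 < moi <= 1 or not 0 < retained_fraction <= 1:
        raise ValueError("moi and retained_fraction must be in (0, 1]")
    return math.ceil(base / (moi * retained_fraction))
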