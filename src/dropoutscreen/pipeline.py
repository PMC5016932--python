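"""End-to-end orchestration: one config in, a deterministic report directory out.

Stage order mirrors the primary analysis: (optional) read quantification,
normalization + pseudocount, log2 fold changes, QC, sgRNA hit calling per
timepoint, gene scores (Q1 / RSA-down), KS gene-set enrichment at the first
post-baseline timepoint, expression cross-check, and the cumulative score
table.  Every output is a fixed-format TSV; a machine-readable manifest
records the parameter hash and the sha256 of each artifact so a rerun under
the same config is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dropoutscreen import io as sio
from dropoutscreen.enrichment import enrich, select_top_sets, summarize_gene_values
from dropoutscreen.genescores import gene_scores
from dropoutscreen.hits import call_hits, expression_crosscheck, hit_genes, \
    cumulative_score, ranked_table
from dropoutscreen.normalize import add_pseudocount, log2_fold_change, normalize, \
    qc_report
from dropoutscreen.quantify import QuantifyConfig, count_reads

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    library: str
    counts: str | None = None
    meta: str | None = None
    fastq: dict[str, str] = field(default_factory=dict)  # sample_id -> path
    gmt: str | None = None
    expression: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)  # tag -> gene list
    essential_tag: str = "published_essential"
    other_screen_hits: str | None = None
    fraction: float = 0.05
    pseudocount: float = 0.1
    size_bounds: tuple[int, int] = (20, 2000)
    top_k: int = 20
    threshold: float = 7.0
    coverage_k: int = 100
    expressed_threshold: float = 1.0
    max_mismatches: int = 1
    ranked_tag: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.threshold < 0 or self.top_k < 1:
            raise ValueError("invalid selection parameters")
        if self.counts is None and not self.fastq:
            raise ValueError("either a counts table or FASTQ inputs are required")
        if self.counts is not None and self.meta is None:
            raise ValueError("a counts table requires sample metadata")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "size_bounds" in raw:
            raw["size_bounds"] = tuple(raw["size_bounds"])
        return cls(**raw)

    def params_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


class StageError(RuntimeError):
    """An error inside one pipeline stage, labeled with the stage name."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write the artifact set plus manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s", name)
        t0 = time.perf_counter()

        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
                return False

        return _Ctx()

    with stage("library"):
        library = sio.read_library(cfg.library, cfg.annotations or None)

    with stage("counts"):
        if cfg.counts is not None:
            counts = sio.read_counts(cfg.counts, cfg.meta, library)
        else:
            qcfg = QuantifyConfig(max_mismatches=cfg.max_mismatches)
            cols = {}
            for sample_id, fq in sorted(cfg.fastq.items()):
                col, stats = count_reads(fq, library, qcfg)
                cols[sample_id] = col
                logger.info(
                    "quantified %s: %d/%d assigned", sample_id,
                    stats.assigned, stats.total_reads,
                )
            samples = sio.read_sample_meta(cfg.meta)
            values = pd.DataFrame(cols)[[s.sample_id for s in samples]]
            counts = sio.ScreenCounts(library, samples, values, scale="raw")
        sio.write_table(counts, outdir / "raw_counts.tsv")
        outputs["raw_counts"] = outdir / "raw_counts.tsv"

    with stage("qc"):
        qc = qc_report(counts, k=cfg.coverage_k)
        qc.fraction_covered.rename_axis("sample").to_frame().to_csv(
            outdir / "qc_coverage.tsv", sep="\t", float_format="%.10g"
        )
        qc.replicate_correlations.to_csv(
            outdir / "qc_correlations.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        outputs["qc_coverage"] = outdir / "qc_coverage.tsv"
        outputs["qc_correlations"] = outdir / "qc_correlations.tsv"

    with stage("normalize"):
        norm = normalize(counts)
        pseudo = add_pseudocount(norm, cfg.pseudocount)
        sio.write_table(pseudo, outdir / "normalized_counts.tsv")
        outputs["normalized_counts"] = outdir / "normalized_counts.tsv"

    with stage("fold_change"):
        fc = log2_fold_change(pseudo)
        fc_out = fc.log2fc.copy()
        fc_out.insert(0, "gene", fc.genes)
        fc_out.index.name = "sgrna_id"
        fc_out.to_csv(outdir / "log2fc.tsv", sep="\t", float_format="%.10g")
        outputs["log2fc"] = outdir / "log2fc.tsv"

    first_tp = fc.timepoints[0]

    with stage("hit_calling"):
        hits_by_tp = {}
        rows = []
        for tp in fc.timepoints:
            res = call_hits(fc, tp, cfg.fraction)
            hits_by_tp[tp] = res
            rows.append(
                {
                    "timepoint": tp,
                    "cutoff": res.cutoff,
                    "n_depleted": res.n_depleted,
                    "n_hits": res.n_hits,
                }
            )
            pd.DataFrame({"sgrna_id": sorted(res.hits)}).to_csv(
                outdir / f"hits_{tp}.tsv", sep="\t", index=False
            )
            outputs[f"hits_{tp}"] = outdir / f"hits_{tp}.tsv"
        pd.DataFrame(rows).to_csv(
            outdir / "hit_summary.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        outputs["hit_summary"] = outdir / "hit_summary.tsv"
        if cfg.ranked_tag is not None:
            for tp in fc.timepoints:
                tab = ranked_table(fc, tp, tag=cfg.ranked_tag, k=cfg.top_k)
                tab.to_csv(
                    outdir / f"top_{cfg.ranked_tag}_{tp}.tsv", sep="\t",
                    index=False, float_format="%.10g",
                )
                outputs[f"top_{cfg.ranked_tag}_{tp}"] = (
                    outdir / f"top_{cfg.ranked_tag}_{tp}.tsv"
                )

    with stage("gene_scores"):
        scores = gene_scores(fc, first_tp)
        scores.to_csv(outdir / "gene_scores.tsv", sep="\t", float_format="%.10g")
        outputs["gene_scores"] = outdir / "gene_scores.tsv"

    expr = None
    if cfg.expression is not None:
        with stage("expression_crosscheck"):
            expr = sio.read_expression(cfg.expression, cfg.expressed_threshold)
            genes = hit_genes(fc, hits_by_tp[first_tp])
            frac, groups = expression_crosscheck(genes, expr)
            payload = {
                "fraction_not_expressed": frac,
                **{k: sorted(v) for k, v in groups.items()},
            }
            with open(outdir / "expression_crosscheck.json", "w",
                      encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            outputs["expression_crosscheck"] = outdir / "expression_crosscheck.json"

    with stage("cumulative_score"):
        essential = library.genes_with_tag(cfg.essential_tag)
        other = (
            sio.read_gene_list(cfg.other_screen_hits)
            if cfg.other_screen_hits
            else set()
        )
        cum = cumulative_score(
            fc, essential_genes=essential, other_screen_hits=other, expr=expr
        )
        cum.rename_axis("gene").to_frame().to_csv(
            outdir / "cumulative_score.tsv", sep="\t", float_format="%.10g"
        )
        outputs["cumulative_score"] = outdir / "cumulative_score.tsv"

    if cfg.gmt is not None:
        with stage("enrichment"):
            sets = sio.read_gmt(cfg.gmt, cfg.size_bounds)
            values = summarize_gene_values(fc, first_tp)
            table = enrich(values, sets)
            table.to_csv(outdir / "enrichment.tsv", sep="\t", float_format="%.10g")
            outputs["enrichment"] = outdir / "enrichment.tsv"
            selected = select_top_sets(table, cfg.top_k, cfg.threshold)
            for direction, sel in selected.items():
                sel.to_csv(
                    outdir / f"enrichment_top_{direction}.tsv", sep="\t",
                    float_format="%.10g",
                )
                outputs[f"enrichment_top_{direction}"] = (
                    outdir / f"enrichment_top_{direction}.tsv"
                )

    with stage("manifest"):
        hashes = {name: _sha256(path) for name, path in sorted(outputs.items())}
        manifest = {
            "params_hash": cfg.params_hash(),
            "seed": cfg.seed,
            "outputs": hashes,
        }
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()
        ).hexdigest()
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return outdir
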