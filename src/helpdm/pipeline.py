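"""End-to-end pipeline driver: simulate/ingest -> annotate -> DM + DE ->
enrichment -> DM x DE integration -> classification -> candidate ranking.

Each stage writes its table under the configured output directory and the
run ends with a machine-readable ``report.json`` holding every summary plus
the fully resolved configuration and all derived seeds, so a run can be
reproduced exactly from its report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from helpdm import io
from helpdm.annotation import annotate_loci
from helpdm.classify import consistency_rank, iterate_classification
from helpdm.enrichment import (
    chi_square_independence,
    compartment_summary,
    permutation_compartment_test,
)
from helpdm.integration import (
    build_counts_table,
    counts_table_stats,
    link_loci_to_genes,
    subcompartment_breakdown,
)
from helpdm.paired import run_de, run_dm
from helpdm.simulate import SimConfig, simulate_dataset

log = logging.getLogger("helpdm")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "helpdm_run"
    seed: int = 0
    alpha: float = 0.05
    promoter_width: int = 2000
    gb_start_offset: int = 0
    shore_width: int = 2000
    shore_mode: str = "both-flanks"
    permutation_B: int = 1000
    permutation_target: str = "GB"
    classifier_k: int = 25
    classifier_iterations: int = 10
    consistency_window: int = 2000
    dedup_locus: bool = True
    # either simulate (dict of SimConfig overrides) ...
    simulate: dict | None = field(default_factory=dict)
    # ... or paths to user-supplied inputs
    loci_bed: str | None = None
    genes_tsv: str | None = None
    cgi_bed: str | None = None
    methylation_tsv: str | None = None
    expression_tsv: str | None = None
    sample_sheet_tsv: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the one global seed."""
    stream = {"sim": 11, "perm": 13, "classify": 17}[stage]
    return int(
        np.random.SeedSequence([int(global_seed), stream]).generate_state(1)[0]
        % (2**31)
    )


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to
    ``<outdir>/report.json``).  Any stage failure raises :class:`StageError`
    naming the stage."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "seeds": {}}

    # --- stage: simulate or ingest -----------------------------------------
    stage = "ingest"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_seed = derive_seed(config.seed, "sim")
            report["seeds"]["simulate"] = sim_seed
            sim_cfg = SimConfig.from_dict(
                {**config.simulate, "seed": sim_seed}
            )
            data = simulate_dataset(sim_cfg)
            genes, cgis = data["genes"], data["cgis"]
            loci, chrom_lengths = data["loci"], data["chrom_lengths"]
            loci_ann = data["loci_annotated"]
            meth, expr = data["methylation"], data["expression"]
            design, truth = data["design"], data["truth"]
            io.write_genes_tsv(genes, out / "genes.tsv")
            io.write_bed(cgis.assign(locus_id="."), out / "cgi.bed")
            io.write_bed(loci, out / "loci.bed")
            io.write_matrix(meth, out / "methylation.tsv")
            io.write_matrix(expr, out / "expression.tsv")
            io.write_sample_sheet(design, out / "sample_sheet.tsv")
            io.write_table(truth.loci, out / "truth_loci.tsv")
            io.write_table(truth.genes, out / "truth_genes.tsv")
            io.write_table(truth.pairs, out / "truth_pairs.tsv")
            report["simulate"] = {
                "sim_config": sim_cfg.to_dict(),
                "n_loci": len(loci),
                "n_genes": len(genes),
            }
        else:
            for name in ("loci_bed", "genes_tsv", "methylation_tsv",
                         "expression_tsv", "sample_sheet_tsv"):
                path = getattr(config, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"missing input {name}: {path}")
            loci = io.read_bed(config.loci_bed)
            genes = io.read_genes_tsv(config.genes_tsv)
            cgis = (
                io.read_bed(config.cgi_bed)[["chrom", "start", "end"]]
                if config.cgi_bed
                else None
            )
            meth = io.read_matrix(config.methylation_tsv)
            expr = io.read_matrix(config.expression_tsv)
            _, design = io.read_sample_sheet(config.sample_sheet_tsv)
            chrom_lengths = None
            truth = None
            stage = "annotate"
            loci_ann = annotate_loci(
                loci,
                genes,
                cgis,
                promoter_width=config.promoter_width,
                gb_start_offset=config.gb_start_offset,
                shore_width=config.shore_width,
                shore_mode=config.shore_mode,
            )
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    log.info("annotated %d loci", len(loci_ann))
    io.write_table(loci_ann, out / "loci_annotated.tsv")

    # --- stage: differential methylation / expression ----------------------
    try:
        stage = "dm"
        dm = run_dm(meth, design, loci_ann, alpha=config.alpha)
        io.write_table(dm, out / "dm.tsv")
        stage = "de"
        de = run_de(expr, design, alpha=config.alpha)
        io.write_table(de, out / "de.tsv")
    except Exception as err:
        raise StageError(stage, err) from err
    n_dm = int((dm["q"] < config.alpha).sum())
    n_de = int((de["q"] < config.alpha).sum())
    log.info("DM loci: %d / %d; DE genes: %d / %d", n_dm, len(dm), n_de, len(de))
    summary = compartment_summary(dm, loci_ann)
    io.write_table(summary, out / "compartment_summary.tsv")
    report["dm"] = {"n_significant": n_dm, "n_tested": len(dm)}
    report["de"] = {"n_significant": n_de, "n_tested": len(de)}
    report["compartment_summary"] = summary.to_dict(orient="records")

    # --- stage: enrichment --------------------------------------------------
    try:
        stage = "enrich"
        perm_seed = derive_seed(config.seed, "perm")
        report["seeds"]["permutation"] = perm_seed
        dm_ids = dm.loc[dm["q"] < config.alpha, "locus_id"]
        enr = permutation_compartment_test(
            dm_ids,
            loci_ann[["locus_id", "compartment"]],
            target=config.permutation_target,
            B=config.permutation_B,
            seed=perm_seed,
        )
        report["enrichment"] = enr.to_dict()
    except Exception as err:
        raise StageError(stage, err) from err

    # --- stage: integration -------------------------------------------------
    try:
        stage = "integrate"
        records = link_loci_to_genes(
            dm,
            de,
            genes,
            loci=loci_ann,
            alpha=config.alpha,
            promoter_width=config.promoter_width,
            gb_start_offset=config.gb_start_offset,
            dedup_locus=config.dedup_locus,
            chrom_lengths=chrom_lengths,
        )
        counts = build_counts_table(records)
        grid = subcompartment_breakdown(records)
        io.write_table(records, out / "integration_records.tsv")
        io.write_table(counts, out / "integration_counts.tsv")
        grid.to_csv(out / "subcompartment_grid.tsv", sep="\t")
        stats = counts_table_stats(counts)
        nz = grid.loc[grid.sum(axis=1) > 0, grid.columns[grid.sum(axis=0) > 0]]
        if nz.shape[0] >= 2 and nz.shape[1] >= 2:
            chi2, dof, p = chi_square_independence(nz.to_numpy())
            stats["subcompartment_chi2"] = {"chi2": chi2, "df": dof, "p": p}
        report["integration"] = stats
    except Exception as err:
        raise StageError(stage, err) from err

    # --- stage: classify + rank --------------------------------------------
    try:
        stage = "classify"
        cls_seed = derive_seed(config.seed, "classify")
        report["seeds"]["classifier"] = cls_seed
        cls = iterate_classification(
            meth,
            design,
            k=config.classifier_k,
            n_iterations=config.classifier_iterations,
            seed=cls_seed,
            alpha=config.alpha,
        )
        report["classifier"] = cls.to_dict()
        stage = "rank-candidates"
        sig = dm[dm["direction"].isin(["hyper", "hypo"])]
        ranks = consistency_rank(sig, window=config.consistency_window)
        io.write_table(ranks, out / "consistency_rank.tsv")
        report["consistency_top"] = ranks.head(20).to_dict(orient="records")
    except Exception as err:
        raise StageError(stage, err) from err

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    log.info("report written to %s", out / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")
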