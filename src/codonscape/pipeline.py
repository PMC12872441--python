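"""End-to-end orchestration: expression → tRNA pool → adaptation →
balance → ribosome landscape, over a dataset directory laid out as by
:func:`codonscape.simulate.write_dataset`.

Each stage writes its TSV/JSON outputs under the configured output
directory and logs input/output row counts to stderr; a failing stage
aborts with a stage-tagged error, leaving earlier outputs in place next
to a ``FAILED`` marker file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from codonscape import adaptation, balance, expression, landscape, trna
from codonscape.codon_core import WobbleConstraintSet
from codonscape.io import (
    load_config_file,
    read_cds_fasta,
    read_counts_tsv,
    read_footprint_track,
    read_gene_table,
    read_trna_reads,
    write_tsv,
)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

logger = logging.getLogger("codonscape")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
logger.setLevel(logging.INFO)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and scopes for a full run."""

    dataset_dir: str
    output_dir: str
    rpkm_threshold: float = 10.0
    pause_k: float = 2.0
    min_mean_rpf: float = 1.0
    sfr_mode: str = "total"
    constraints: tuple[float, float, float, float, float] = (
        1.0,
        0.0,
        1.0,
        0.0065956,
        0.90832489,
    )
    pool_scope: tuple[str, ...] = ("host", "virus")
    demand_scope: str = "all"  # host+virus combined mRNA demand
    timepoints: tuple[str, ...] | None = None  # default: discover from files
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        data = load_config_file(path, known)
        for key in ("constraints", "pool_scope", "timepoints"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                logger.info("stage %s: done", name)
                return out
            except Exception as exc:  # noqa: BLE001 - re-tagged below
                raise StageError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def _discover_timepoints(dataset: Path) -> list[str]:
    return sorted(
        p.stem.replace("rna_counts_", "") for p in dataset.glob("rna_counts_*.tsv")
    )


@dataclass
class PipelineResult:
    outputs: dict[str, str] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage over a dataset directory; returns the file bundle."""
    dataset = Path(config.dataset_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    try:
        return _run(config, dataset, out, result)
    except StageError:
        (out / "FAILED").write_text("pipeline aborted; see stderr log\n")
        raise


def _run(config: PipelineConfig, dataset: Path, out: Path, result: PipelineResult) -> PipelineResult:
    genes = read_cds_fasta(dataset / "cds.fasta")
    gene_table = read_gene_table(dataset / "genes.tsv")
    timepoints = list(config.timepoints or _discover_timepoints(dataset))
    logger.info("loaded %d genes, %d timepoints", len(genes), len(timepoints))

    # --- expression ------------------------------------------------------
    @_stage("expression")
    def stage_expression():
        tables = {}
        for tp in timepoints:
            rna = read_counts_tsv(dataset / f"rna_counts_{tp}.tsv")
            rpf = read_counts_tsv(dataset / f"rpf_counts_{tp}.tsv")
            lengths = gene_table["length_nt"]
            organisms = gene_table["organism"]
            rna_rpkm = expression.compute_rpkm(rna, lengths, organisms=organisms)
            rpf_rpkm = expression.compute_rpkm(rpf, lengths, organisms=organisms)
            retained = expression.filter_expressed_genes(
                rna_rpkm, rpf_rpkm, config.rpkm_threshold
            )
            rna_tpm = expression.compute_tpm(rna, lengths)
            rpf_tpm = expression.compute_tpm(rpf, lengths)
            te = expression.compute_te(rna_tpm, rpf_tpm, genes=retained)
            tables[tp] = {
                "rna_tpm": rna_tpm,
                "rpf_tpm": rpf_tpm,
                "retained": retained,
                "te": te,
            }
            write_tsv(rna_tpm, out / f"rna_tpm_{tp}.tsv")
            write_tsv(rpf_tpm, out / f"rpf_tpm_{tp}.tsv")
            write_tsv(te, out / f"te_{tp}.tsv")
            logger.info(
                "expression %s: %d/%d genes retained", tp, len(retained), len(rna)
            )
        return tables

    expr = stage_expression()

    # --- tRNA pool -------------------------------------------------------
    @_stage("trna_pool")
    def stage_trna():
        reads = read_trna_reads(dataset / "trna_reads.tsv")
        retained = trna.filter_trna_reads(reads)
        pool = trna.pool_proportions(retained, scope_genomes=list(config.pool_scope))
        write_tsv(pool.table, out / "trna_pool.tsv", index=False)
        logger.info(
            "trna: %d/%d reads retained, %d anticodons",
            len(retained),
            reads["read_id"].nunique(),
            pool.table["anticodon"].nunique(),
        )
        return pool

    pool = stage_trna()

    # --- adaptation ------------------------------------------------------
    @_stage("adaptation")
    def stage_adaptation():
        constraints = WobbleConstraintSet.from_vector(config.constraints)
        W = adaptation.compute_w_scores(pool, constraints)
        wtab = adaptation.relative_adaptiveness(W)
        tai = pd.Series(
            {g.gene_id: adaptation.compute_tai(g, wtab) for g in genes}, name="tai"
        )
        write_tsv(wtab, out / "adaptation.tsv")
        write_tsv(tai, out / "tai.tsv")
        return wtab, tai

    wtab, tai = stage_adaptation()

    # --- demand / balance ------------------------------------------------
    @_stage("balance")
    def stage_balance():
        summaries = {}
        for tp in timepoints:
            rna_tpm = expr[tp]["rna_tpm"].mean(axis=1)
            scope_genes = genes
            if config.demand_scope != "all":
                scope_genes = [g for g in genes if g.organism == config.demand_scope]
            retained = expr[tp]["retained"]
            scope_genes = [g for g in scope_genes if g.gene_id in retained]
            demand = balance.codon_usage_weighted(scope_genes, rna_tpm)
            btab = balance.balance_scores(wtab, demand)
            summaries[tp] = balance.balance_by_class(btab)
            write_tsv(btab, out / f"balance_{tp}.tsv")
        (out / "balance_by_class.json").write_text(
            json.dumps(summaries, indent=1, sort_keys=True)
        )
        return summaries

    balance_summaries = stage_balance()

    # --- ribosome landscape ----------------------------------------------
    @_stage("landscape")
    def stage_landscape():
        summary = {}
        for tp in timepoints:
            track_all = read_footprint_track(dataset / f"footprints_{tp}.tsv")
            reps = (
                sorted(track_all["replicate"].unique())
                if "replicate" in track_all.columns
                else [None]
            )
            for rep in reps:
                track = (
                    track_all[track_all["replicate"] == rep]
                    if rep is not None
                    else track_all
                )
                tag = f"{tp}_{rep}" if rep is not None else tp
                occ = landscape.codon_occupancy(track, config.min_mean_rpf)
                pauses = landscape.detect_pauses(occ, k=config.pause_k)
                sfr = landscape.short_footprint_ratio(
                    track, occ.included_genes, mode=config.sfr_mode
                )
                write_tsv(occ.per_codon_type, out / f"occupancy_{tag}.tsv")
                write_tsv(pauses.per_codon_type, out / f"pauses_{tag}.tsv")
                write_tsv(sfr, out / f"sfr_{tag}.tsv")
                summary[tag] = {
                    "included_genes": int(occ.gene_stats["included"].sum()),
                    "n_pause_calls": int(pauses.calls["is_pause"].sum()),
                    "sfr_au3_vs_gc3": landscape.occupancy_by_class(sfr),
                }
                logger.info(
                    "landscape %s: %d genes, %d pauses",
                    tag,
                    summary[tag]["included_genes"],
                    summary[tag]["n_pause_calls"],
                )
        return summary

    landscape_summary = stage_landscape()

    report = {
        "timepoints": timepoints,
        "n_genes": len(genes),
        "retained_per_timepoint": {
            tp: int(len(expr[tp]["retained"])) for tp in timepoints
        },
        "pool_genome_fractions": pool.genome_fractions().to_dict(),
        "balance_by_class": balance_summaries,
        "landscape": landscape_summary,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    result.report = report
    result.outputs = {p.name: str(p) for p in out.iterdir()}
    return result
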