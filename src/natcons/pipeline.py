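"""End-to-end pipeline: ingest → orthology → divergence → calls → screens.

The runner composes the library stages over a directory of input files (as
produced by :func:`natcons.simulate.write_dataset`, or assembled by hand in
the same formats) and writes all tables, reports, and a manifest sufficient
to reproduce every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .divergence import run_divergence_comparison, tissue_correlation_matrix
from .expression import average_replicates
from .io import (
    read_bed,
    read_expression_table,
    read_fasta,
    read_homology,
    write_expression_table,
    write_json,
)
from .novelty import build_reference_index, screen_probesets
from .orthology import (
    DEFAULT_MIN_IDENTITY,
    gene_orthologs,
    map_orthologs,
    pairs_to_frame,
    remove_dual_strand_overlaps,
)
from .sense_antisense import divergence_correlation, per_tissue_correlation, records_to_frame
from .tissue_specificity import call_tissue_specific, calls_to_frame

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = (
    "ingest",
    "average_replicates",
    "orthology",
    "dual_strand_filter",
    "divergence",
    "tissue_specificity",
    "novelty",
    "sense_antisense",
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    input_dir: str
    out_dir: str
    species: tuple[str, ...] = ("human", "mouse", "rat")
    exclude_tissues: tuple[str, ...] = ()
    expression_threshold: float | None = 6.5
    z_cut: float = 2.0
    margin_cut: float = 1.0
    min_identity: float = DEFAULT_MIN_IDENTITY
    measure: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expression_threshold is not None and not 0 <= self.expression_threshold < 20:
            raise ValueError("expression_threshold outside the log2 intensity range")
        if not 0 < self.min_identity < 1:
            raise ValueError("min_identity must be in (0, 1)")
        if self.measure not in ("euclidean", "pearson"):
            raise ValueError("measure must be 'euclidean' or 'pearson'")
        self.species = tuple(self.species)
        self.exclude_tissues = tuple(self.exclude_tissues)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = list(self.species)
        d["exclude_tissues"] = list(self.exclude_tissues)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle (also written to disk).

    Any stage failure aborts with the stage name prepended to the cause.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_by_pair = {}  # (a, b, protocol) -> Generator, in fixed order
    children = iter(ss.spawn(2 * len(list(combinations(config.species, 2)))))
    for a, b in combinations(config.species, 2):
        for prot in ("sense", "antisense"):
            rng_by_pair[(a, b, prot)] = np.random.default_rng(next(children))

    report: dict = {"stages": {}, "seed": config.seed}
    stage = "ingest"
    try:
        raw = {}
        for sp in config.species:
            for prot in ("sense", "antisense"):
                raw[(sp, prot)] = read_expression_table(
                    indir / f"{sp}_{prot}_expression.tsv", species=sp, protocol=prot
                )
        exons = {sp: read_fasta(indir / f"{sp}_exons.fasta") for sp in config.species}
        transcripts = {sp: read_bed(indir / f"{sp}_transcripts.bed") for sp in config.species}
        probeset_beds = {sp: read_bed(indir / f"{sp}_probesets.bed") for sp in config.species}
        homology = read_homology(indir / "homology.tsv")
        refseq = read_fasta(indir / "refseq_standin.fasta")
        est = read_fasta(indir / "est_standin.fasta")
        report["stages"][stage] = {
            "matrices": len(raw),
            "probesets": {sp: int(len(exons[sp])) for sp in config.species},
        }

        stage = "average_replicates"
        averaged = {}
        for key, m in raw.items():
            avg = average_replicates(m)
            averaged[key] = avg
            write_expression_table(avg, outdir / f"{key[0]}_{key[1]}_averaged.tsv")
        report["stages"][stage] = {"matrices": len(averaged)}

        stage = "orthology"
        gene_pairs = {}
        exon_pairs = {}
        # gene annotation: homology gene_id -> probesets, via <sp>_gene_map.tsv if
        # present, else the 1:1 convention gene "<sp>_gNNNNN" -> probeset NNNNN
        gene_maps = {}
        for sp in config.species:
            gm_path = indir / f"{sp}_gene_map.tsv"
            if gm_path.exists():
                gm = pd.read_csv(gm_path, sep="\t", dtype=str)
                gene_maps[sp] = gm.groupby("gene_id")["probeset_id"].apply(list).to_dict()
            else:
                gene_maps[sp] = {
                    f"{sp}_g{i:05d}": [f"{sp}_ps{i:05d}"]
                    for i in range(len(exons[sp]))
                    if f"{sp}_ps{i:05d}" in exons[sp]
                }
        for a, b in combinations(config.species, 2):
            gene_pairs[(a, b)] = gene_orthologs(homology, gene_maps[a], gene_maps[b], a, b)
            exon_pairs[(a, b)] = map_orthologs(
                exons[a], exons[b], species_a=a, species_b=b,
                min_identity=config.min_identity,
            )
        report["stages"][stage] = {
            f"{a}__{b}": {"gene": len(gene_pairs[(a, b)]), "exon": len(exon_pairs[(a, b)])}
            for a, b in combinations(config.species, 2)
        }

        stage = "dual_strand_filter"
        retained = {
            sp: remove_dual_strand_overlaps(probeset_beds[sp], transcripts[sp])
            for sp in config.species
        }
        filtered_pairs = {}
        for (a, b), pairs in exon_pairs.items():
            filtered_pairs[(a, b)] = [
                p for p in pairs if p.probeset_a in retained[a] and p.probeset_b in retained[b]
            ]
            pairs_to_frame(filtered_pairs[(a, b)]).to_csv(
                outdir / f"ortholog_pairs_{a}__{b}.tsv", sep="\t", index=False
            )
        report["stages"][stage] = {
            sp: {"retained": len(retained[sp])} for sp in config.species
        }

        stage = "divergence"
        div_reports = {}
        div_records = {}
        for (a, b), pairs in filtered_pairs.items():
            for prot in ("sense", "antisense"):
                rep = run_divergence_comparison(
                    averaged[(a, prot)], averaged[(b, prot)], pairs,
                    measure=config.measure,
                    threshold=config.expression_threshold,
                    rng=rng_by_pair[(a, b, prot)],
                )
                key = f"{a}__{b}__{prot}"
                div_reports[key] = rep.to_dict()
                div_records[(a, b, prot)] = rep.records
                rep.records.to_csv(outdir / f"divergence_{key}.tsv", sep="\t", index=False)
                rep.ecdf.to_csv(outdir / f"ecdf_{key}.tsv", sep="\t", index=False)
                corr = tissue_correlation_matrix(averaged[(a, prot)], averaged[(b, prot)], pairs)
                corr.to_csv(outdir / f"tissue_correlation_{key}.tsv", sep="\t")
        report["stages"][stage] = div_reports

        stage = "tissue_specificity"
        ts_summary = {}
        for sp in config.species:
            calls = call_tissue_specific(
                averaged[(sp, "antisense")],
                threshold=config.expression_threshold
                if config.expression_threshold is not None
                else 6.5,
                z_cut=config.z_cut,
                margin_cut=config.margin_cut,
                exclude_tissues=config.exclude_tissues,
            )
            calls_to_frame(calls).to_csv(
                outdir / f"tissue_specific_{sp}_antisense.tsv", sep="\t", index=False
            )
            ts_summary[sp] = {"n_calls": len(calls)}
        report["stages"][stage] = ts_summary

        stage = "novelty"
        refseq_index = build_reference_index(refseq, source="refseq-standin")
        est_index = build_reference_index(est, source="est-standin")
        nov_summary = {}
        for sp in config.species:
            table, summary = screen_probesets(exons[sp], refseq_index, est_index)
            table.to_csv(outdir / f"novelty_{sp}.tsv", sep="\t", index=False)
            nov_summary[sp] = summary
        report["stages"][stage] = nov_summary

        stage = "sense_antisense"
        sa_summary = {}
        for sp in config.species:
            recs = per_tissue_correlation(averaged[(sp, "sense")], averaged[(sp, "antisense")])
            records_to_frame(recs).to_csv(
                outdir / f"sense_antisense_{sp}.tsv", sep="\t", index=False
            )
            sa_summary[sp] = {
                "per_tissue_r": {c.scope: (c.r if c.defined else None) for c in recs}
            }
        for (a, b) in combinations(config.species, 2):
            try:
                rec = divergence_correlation(
                    div_records[(a, b, "sense")], div_records[(a, b, "antisense")]
                )
                sa_summary[f"{a}__{b}"] = {"divergence_r": rec.r, "n": rec.n}
            except ValueError as exc:
                sa_summary[f"{a}__{b}"] = {"divergence_r": None, "error": str(exc)}
        report["stages"][stage] = sa_summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    write_report(report, config, outdir)
    return report


_REQUIRED_REPORT_KEYS = ("stages", "seed")


def write_report(report: dict, config: PipelineConfig, out_dir: str | Path) -> None:
    """Write the aggregate report and the run manifest (schema-checked)."""
    outdir = Path(out_dir)
    for key in _REQUIRED_REPORT_KEYS:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for stage in STAGES:
        report["stages"].setdefault(stage, None)
    write_json(report, outdir / "report.json")
    manifest = {
        "package": "natcons",
        "version": __version__,
        "stages": list(STAGES),
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
    }
    write_json(manifest, outdir / "manifest.json")
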