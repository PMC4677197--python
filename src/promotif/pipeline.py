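"""End-to-end orchestration: scan -> count -> enrich -> correlate.

`run_pipeline` reads a motif collection, a population promoter FASTA and a
foreground gene list, and writes the full artifact set: per-hit BED,
gene x motif count matrix, enrichment table, correlation tables, per-motif
logo matrices, and a run manifest recording the configuration, input
checksums and the population/foreground/panel sizes actually used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .cooccurrence import correlation_matrix, rho_matrix
import pandas as pd

from .io import (
    iter_promoters_fasta,
    read_gene_list,
    read_pfm_collection,
    write_hits_bed,
    write_table,
)
from .matrices import encode_sequence, logo_matrix, pfm_to_ppm, ppm_to_pwm
from .model import MotifEnrichment
from .scan import scan_sequence

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs, outputs and tunables for a full pipeline run."""

    pfm_path: str
    population_fasta: str
    foreground_list: str
    out_dir: str
    rel_threshold: float = 0.95
    strands: str = "both"
    pseudocount_total: float = 0.8
    background_model: str = "uniform"
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_threshold <= 1.0:
            raise ValueError("rel_threshold must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")
        if self.background_model not in ("uniform", "empirical"):
            raise ValueError("background_model must be 'uniform' or 'empirical'")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _empirical_background(promoters) -> np.ndarray:
    """Mononucleotide frequencies over all promoters, N excluded."""
    totals = np.zeros(4, dtype=np.int64)
    for _, seq in promoters:
        codes = encode_sequence(seq)
        totals += np.bincount(codes[codes < 4], minlength=4)
    if totals.sum() == 0:
        raise ValueError("no unambiguous bases to estimate a background from")
    return totals / totals.sum()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a mapping of artifact name -> path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pfms = read_pfm_collection(config.pfm_path, skip_invalid=True)
    logger.info("parsed %d motif matrices", len(pfms))
    foreground = read_gene_list(config.foreground_list)

    if config.background_model == "empirical":
        # first streaming pass over the FASTA, sequences not retained
        background = _empirical_background(
            iter_promoters_fasta(config.population_fasta)
        )
        logger.info("empirical background: %s", np.round(background, 4))
    else:
        background = None

    ppms = [pfm_to_ppm(p, config.pseudocount_total, background) for p in pfms]
    pwms = [ppm_to_pwm(p) for p in ppms]

    artifacts: dict[str, Path] = {}

    logo_dir = out / "logos"
    logo_dir.mkdir(exist_ok=True)
    for ppm in ppms:
        path = logo_dir / f"{ppm.motif_id}_logo.tsv"
        write_table(logo_matrix(ppm), path)
    artifacts["logos"] = logo_dir

    logger.info(
        "scanning promoters x %d motifs (threshold %.2f, strands=%s)",
        len(pwms), config.rel_threshold, config.strands,
    )
    # single streaming pass: one promoter resident at a time, only the
    # count rows and the (small) hit records are accumulated
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    hits = []
    for gene_id, seq in iter_promoters_fasta(config.population_fasta):
        row = np.zeros(len(pwms), dtype=np.int64)
        for j, pwm in enumerate(pwms):
            gene_hits = scan_sequence(
                pwm, gene_id, seq, config.rel_threshold, config.strands
            )
            row[j] = len(gene_hits)
            hits.extend(gene_hits)
            logger.debug("%s x %s: %d hits", gene_id, pwm.motif_id, len(gene_hits))
        gene_ids.append(gene_id)
        rows.append(row)
    counts = pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, len(pwms)), dtype=np.int64),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[p.motif_id for p in pwms],
    )

    missing = set(foreground.gene_ids) - set(gene_ids)
    if missing:
        raise ValueError(
            f"foreground gene {sorted(missing)[0]!r} not present in population FASTA"
        )

    artifacts["hits_bed"] = out / "hits.bed"
    write_hits_bed(hits, artifacts["hits_bed"])
    artifacts["counts_tsv"] = out / "counts.tsv"
    write_table(counts, artifacts["counts_tsv"], index=True)

    model = MotifEnrichment(counts, foreground)
    results = model.fit(alpha=config.alpha)
    artifacts["enrichment_tsv"] = out / "enrichment.tsv"
    write_table(results.table, artifacts["enrichment_tsv"])
    logger.info(
        "enrichment: m=%d, Bonferroni cut %.6g, %d significant",
        results.m, results.threshold, len(results.significant_motifs),
    )

    fg_ids = model.foreground_ids
    artifacts["correlation_pairs_tsv"] = out / "correlation_pairs.tsv"
    write_table(correlation_matrix(counts, fg_ids), artifacts["correlation_pairs_tsv"])
    artifacts["correlation_matrix_tsv"] = out / "correlation_matrix.tsv"
    write_table(rho_matrix(counts, fg_ids), artifacts["correlation_matrix_tsv"], index=True)

    artifacts["summary_txt"] = out / "summary.txt"
    artifacts["summary_txt"].write_text(results.summary() + "\n")

    manifest = out / "manifest.txt"
    lines = [
        f"promotif version: {__version__}",
        f"timestamp: {datetime.now(timezone.utc).isoformat()}",
        "",
        "[inputs]",
        f"pfm_path = {config.pfm_path} (sha256 {_sha256(config.pfm_path)})",
        f"population_fasta = {config.population_fasta} "
        f"(sha256 {_sha256(config.population_fasta)})",
        f"foreground_list = {config.foreground_list} "
        f"(sha256 {_sha256(config.foreground_list)})",
        "",
        "[config]",
    ]
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {getattr(config, f.name)}")
    lines += [
        "",
        "[run]",
        f"motifs_parsed = {len(pfms)}",
        f"population_genes (N) = {len(gene_ids)}",
        f"foreground_genes (n) = {len(fg_ids)}",
        f"motifs_tested (m) = {results.m}",
        f"bonferroni_cut (alpha/m) = {results.threshold!r}",
        f"hits_retained = {len(hits)}",
        f"significant_motifs = {','.join(results.significant_motifs) or '-'}",
    ]
    manifest.write_text("\n".join(lines) + "\n")
    artifacts["manifest"] = manifest
    return artifacts
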