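"""Synthetic promoter studies with planted motif sites and known truth.

Real inputs for a promoter enrichment study — a genome-scale set of
fixed-length upstream sequences and a curated motif collection — are large
and external.  This module emulates them at configurable scale: i.i.d.
background promoters of chosen length and GC content, a foreground subset
(the "pathway" genes), and motif instances sampled from a PFM's column
distributions planted at controlled Poisson rates per promoter, with every
placement recorded in a truth table.  Because an enriched motif is planted
at a higher rate in the foreground than in the rest of the population, the
true enrichment signal is known by construction, enabling power and
type-I-error calibration of the whole pipeline.

Everything is a pure function of the configuration, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import PromoterSet, write_gene_list, write_promoters_fasta
from .matrices import BASES, PFM, pfm_to_ppm, reverse_complement

__all__ = [
    "SyntheticConfig",
    "Study",
    "generate_promoters",
    "plant_sites",
    "make_study",
    "random_pfm",
    "random_panel",
    "write_defective_pfm_collection",
]

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_promoters(
    n: int,
    length: int,
    gc_content: float = 0.5,
    seed=None,
    prefix: str = "g",
) -> PromoterSet:
    """n i.i.d. promoters with P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2.

    Gene ids are ``g000001`` ... in order; fully deterministic for a fixed
    seed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = _rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    records = []
    for i in range(n):
        codes = rng.choice(4, size=length, p=p)
        seq = base_arr[codes].tobytes().decode("ascii")
        records.append((f"{prefix}{i + 1:06d}", seq))
    return PromoterSet(records, validate=False)


def _sample_site(rng: np.random.Generator, probs: np.ndarray) -> str:
    """One site drawn column-wise from the (pseudocounted) PPM."""
    return "".join(
        BASES[rng.choice(4, p=probs[:, j])] for j in range(probs.shape[1])
    )


def plant_sites(
    promoters: PromoterSet,
    pfm: PFM,
    rate: float | Mapping[str, float],
    seed=None,
    *,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    consensus_only: bool = False,
    pseudocount_total: float = 0.8,
    retry_cap: int = 1000,
) -> tuple[PromoterSet, pd.DataFrame]:
    """Plant Poisson(rate) sites of one motif per promoter.

    Each site's sequence is sampled column-wise from the PFM's
    pseudocounted probabilities (or is the fixed consensus with
    ``consensus_only``), placed on a uniform strand at a uniform
    non-overlapping legal offset (rejection sampling with a retry cap),
    and substituted in place.  ``rate`` may be a scalar or a per-gene
    mapping (genes absent from the mapping get rate 0).  ``occupied`` —
    shared across calls when planting several motifs — guarantees
    non-overlap between motifs too.

    Returns the new PromoterSet and a truth table with columns
    gene_id, motif_id, start, strand, site_seq.
    """
    rng = _rng(seed)
    L = pfm.length
    probs = pfm_to_ppm(pfm, pseudocount_total).probs
    if occupied is None:
        occupied = {}
    per_gene = rate if isinstance(rate, Mapping) else None
    new_seqs: dict[str, str] = {}
    truth_rows: list[dict] = []
    for gene_id, seq in promoters:
        r = per_gene.get(gene_id, 0.0) if per_gene is not None else float(rate)
        if r < 0:
            raise ValueError("planting rate must be non-negative")
        n_sites = int(rng.poisson(r))
        if n_sites == 0:
            continue
        if len(seq) < L:
            raise ValueError(
                f"promoter {gene_id!r} shorter than motif {pfm.motif_id!r}"
            )
        intervals = occupied.setdefault(gene_id, [])
        for _ in range(n_sites):
            start = -1
            for _attempt in range(retry_cap):
                cand = int(rng.integers(0, len(seq) - L + 1))
                if all(not (cand < e and cand + L > s) for s, e in intervals):
                    start = cand
                    break
            if start < 0:
                raise RuntimeError(
                    f"site placement saturated in {gene_id!r} after {retry_cap} "
                    f"tries (rate {r} too high for promoter length)"
                )
            intervals.append((start, start + L))
            site = pfm.consensus if consensus_only else _sample_site(rng, probs)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else reverse_complement(site)
            seq = seq[:start] + inserted + seq[start + L :]
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "motif_id": pfm.motif_id,
                    "start": start,
                    "strand": strand,
                    "site_seq": site,
                }
            )
        new_seqs[gene_id] = seq
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "motif_id", "start", "strand", "site_seq"]
    )
    return promoters.with_sequences(new_seqs), truth


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design: sizes, composition, panel, planting rates, seed.

    ``planting_rate_fg`` applies to enriched motifs in foreground
    promoters; ``planting_rate_bg`` applies to enriched motifs elsewhere
    and to non-enriched motifs everywhere.  Equal rates therefore give a
    null study with no enrichment signal by construction.
    """

    n_foreground: int
    n_background: int
    motif_panel: tuple[PFM, ...]
    enriched_motifs: frozenset[str] = frozenset()
    promoter_length: int = 5000
    gc_content: float = 0.5
    planting_rate_fg: float = 2.0
    planting_rate_bg: float = 0.05
    consensus_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif_panel", tuple(self.motif_panel))
        object.__setattr__(self, "enriched_motifs", frozenset(self.enriched_motifs))
        if not 0 <= self.n_foreground <= self.n_background:
            raise ValueError("require 0 <= n_foreground <= n_background")
        if self.planting_rate_fg < 0 or self.planting_rate_bg < 0:
            raise ValueError("planting rates must be non-negative")
        if not self.motif_panel:
            raise ValueError("motif panel is empty")
        max_len = max(p.length for p in self.motif_panel)
        if self.promoter_length < max_len:
            raise ValueError("promoter_length shorter than the longest motif")
        panel_ids = {p.motif_id for p in self.motif_panel}
        if len(panel_ids) != len(self.motif_panel):
            raise ValueError("duplicate motif ids in panel")
        unknown = self.enriched_motifs - panel_ids
        if unknown:
            raise ValueError(f"enriched motifs not in panel: {sorted(unknown)}")


@dataclass(frozen=True)
class Study:
    """A generated study: population promoters, foreground ids, truth."""

    population: PromoterSet
    foreground_ids: tuple[str, ...]
    truth: pd.DataFrame
    config: SyntheticConfig

    @property
    def foreground(self) -> PromoterSet:
        return self.population.subset(self.foreground_ids)


def make_study(config: SyntheticConfig, out_dir: str | Path | None = None) -> Study:
    """Generate a full study from a configuration; optionally write files.

    The population is generated first; the foreground is its first
    ``n_foreground`` genes.  Enriched motifs are planted at
    ``planting_rate_fg`` in foreground promoters and ``planting_rate_bg``
    in the rest; non-enriched motifs at ``planting_rate_bg`` everywhere.
    With ``out_dir`` set, writes population.fa, foreground.fa,
    foreground_genes.txt, truth.tsv and config.toml.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.motif_panel))
    population = generate_promoters(
        config.n_background, config.promoter_length, config.gc_content, seed=children[0]
    )
    fg_ids = tuple(population.gene_ids[: config.n_foreground])
    fg_set = set(fg_ids)
    occupied: dict[str, list[tuple[int, int]]] = {}
    truths = []
    for pfm, child in zip(config.motif_panel, children[1:]):
        if pfm.motif_id in config.enriched_motifs:
            rates = {
                g: (config.planting_rate_fg if g in fg_set else config.planting_rate_bg)
                for g in population.gene_ids
            }
        else:
            rates = {g: config.planting_rate_bg for g in population.gene_ids}
        population, truth = plant_sites(
            population,
            pfm,
            rates,
            seed=np.random.default_rng(child),
            occupied=occupied,
            consensus_only=config.consensus_only,
        )
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(
        columns=["gene_id", "motif_id", "start", "strand", "site_seq"]
    )
    study = Study(
        population=population, foreground_ids=fg_ids, truth=truth, config=config
    )
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _write_study(study: Study, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_promoters_fasta(study.population, out_dir / "population.fa")
    write_promoters_fasta(study.foreground, out_dir / "foreground.fa")
    write_gene_list(study.foreground_ids, out_dir / "foreground_genes.txt")
    study.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    c = study.config
    lines = [
        f"n_foreground = {c.n_foreground}",
        f"n_background = {c.n_background}",
        f"promoter_length = {c.promoter_length}",
        f"gc_content = {c.gc_content}",
        f"planting_rate_fg = {c.planting_rate_fg}",
        f"planting_rate_bg = {c.planting_rate_bg}",
        f"consensus_only = {str(c.consensus_only).lower()}",
        f"seed = {c.seed}",
        "motif_panel = [{}]".format(
            ", ".join(f'"{p.motif_id}"' for p in c.motif_panel)
        ),
        "enriched_motifs = [{}]".format(
            ", ".join(f'"{m}"' for m in sorted(c.enriched_motifs))
        ),
    ]
    (out_dir / "config.toml").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic motif collections


def random_pfm(
    seed=None,
    motif_id: str = "SYN0001",
    name: str = "synTF",
    length: int | None = None,
    depth: int = 20,
    concentration: float = 0.12,
) -> PFM:
    """A random informative PFM (synthetic stand-in for a curated motif).

    Column base probabilities are Dirichlet(concentration) draws — small
    concentration gives peaked, binding-site-like columns — and counts are
    a multinomial of ``depth`` observations per column.  Lengths default
    to 8-14 bp, the range typical of curated vertebrate motifs; very short
    motifs saturate gene-level presence at genome scale and are not
    representative of a curated collection.
    """
    rng = _rng(seed)
    if length is None:
        length = int(rng.integers(8, 15))
    counts = np.zeros((4, length), dtype=np.int64)
    for j in range(length):
        p = rng.dirichlet(np.full(4, concentration))
        counts[:, j] = rng.multinomial(depth, p)
    return PFM(motif_id=motif_id, name=name, counts=counts)


def random_panel(n: int, seed=None, prefix: str = "SYN") -> list[PFM]:
    """n distinct random PFMs named ``SYN0001`` ..."""
    rng = _rng(seed)
    return [
        random_pfm(rng, motif_id=f"{prefix}{i + 1:04d}", name=f"synTF{i + 1}")
        for i in range(n)
    ]


_DEFECTS = ("missing_row", "ragged", "negative", "non_numeric", "zero_column")


def write_defective_pfm_collection(
    path: str | Path,
    n_total: int = 68,
    n_defective: int = 6,
    seed=None,
) -> list[str]:
    """Write a JASPAR-style file where some records are incomplete.

    Emulates a curated collection in which a handful of matrices cannot be
    turned into weight matrices (missing or ragged rows, negative or
    non-numeric entries, an all-zero column).  Returns the ids of the
    valid records, in file order.
    """
    if not 0 <= n_defective <= n_total:
        raise ValueError("require 0 <= n_defective <= n_total")
    rng = _rng(seed)
    pfms = random_panel(n_total, seed=rng, prefix="MA")
    bad = set(rng.choice(n_total, size=n_defective, replace=False).tolist())
    lines: list[str] = []
    valid_ids: list[str] = []
    for i, pfm in enumerate(pfms):
        lines.append(f">{pfm.motif_id} {pfm.name}")
        rows = {b: [str(int(c)) for c in pfm.counts[k]] for k, b in enumerate(BASES)}
        if i in bad:
            kind = _DEFECTS[sorted(bad).index(i) % len(_DEFECTS)]
            if kind == "missing_row":
                del rows["T"]
            elif kind == "ragged":
                rows["C"] = rows["C"][:-1]
            elif kind == "negative":
                rows["A"][0] = "-3"
            elif kind == "non_numeric":
                rows["G"][0] = "NA"
            elif kind == "zero_column":
                for b in rows:
                    rows[b][0] = "0"
        else:
            valid_ids.append(pfm.motif_id)
        for b in BASES:
            if b in rows:
                lines.append(f"{b} [ {' '.join(rows[b])} ]")
    Path(path).write_text("\n".join(lines) + "\n")
    return valid_ids
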