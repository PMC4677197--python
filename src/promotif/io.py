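"""Readers and writers: JASPAR PFM text, promoter FASTA, gene lists, BED, TSV.

The JASPAR plain-text dialects accepted are the bare four-row form::

    >MA0003 TFAP2A
    0  0 22 20
    0  0  0  0
    ...

and the bracketed, row-labelled form (labels override positional order)::

    >MA0003 TFAP2A
    A [  0  0 22 20 ]
    C [  0  0  0  0 ]
    ...

A record is *incomplete* (and rejected, or skipped with ``skip_invalid``)
when a nucleotide row is missing or duplicated, rows have unequal lengths,
an entry is negative or non-numeric, or a column is all zero — the failure
modes that block reconstruction of a position weight matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .matrices import BASES, PFM, reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .scan import MotifHit

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterSet",
    "GeneSet",
    "read_pfm_collection",
    "write_pfm_collection",
    "read_promoters_fasta",
    "iter_promoters_fasta",
    "write_promoters_fasta",
    "read_gene_list",
    "write_gene_list",
    "write_hits_bed",
    "write_table",
]

_VALID_CHARS = set("ACGTN")


class PromoterSet:
    """Ordered collection of (gene_id, upstream sequence) records.

    Sequences are stored uppercase over the alphabet {A, C, G, T, N};
    gene ids are unique.  Iterating yields ``(gene_id, sequence)`` pairs in
    input order; indexing by gene id returns the sequence.
    """

    def __init__(self, records: Iterable[tuple[str, str]], validate: bool = True):
        self._ids: list[str] = []
        self._seqs: dict[str, str] = {}
        for gene_id, seq in records:
            seq = seq.upper()
            if validate:
                if gene_id in self._seqs:
                    raise ValueError(f"duplicate gene id {gene_id!r}")
                if not seq:
                    raise ValueError(f"empty sequence for gene {gene_id!r}")
                bad = set(seq) - _VALID_CHARS
                if bad:
                    raise ValueError(
                        f"illegal character {sorted(bad)[0]!r} in record {gene_id!r}"
                    )
            self._ids.append(gene_id)
            self._seqs[gene_id] = seq

    @property
    def gene_ids(self) -> list[str]:
        return list(self._ids)

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for g in self._ids:
            yield g, self._seqs[g]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._seqs

    def __getitem__(self, gene_id: str) -> str:
        return self._seqs[gene_id]

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        """Records for the given ids, preserving this set's order."""
        wanted = set(gene_ids)
        missing = wanted - set(self._ids)
        if missing:
            raise KeyError(f"gene ids not in promoter set: {sorted(missing)[:5]}")
        return PromoterSet(
            ((g, self._seqs[g]) for g in self._ids if g in wanted), validate=False
        )

    def reverse_complement(self) -> "PromoterSet":
        return PromoterSet(
            ((g, reverse_complement(s)) for g, s in self), validate=False
        )

    def with_sequences(self, seqs: dict[str, str]) -> "PromoterSet":
        """Copy with some sequences replaced (same ids, same order)."""
        return PromoterSet(
            ((g, seqs.get(g, self._seqs[g])) for g in self._ids), validate=False
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids (e.g. the pathway foreground)."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


# ---------------------------------------------------------------------------
# JASPAR PFM text

_ROW_RE = re.compile(r"^\s*([ACGTacgt])\s*[\[\s]")


def _parse_record(header: str, body: list[str]) -> PFM:
    tokens = header[1:].split()
    if not tokens:
        raise ValueError("header line has no motif id")
    motif_id = tokens[0]
    name = " ".join(tokens[1:])

    labelled: dict[str, list[float]] = {}
    bare: list[list[float]] = []
    for line in body:
        m = _ROW_RE.match(line)
        if m:
            label = m.group(1).upper()
            payload = line[m.end(1):]
        else:
            label = None
            payload = line
        payload = payload.replace("[", " ").replace("]", " ")
        try:
            values = [float(tok) for tok in payload.split()]
        except ValueError as exc:
            raise ValueError(f"PFM {motif_id!r}: non-numeric entry ({exc})") from None
        if not values:
            raise ValueError(f"PFM {motif_id!r}: empty count row")
        if label is not None:
            if label in labelled:
                raise ValueError(f"PFM {motif_id!r}: duplicate row for base {label}")
            labelled[label] = values
        else:
            bare.append(values)

    if labelled and bare:
        raise ValueError(f"PFM {motif_id!r}: mixed labelled and unlabelled rows")
    if labelled:
        missing = [b for b in BASES if b not in labelled]
        if missing:
            raise ValueError(f"PFM {motif_id!r}: missing row for base {missing[0]}")
        rows = [labelled[b] for b in BASES]
    else:
        if len(bare) != 4:
            raise ValueError(
                f"PFM {motif_id!r}: expected 4 nucleotide rows, found {len(bare)}"
            )
        rows = bare

    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"PFM {motif_id!r}: rows have unequal lengths {sorted(lengths)}")
    # PFM __post_init__ enforces non-negativity, integrality, no all-zero column
    return PFM(motif_id=motif_id, name=name, counts=rows)


def read_pfm_collection(path: str | Path, skip_invalid: bool = False) -> list[PFM]:
    """Parse a JASPAR plain-text file into PFMs, in file order.

    With ``skip_invalid``, records failing the invariants are logged and
    dropped; otherwise the first failure raises a ``ValueError`` naming the
    offending motif.  A duplicate motif id is always an error, and a file
    yielding no valid matrices is an error.
    """
    path = Path(path)
    text = path.read_text()
    records: list[tuple[str, list[str]]] = []
    header: str | None = None
    body: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, body))
            header, body = line, []
        elif header is not None:
            body.append(line)
        else:
            raise ValueError(f"{path}: data before first '>' header")

    if header is not None:
        records.append((header, body))

    pfms: list[PFM] = []
    seen: set[str] = set()
    n_skipped = 0
    for hdr, lines in records:
        rec_id = hdr[1:].split()[0] if hdr[1:].split() else "<unnamed>"
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate motif id {rec_id!r}")
        try:
            pfm = _parse_record(hdr, lines)
        except ValueError as exc:
            if skip_invalid:
                n_skipped += 1
                logger.warning("skipping invalid matrix %s: %s", rec_id, exc)
                seen.add(rec_id)
                continue
            raise
        seen.add(pfm.motif_id)
        pfms.append(pfm)

    if not pfms:
        raise ValueError(f"{path}: no valid matrices")
    if n_skipped:
        logger.info("parsed %d matrices, skipped %d invalid", len(pfms), n_skipped)
    return pfms


def write_pfm_collection(pfms: Iterable[PFM], path: str | Path) -> None:
    """Write PFMs in the bracketed JASPAR dialect (round-trips exactly)."""
    lines: list[str] = []
    for pfm in pfms:
        header = f">{pfm.motif_id} {pfm.name}".rstrip()
        lines.append(header)
        for i, base in enumerate(BASES):
            row = " ".join(str(int(c)) for c in pfm.counts[i])
            lines.append(f"{base} [ {row} ]")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA / gene lists


def iter_promoters_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream validated (gene_id, SEQUENCE) pairs from a FASTA file.

    Record ids are the first whitespace-delimited token after ``>``;
    sequences are uppercased and must be over {A, C, G, T, N}.  Duplicate
    ids, empty sequences and illegal characters raise ``ValueError``.
    """
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        gene_id = record.id
        if gene_id in seen:
            raise ValueError(f"duplicate FASTA id {gene_id!r}")
        seen.add(gene_id)
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {gene_id!r}")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"illegal character {sorted(bad)[0]!r} in record {gene_id!r}"
            )
        yield gene_id, seq


def read_promoters_fasta(path: str | Path) -> PromoterSet:
    """Load a promoter FASTA into a :class:`PromoterSet`."""
    return PromoterSet(iter_promoters_fasta(path), validate=False)


def write_promoters_fasta(promoters: PromoterSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in promoters:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene id per line; '#' starts a comment; blank lines ignored."""
    path = Path(path)
    ids = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    if not ids:
        raise ValueError(f"{path}: no gene ids")
    return GeneSet(name=name or path.stem, gene_ids=frozenset(ids))


def write_gene_list(gene_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


# ---------------------------------------------------------------------------
# BED / TSV output


def write_hits_bed(hits: Iterable["MotifHit"], path: str | Path) -> None:
    """BED6 output, promoter-relative 0-based half-open coordinates.

    chrom = gene id, name = motif id, score = round(1000 * relative score)
    clamped to [0, 1000]; lines ordered by gene id then start ('+' before
    '-' at equal start).
    """
    rows = sorted(hits, key=lambda h: (h.gene_id, h.start, h.strand))
    with open(path, "w") as fh:
        for h in rows:
            score = min(1000, max(0, round(1000 * h.relative_score)))
            fh.write(
                f"{h.gene_id}\t{h.start}\t{h.end}\t{h.motif_id}\t{score}\t{h.strand}\n"
            )


def write_table(rows: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Tab-separated output with a header row.

    Floats use Python's shortest round-trip representation so output files
    are diff-stable across runs.
    """
    df = rows.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda v: repr(float(v)) if pd.notna(v) else "nan")
    df.to_csv(path, sep="\t", index=index)
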