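"""Sequence records and file I/O: FASTA, pair TSVs, truth labels, embedding matrices.

DNA sequences are upper-case strings over {A, C, G, T, N}. All genomic
coordinates in the package are 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .exceptions import AlphabetError, DegenerateInputError, FormatError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence, optionally tagged with its species/genome of origin."""

    id: str
    seq: str
    species_id: Optional[str] = None
    genome_id: Optional[str] = None

    def __post_init__(self):
        if not self.seq:
            raise DegenerateInputError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Complement each base (A<->T, C<->G, N->N), then reverse the sequence."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"characters outside ACGTN: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords.

    The header token before the first whitespace becomes the id; sequence is
    case-folded to upper. Raises FormatError on malformed input and
    DegenerateInputError on an empty file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: not FASTA "
                        "(expected '>' header)")
                break
    records = []
    seen = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(SeqRecord(id=rec.id, seq=seq))
    except ValueError as e:  # Biopython signals malformed FASTA this way
        raise FormatError(f"{path}: {e}") from e
    if not records:
        raise DegenerateInputError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Pair TSVs

PAIR_COLUMNS = ("anchor", "positive", "genome_id")


def write_pairs(pairs, path: str | os.PathLike) -> None:
    """Write contrastive pairs as a 3-column TSV (anchor, positive, genome_id)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(f"{p.anchor.seq}\t{p.positive.seq}\t{p.genome_id}\n")


def read_pairs(path: str | os.PathLike):
    """Read pairs written by :func:`write_pairs`. Returns a list of SequencePair."""
    from .pairs import SequencePair  # local import avoids a cycle

    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PAIR_COLUMNS:
            raise FormatError(f"{path}: row 1: bad header {header!r}")
        for rowno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}: row {rowno}: expected 3 columns, got {len(fields)}"
                )
            a, p, gid = fields
            pairs.append(
                SequencePair(
                    anchor=SeqRecord(id=f"a{rowno - 2}", seq=a, genome_id=gid),
                    positive=SeqRecord(id=f"p{rowno - 2}", seq=p, genome_id=gid),
                    genome_id=gid,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Truth labels and embedding matrices


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    """Read an `id <tab> species` truth table into a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["id", "species"]:
        raise FormatError(f"{path}: expected header 'id\\tspecies'")
    return df


def write_truth(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class EmbeddingMatrix:
    """N fixed-size embedding rows keyed by sequence id, plus provenance."""

    ids: list[str]
    rows: np.ndarray  # (N, D) float
    source: str = "unknown"

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.ids):
            raise ValueError("rows must be (N, D) with N == len(ids)")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("non-finite entries in embedding matrix")

    @property
    def shape(self):
        return self.rows.shape


def write_embeddings(emb: EmbeddingMatrix, path: str | os.PathLike) -> None:
    """TSV: first column `id`, remaining columns embedding floats."""
    df = pd.DataFrame(emb.rows, index=pd.Index(emb.ids, name="id"))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_embeddings(path: str | os.PathLike, source: str = "file") -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return EmbeddingMatrix(ids=[str(i) for i in df.index], rows=df.to_numpy(float),
                           source=source)
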