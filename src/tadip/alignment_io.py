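"""Hit-summary I/O: the five-column alignment format, BLAST outfmt-6, taxonomy tables.

The mixture model consumes per-read hit summaries: for read *j* and candidate
genome *i*, the matched length ``M_ji`` (identical bases) and the alignment
length.  Because alignment lengths for a read's hits are nearly identical,
each read keeps a single length ``L_j = max_i L_ji``.  Hits are stored sparsely
(reads typically align to a handful of candidate genomes, not all of them).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "HitRecord",
    "AlignmentTable",
    "TamerDialect",
    "TaxonomyTable",
    "parse_tamer_input",
    "parse_blast_tabular",
    "read_taxonomy",
    "write_tamer_input",
    "write_assignments",
]

#: Taxonomic ranks, most specific first.
RANKS = ("species", "genus", "family", "order", "class", "phylum", "kingdom")


@dataclass(frozen=True)
class HitRecord:
    """One (read, genome) alignment summary."""

    read_id: str
    genome_id: str
    taxon_id: str
    matched_length: int
    alignment_length: int

    def __post_init__(self) -> None:
        if self.alignment_length <= 0:
            raise ValueError(
                f"hit ({self.read_id}, {self.genome_id}): alignment_length "
                f"{self.alignment_length} must be positive"
            )
        if not 0 <= self.matched_length <= self.alignment_length:
            raise ValueError(
                f"hit ({self.read_id}, {self.genome_id}): matched_length "
                f"{self.matched_length} outside [0, {self.alignment_length}]"
            )


class AlignmentTable:
    """Sparse per-read candidate-hit table.

    Parameters
    ----------
    read_ids, genome_ids
        Ordered identifiers (first-appearance order as parsed).
    indptr, hit_genome, hit_matched
        CSR-style storage: hits of read ``j`` occupy the slice
        ``indptr[j]:indptr[j+1]`` of ``hit_genome`` (genome indices) and
        ``hit_matched`` (matched lengths ``M_ji``).
    read_length
        ``L_j``, the maximum alignment length over read ``j``'s hits.
    taxon_ids
        Optional per-genome taxon identifier (may be empty strings).
    """

    def __init__(
        self,
        read_ids: Sequence[str],
        genome_ids: Sequence[str],
        indptr: np.ndarray,
        hit_genome: np.ndarray,
        hit_matched: np.ndarray,
        read_length: np.ndarray,
        taxon_ids: Sequence[str] | None = None,
    ) -> None:
        self.read_ids = np.asarray(read_ids, dtype=object)
        self.genome_ids = np.asarray(genome_ids, dtype=object)
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.hit_genome = np.asarray(hit_genome, dtype=np.int64)
        self.hit_matched = np.asarray(hit_matched, dtype=np.int64)
        self.read_length = np.asarray(read_length, dtype=np.int64)
        self.taxon_ids = (
            np.asarray(taxon_ids, dtype=object)
            if taxon_ids is not None
            else np.asarray([""] * len(self.genome_ids), dtype=object)
        )
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[HitRecord]) -> "AlignmentTable":
        """Build a table from hit records.

        Duplicate (read, genome) pairs are collapsed keeping the largest
        matched length (the best HSP).  Read and genome order is
        first-appearance order.
        """
        read_index: dict[str, int] = {}
        genome_index: dict[str, int] = {}
        taxon_by_genome: dict[str, str] = {}
        # per read: {genome_idx: matched}, and max alignment length
        hits: list[dict[int, int]] = []
        lengths: list[int] = []
        for rec in records:
            j = read_index.setdefault(rec.read_id, len(read_index))
            if j == len(hits):
                hits.append({})
                lengths.append(0)
            i = genome_index.setdefault(rec.genome_id, len(genome_index))
            if rec.taxon_id and not taxon_by_genome.get(rec.genome_id):
                taxon_by_genome[rec.genome_id] = rec.taxon_id
            prev = hits[j].get(i)
            if prev is None or rec.matched_length > prev:
                hits[j][i] = rec.matched_length
            lengths[j] = max(lengths[j], rec.alignment_length)
        if not hits:
            raise ValueError("no hit records provided")
        indptr = np.zeros(len(hits) + 1, dtype=np.int64)
        hit_genome: list[int] = []
        hit_matched: list[int] = []
        for j, h in enumerate(hits):
            for i in sorted(h):
                hit_genome.append(i)
                hit_matched.append(h[i])
            indptr[j + 1] = len(hit_genome)
        genome_ids = list(genome_index)
        return cls(
            read_ids=list(read_index),
            genome_ids=genome_ids,
            indptr=indptr,
            hit_genome=np.asarray(hit_genome),
            hit_matched=np.asarray(hit_matched),
            read_length=np.asarray(lengths),
            taxon_ids=[taxon_by_genome.get(g, "") for g in genome_ids],
        )

    # -- properties ----------------------------------------------------

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_hits(self) -> int:
        return len(self.hit_genome)

    @property
    def hit_read(self) -> np.ndarray:
        """Read index of every stored hit (expanded from ``indptr``)."""
        return np.repeat(
            np.arange(self.n_reads), np.diff(self.indptr)
        )

    def hits_of(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Genome indices and matched lengths of read ``j``."""
        sl = slice(self.indptr[j], self.indptr[j + 1])
        return self.hit_genome[sl], self.hit_matched[sl]

    # -- validation / conversion --------------------------------------

    def _validate(self) -> None:
        if self.indptr[0] != 0 or self.indptr[-1] != self.n_hits:
            raise ValueError("indptr does not index the hit arrays")
        counts = np.diff(self.indptr)
        if (counts < 1).any():
            j = int(np.argmax(counts < 1))
            raise ValueError(f"read {self.read_ids[j]!r} has no hits")
        L = self.read_length[self.hit_read]
        if (self.hit_matched > L).any():
            bad = int(np.argmax(self.hit_matched > L))
            j = int(np.searchsorted(self.indptr, bad, side="right") - 1)
            raise ValueError(
                f"read {self.read_ids[j]!r}: matched_length "
                f"{self.hit_matched[bad]} exceeds read length {L[bad]}"
            )
        if self.hit_genome.size and (
            self.hit_genome.min() < 0 or self.hit_genome.max() >= self.n_genomes
        ):
            raise ValueError("hit genome index out of range")

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format view: one row per hit, TAMER column order."""
        jj = self.hit_read
        return pd.DataFrame(
            {
                "read_id": self.read_ids[jj],
                "genome_id": self.genome_ids[self.hit_genome],
                "taxon_id": self.taxon_ids[self.hit_genome],
                "matched_length": self.hit_matched,
                "alignment_length": self.read_length[jj],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignmentTable):
            return NotImplemented
        return (
            np.array_equal(self.read_ids, other.read_ids)
            and np.array_equal(self.genome_ids, other.genome_ids)
            and np.array_equal(self.indptr, other.indptr)
            and np.array_equal(self.hit_genome, other.hit_genome)
            and np.array_equal(self.hit_matched, other.hit_matched)
            and np.array_equal(self.read_length, other.read_length)
        )

    def __repr__(self) -> str:
        return (
            f"AlignmentTable(n_reads={self.n_reads}, "
            f"n_genomes={self.n_genomes}, n_hits={self.n_hits})"
        )


@dataclass(frozen=True)
class TamerDialect:
    """Column layout of the five-column hit-summary format.

    Field order is explicit configuration, never sniffed.
    """

    delimiter: str = "\t"
    columns: tuple[str, ...] = (
        "read_id",
        "genome_id",
        "taxon_id",
        "matched_length",
        "alignment_length",
    )
    header: bool = True

    def __post_init__(self) -> None:
        required = {
            "read_id",
            "genome_id",
            "taxon_id",
            "matched_length",
            "alignment_length",
        }
        if set(self.columns) != required:
            raise ValueError(
                f"dialect columns must be a permutation of {sorted(required)}"
            )


def _records_from_frame(df: pd.DataFrame, path: Path) -> AlignmentTable:
    records = []
    for row in df.itertuples(index=False):
        line_no = getattr(row, "Index", None)
        try:
            records.append(
                HitRecord(
                    read_id=str(row.read_id),
                    genome_id=str(row.genome_id),
                    taxon_id="" if pd.isna(row.taxon_id) else str(row.taxon_id),
                    matched_length=int(row.matched_length),
                    alignment_length=int(row.alignment_length),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad record {tuple(row)}: {exc}") from exc
    return AlignmentTable.from_records(records)


def parse_tamer_input(
    path: str | Path, dialect: TamerDialect = TamerDialect()
) -> AlignmentTable:
    """Parse a five-column hit-summary file into an :class:`AlignmentTable`.

    Duplicate (read, genome) pairs keep the largest matched length.
    Malformed lines raise ``ValueError`` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=0 if dialect.header else None,
            names=dialect.columns,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed file: {exc}") from exc
    offset = 2 if dialect.header else 1
    for col in ("matched_length", "alignment_length"):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            line = int(np.argmax(converted.isna().to_numpy())) + offset
            raise ValueError(f"{path}: line {line}: non-numeric {col}")
        df[col] = converted
    df = df[list(TamerDialect().columns)]
    return _records_from_frame(df, path)


#: Default BLAST -outfmt 6 field order.
BLAST6_DEFAULT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def parse_blast_tabular(
    path: str | Path,
    columns: Sequence[str] = BLAST6_DEFAULT_COLUMNS,
) -> AlignmentTable:
    """Parse BLAST tabular (``-outfmt 6``) output.

    ``columns`` declares the field order actually written by the BLAST run
    (outfmt-6 field order is user-defined, so it is never guessed).  The
    matched length is taken from ``nident`` when present, otherwise
    reconstructed as ``round(pident / 100 * length)``; ``staxids``
    populates the taxon identifier when present.
    """
    path = Path(path)
    columns = tuple(columns)
    for req in ("qseqid", "sseqid", "length"):
        if req not in columns:
            raise ValueError(f"BLAST columns config missing required field {req!r}")
    if "nident" not in columns and "pident" not in columns:
        raise ValueError("BLAST columns config needs either 'nident' or 'pident'")
    df = pd.read_csv(path, sep="\t", header=None, names=columns, dtype=str)
    length = pd.to_numeric(df["length"])
    if "nident" in columns:
        matched = pd.to_numeric(df["nident"]).astype(int)
    else:
        matched = (
            (pd.to_numeric(df["pident"]) / 100.0 * length).round().astype(int)
        )
    out = pd.DataFrame(
        {
            "read_id": df["qseqid"],
            "genome_id": df["sseqid"],
            "taxon_id": df["staxids"] if "staxids" in columns else "",
            "matched_length": matched,
            "alignment_length": length.astype(int),
        }
    )
    return _records_from_frame(out, path)


@dataclass
class TaxonomyTable:
    """Genome → lineage map; lineages are 7-tuples ordered Species→Kingdom."""

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, lin in self.lineages.items():
            if len(lin) != len(RANKS):
                raise ValueError(
                    f"genome {g!r}: lineage has {len(lin)} slots, expected {len(RANKS)}"
                )

    def lineage(self, genome_id: str) -> tuple[str, ...]:
        try:
            return self.lineages[genome_id]
        except KeyError:
            raise KeyError(f"genome {genome_id!r} missing from taxonomy") from None

    def taxon(self, genome_id: str, rank: str) -> str:
        return self.lineage(genome_id)[RANKS.index(rank)]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.lineages


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a lineage table: genome_id + 7 rank columns, Species→Kingdom.

    Empty cells become ``"unknown"``.  A genome listed twice with
    conflicting lineages is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    if df.shape[1] != 1 + len(RANKS):
        raise ValueError(
            f"{path}: expected {1 + len(RANKS)} columns (genome_id + ranks), "
            f"got {df.shape[1]}"
        )
    lineages: dict[str, tuple[str, ...]] = {}
    for row in df.itertuples(index=False):
        g = str(row[0])
        lin = tuple(str(v) if str(v) else "unknown" for v in row[1:])
        if g in lineages and lineages[g] != lin:
            raise ValueError(f"{path}: genome {g!r} has conflicting lineages")
        lineages[g] = lin
    return TaxonomyTable(lineages)


def write_tamer_input(
    table: AlignmentTable,
    path: str | Path,
    dialect: TamerDialect = TamerDialect(),
) -> None:
    """Write an :class:`AlignmentTable` in the five-column format."""
    df = table.to_dataframe()[list(dialect.columns)]
    df.to_csv(path, sep=dialect.delimiter, index=False, header=dialect.header)


def write_assignments(
    assignments: Mapping[str, Mapping[str, float]],
    path: str | Path,
) -> None:
    """Write per-read assignments as TSV rows ``read_id, genome_id, posterior``.

    Multiply-assigned reads (posterior ties) emit one row per genome.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "genome_id", "posterior"])
        for read_id, genomes in assignments.items():
            for genome_id, prob in genomes.items():
                writer.writerow([read_id, genome_id, f"{prob:.6g}"])
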