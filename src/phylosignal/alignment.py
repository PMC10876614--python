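"""Multi-locus alignment handling: FASTA I/O, concatenation, occupancy, trimming.

The central container is :class:`Alignment`, a rectangular taxa x sites
character matrix over nucleotide symbols (IUPAC codes, gap ``-`` and missing
``?``). Loci are stitched into a supermatrix by :func:`concatenate`, which
also produces the :class:`PartitionScheme` mapping each locus to its 1-based
inclusive column range (the RAxML partition-file convention). Occupancy and
column trimming reproduce the matrix-construction choices typical of small
multi-locus datasets: a taxon counts as sampled for a locus if it has at
least one non-missing character there, and a column is dropped when its
missing fraction strictly exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: symbols treated as missing data for occupancy and trimming purposes
MISSING_SYMBOLS = frozenset("?-")

#: accepted residue symbols (uppercase canonical form)
VALID_SYMBOLS = frozenset("ACGTURYSWKMBDHVN?-")


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments, duplicate taxa or unparseable input."""


@dataclass(frozen=True)
class PartitionEntry:
    locus_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def n_sites(self) -> int:
        return self.end - self.start + 1

    def column_indices(self) -> np.ndarray:
        """0-based column indices covered by this locus."""
        return np.arange(self.start - 1, self.end)


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered, contiguous, non-overlapping locus -> column-range mapping."""

    entries: tuple[PartitionEntry, ...]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("partition scheme must contain at least one entry")
        ids = [e.locus_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in partition scheme")
        pos = 1
        for e in self.entries:
            if e.start != pos or e.end < e.start:
                raise ValueError(
                    f"partition entries must tile columns contiguously; "
                    f"locus {e.locus_id!r} spans {e.start}-{e.end}, expected start {pos}"
                )
            pos = e.end + 1

    @property
    def n_columns(self) -> int:
        return self.entries[-1].end

    @property
    def locus_ids(self) -> list[str]:
        return [e.locus_id for e in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, locus_id: str) -> PartitionEntry:
        for e in self.entries:
            if e.locus_id == locus_id:
                return e
        raise KeyError(locus_id)

    def locus_of_column(self, col: int) -> str:
        """Locus id owning 0-based column ``col``."""
        for e in self.entries:
            if e.start - 1 <= col <= e.end - 1:
                return e.locus_id
        raise IndexError(col)


class Alignment:
    """Rectangular taxa x sites character matrix.

    Parameters
    ----------
    taxa : sequence of str
        Unique taxon labels, one per row.
    matrix : array-like of single characters, shape (n_taxa, n_sites)
        Stored uppercase.
    """

    def __init__(self, taxa: Sequence[str], matrix):
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            raise AlignmentFormatError("duplicate taxon labels")
        arr = np.asarray(matrix, dtype="<U1")
        if arr.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if arr.shape[0] != len(taxa):
            raise AlignmentFormatError("row count does not match taxon count")
        arr = np.char.upper(arr)
        bad = set(np.unique(arr)) - VALID_SYMBOLS
        if bad:
            raise AlignmentFormatError(f"invalid symbols in alignment: {sorted(bad)}")
        self.taxa = taxa
        self.matrix = arr

    # -- basic protocol ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.taxa == other.taxa and np.array_equal(self.matrix, other.matrix)

    def __repr__(self) -> str:
        return f"<Alignment {self.n_taxa} taxa x {self.n_columns} columns>"

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of cells counting as missing ('?' or '-')."""
        return (self.matrix == "?") | (self.matrix == "-")

    def subset_taxa(self, taxa: Iterable[str]) -> "Alignment":
        taxa = list(taxa)
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(taxa, self.matrix[idx])

    def subset_columns(self, cols) -> "Alignment":
        return Alignment(self.taxa, self.matrix[:, cols])

    @classmethod
    def from_sequences(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        taxa, seqs = [], []
        for name, seq in pairs:
            taxa.append(name)
            seqs.append(list(seq))
        if not taxa:
            raise AlignmentFormatError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentFormatError("ragged alignment: unequal sequence lengths")
        return cls(taxa, np.array(seqs, dtype="<U1"))


# -- FASTA I/O -------------------------------------------------------------

def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment` (uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    return Alignment.from_sequences((r.id, str(r.seq)) for r in records)


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=taxon, description="")
        for taxon, row in zip(alignment.taxa, alignment.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")


# -- partition file I/O (RAxML style: "DNA, gene1 = 1-500") -----------------

def read_partition_file(path) -> PartitionScheme:
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            _dtype, rest = line.split(",", 1)
            name, rng = rest.split("=")
            lo, hi = rng.strip().split("-")
            entries.append(PartitionEntry(name.strip(), int(lo), int(hi)))
        except ValueError as exc:
            raise AlignmentFormatError(f"cannot parse partition line: {line!r}") from exc
    return PartitionScheme(tuple(entries))


def write_partition_file(scheme: PartitionScheme, path) -> None:
    lines = [f"DNA, {e.locus_id} = {e.start}-{e.end}" for e in scheme]
    Path(path).write_text("\n".join(lines) + "\n")


# -- concatenation ----------------------------------------------------------

def concatenate(loci: Sequence[tuple[str, Alignment]]) -> tuple[Alignment, PartitionScheme]:
    """Concatenate per-locus alignments into a supermatrix.

    The taxon set of the supermatrix is the union over loci; a taxon absent
    from a locus receives ``?`` across that locus's columns. Taxa are ordered
    lexicographically for determinism; partition entries keep input order.
    """
    if not loci:
        raise ValueError("empty locus list")
    ids = [locus_id for locus_id, _ in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus ids")
    all_taxa = sorted({t for _, aln in loci for t in aln.taxa})
    blocks = []
    entries = []
    pos = 1
    for locus_id, aln in loci:
        block = np.full((len(all_taxa), aln.n_columns), "?", dtype="<U1")
        for i, taxon in enumerate(all_taxa):
            if taxon in aln.taxa:
                block[i] = aln.matrix[aln.taxa.index(taxon)]
        blocks.append(block)
        entries.append(PartitionEntry(locus_id, pos, pos + aln.n_columns - 1))
        pos += aln.n_columns
    supermatrix = Alignment(all_taxa, np.hstack(blocks))
    return supermatrix, PartitionScheme(tuple(entries))


# -- occupancy --------------------------------------------------------------

@dataclass
class OccupancyReport:
    """Per-locus and per-column data availability.

    ``per_locus[locus]`` is the fraction of taxa with at least one
    non-missing character in that locus; ``per_column[i]`` the fraction of
    non-missing cells in 0-based column ``i``.
    """

    per_locus: dict[str, float]
    per_column: np.ndarray
    n_taxa_present: dict[str, int] = field(default_factory=dict)

    def to_rows(self) -> list[tuple[str, int, float]]:
        return [
            (locus, self.n_taxa_present[locus], occ)
            for locus, occ in self.per_locus.items()
        ]


def occupancy_report(alignment: Alignment, scheme: PartitionScheme) -> OccupancyReport:
    if scheme.n_columns != alignment.n_columns:
        raise ValueError("partition scheme does not match alignment width")
    missing = alignment.missing_mask()
    per_locus: dict[str, float] = {}
    present_counts: dict[str, int] = {}
    for e in scheme:
        block_missing = missing[:, e.column_indices()]
        present = (~block_missing).any(axis=1)
        present_counts[e.locus_id] = int(present.sum())
        per_locus[e.locus_id] = present.sum() / alignment.n_taxa
    per_column = 1.0 - missing.mean(axis=0)
    return OccupancyReport(per_locus, per_column, present_counts)


def write_occupancy_tsv(report: OccupancyReport, path) -> None:
    lines = ["locus_id\tn_taxa_present\toccupancy"]
    lines += [f"{lo}\t{n}\t{occ:.6g}" for lo, n, occ in report.to_rows()]
    Path(path).write_text("\n".join(lines) + "\n")


# -- trimming ---------------------------------------------------------------

class EmptyAlignmentError(ValueError):
    """Raised when trimming removes every column."""


def trim_columns(
    alignment: Alignment,
    scheme: PartitionScheme | None = None,
    max_missing_fraction: float = 0.5,
    per_locus: bool = False,
) -> tuple[Alignment, np.ndarray, PartitionScheme | None]:
    """Drop columns whose missing fraction strictly exceeds the threshold.

    A column exactly at the threshold survives ("over 50%" read strictly).
    Returns the trimmed alignment, the kept 0-based column indices, and the
    remapped partition scheme (``None`` if none was given). Loci losing all
    their columns are dropped with a warning.

    ``per_locus`` switches to evaluating the criterion independently within
    each locus; with a global missing-fraction criterion the two modes
    coincide, so the flag exists for symmetry with per-locus workflows and is
    meaningful only if a scheme is given.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    if per_locus and scheme is None:
        raise ValueError("per_locus trimming requires a partition scheme")
    missing_frac = alignment.missing_mask().mean(axis=0)
    keep = missing_frac <= max_missing_fraction
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size == 0:
        raise EmptyAlignmentError("trimming removed every column")
    trimmed = alignment.subset_columns(kept_idx)
    new_scheme = None
    if scheme is not None:
        entries = []
        pos = 1
        for e in scheme:
            n_kept = int(keep[e.column_indices()].sum())
            if n_kept == 0:
                logger.warning("locus %s lost all columns during trimming", e.locus_id)
                continue
            entries.append(PartitionEntry(e.locus_id, pos, pos + n_kept - 1))
            pos += n_kept
        new_scheme = PartitionScheme(tuple(entries))
    return trimmed, kept_idx, new_scheme
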