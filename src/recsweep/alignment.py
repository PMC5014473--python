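"""Alignment container, file I/O and column bookkeeping.

Every other module works on :class:`Alignment` objects: ordered, named,
gapped nucleotide sequences of identical padded length.  Residues are
canonicalized on construction (uppercase, ``U``→``T``, IUPAC ambiguity
codes collapsed to ``N``), so downstream code only ever sees the six
symbols ``A C G T - N``.

Coordinates are 0-based half-open internally everywhere; conversion to
1-based inclusive happens only in report writers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "AlignmentError",
    "ColumnMap",
    "read_alignment",
    "write_alignment",
    "strip_shared_gaps",
    "pairwise_identity",
]

# residue codes used by all numeric kernels
A, C, G, T, GAP, N = 0, 1, 2, 3, 4, 5
_CODE_OF = np.full(256, N, dtype=np.uint8)
for _ch, _code in (("A", A), ("C", C), ("G", G), ("T", T), ("-", GAP)):
    _CODE_OF[ord(_ch)] = _code
_CHAR_OF = np.frombuffer(b"ACGT-N", dtype=np.uint8)

_CANON = {c: c for c in "ACGT-"}
_CANON["U"] = "T"


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, duplicate names, empty)."""


def _canonicalize(seq: str) -> str:
    up = seq.upper()
    return "".join(_CANON.get(ch, "N") for ch in up)


@dataclass
class Alignment:
    """An immutable-by-convention multiple nucleotide alignment.

    Parameters
    ----------
    names
        Unique sequence identifiers (whitespace-normalized).
    rows
        Equal-length nucleotide strings; canonicalized on construction.
    descriptions
        Optional free-text descriptions carried through round trips.
    """

    names: list[str]
    rows: list[str]
    descriptions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentError("names and rows differ in count")
        if not self.rows:
            raise AlignmentError("alignment is empty: at least one sequence required")
        self.names = [" ".join(str(n).split()) for n in self.names]
        seen: dict[str, int] = {}
        dups = []
        for nm in self.names:
            seen[nm] = seen.get(nm, 0) + 1
            if seen[nm] == 2:
                dups.append(nm)
        if dups:
            raise AlignmentError(f"duplicate sequence names: {', '.join(dups)}")
        self.rows = [_canonicalize(r) for r in self.rows]
        L = len(self.rows[0])
        for nm, r in zip(self.names, self.rows):
            if len(r) != L:
                raise AlignmentError(
                    f"ragged alignment: sequence {nm!r} has length {len(r)}, expected {L}"
                )
        if L < 1:
            raise AlignmentError("alignment has zero columns")
        if not self.descriptions:
            self.descriptions = [""] * len(self.names)
        self._codes: np.ndarray | None = None

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def codes(self) -> np.ndarray:
        """(n_sequences, length) uint8 matrix, A=0 C=1 G=2 T=3 -=4 N=5."""
        if self._codes is None:
            buf = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
            self._codes = _CODE_OF[buf].reshape(self.n_sequences, self.length)
        return self._codes

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no sequence named {name!r}") from None

    def take_rows(self, indices: list[int]) -> "Alignment":
        return Alignment(
            [self.names[i] for i in indices],
            [self.rows[i] for i in indices],
            [self.descriptions[i] for i in indices],
        )

    @classmethod
    def from_codes(cls, names: list[str], codes: np.ndarray) -> "Alignment":
        rows = [bytes(_CHAR_OF[row]).decode() for row in np.asarray(codes, dtype=np.uint8)]
        return cls(list(names), rows)


@dataclass
class ColumnMap:
    """Maps positions of a column-stripped view back to original columns."""

    kept_columns: np.ndarray  # sorted original indices, one per view column

    def __post_init__(self) -> None:
        self.kept_columns = np.asarray(self.kept_columns, dtype=np.int64)
        if self.kept_columns.size > 1 and not np.all(np.diff(self.kept_columns) > 0):
            raise ValueError("kept_columns must be strictly increasing")

    def __len__(self) -> int:
        return int(self.kept_columns.size)

    def to_original(self, view_pos: int) -> int:
        return int(self.kept_columns[view_pos])

    def interval_to_original(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open view interval to a half-open original interval."""
        if not 0 <= start < end <= len(self):
            raise ValueError(f"invalid view interval [{start}, {end})")
        return int(self.kept_columns[start]), int(self.kept_columns[end - 1]) + 1

    def from_original(self, column: int) -> int:
        """View position of the first kept column >= ``column``."""
        return int(np.searchsorted(self.kept_columns, column, side="left"))


# ---------------------------------------------------------------------------
# file I/O


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                head = line.strip()
                break
        else:
            raise AlignmentError(f"{path}: empty file")
    if head.startswith(">"):
        return "fasta"
    if head.upper().startswith("#NEXUS"):
        return "nexus"
    toks = head.split()
    if len(toks) == 2 and all(t.isdigit() for t in toks):
        return "phylip"
    raise AlignmentError(f"{path}: cannot auto-detect alignment format from {head[:40]!r}")


_BIO_FORMAT = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


def read_alignment(path: str | Path, format: str = "auto") -> Alignment:
    """Read a FASTA / relaxed PHYLIP / NEXUS alignment from *path*.

    ``format="auto"`` sniffs the leading characters (``>``, a numeric
    ``ntax nchar`` header, or ``#NEXUS``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in _BIO_FORMAT:
        raise AlignmentError(f"unknown alignment format {fmt!r}")
    if fmt == "fasta":
        # parse record-wise so a ragged record can be named in the error
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"{path}: no sequences found")
        L = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != L:
                raise AlignmentError(
                    f"{path}: ragged alignment at record {rec.id!r} "
                    f"(length {len(rec.seq)}, expected {L})"
                )
    else:
        try:
            records = list(AlignIO.read(str(path), _BIO_FORMAT[fmt]))
        except ValueError as exc:
            raise AlignmentError(f"{path}: {exc}") from exc
        if not records:
            raise AlignmentError(f"{path}: no sequences found")
    names = [rec.id for rec in records]
    descriptions = []
    for rec in records:
        d = rec.description or ""
        if d.startswith(rec.id):
            d = d[len(rec.id):].strip()
        descriptions.append(d)
    return Alignment(names, [str(rec.seq) for rec in records], descriptions)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write *aln* so that :func:`read_alignment` recovers names and rows."""
    if format not in _BIO_FORMAT:
        raise AlignmentError(f"unknown alignment format {format!r}")
    records = [
        SeqRecord(
            Seq(row),
            id=name,
            description=desc or "",
            annotations={"molecule_type": "DNA"},
        )
        for name, row, desc in zip(aln.names, aln.rows, aln.descriptions)
    ]
    msa = MultipleSeqAlignment(records)
    buf = io.StringIO()
    AlignIO.write(msa, buf, _BIO_FORMAT[format])
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# column bookkeeping primitives


def strip_shared_gaps(aln: Alignment, row_subset: list[int]) -> tuple[Alignment, ColumnMap]:
    """Restrict *aln* to *row_subset* and drop every column in which any
    selected row carries ``-`` or ``N``.

    Returns the stripped view (rows in subset order) and the
    :class:`ColumnMap` from view positions to original columns.  The view
    may have zero columns; it is then returned as a 1-column placeholder
    only if empty alignments were disallowed — instead we return the map
    and a view built directly from codes, bypassing validation.
    """
    if not row_subset:
        raise ValueError("row_subset must be non-empty")
    sub = aln.codes[np.asarray(row_subset, dtype=np.intp)]
    keep = ~np.any(sub >= GAP, axis=0)
    kept = np.flatnonzero(keep)
    cmap = ColumnMap(kept)
    codes = np.ascontiguousarray(sub[:, kept])
    # rows are already canonical: bypass re-validation for the hot path
    view = Alignment.__new__(Alignment)
    view.names = [aln.names[i] for i in row_subset]
    view.rows = [bytes(_CHAR_OF[row]).decode() for row in codes]
    view.descriptions = ["" for _ in row_subset]
    view._codes = codes
    return view, cmap


def pairwise_identity(
    aln: Alignment, i: int, j: int, window: tuple[int, int] | None = None
) -> float | None:
    """Fraction of matching residues between rows *i* and *j* over the
    half-open column *window*, ignoring columns where either row is gap/N.

    Returns ``None`` when no comparable column exists.
    """
    if window is None:
        window = (0, aln.length)
    s, e = window
    if not 0 <= s < e <= aln.length:
        raise ValueError(f"invalid window [{s}, {e}) for alignment of length {aln.length}")
    x = aln.codes[i, s:e]
    y = aln.codes[j, s:e]
    comp = (x < GAP) & (y < GAP)
    n = int(comp.sum())
    if n == 0:
        return None
    return float(np.count_nonzero((x == y) & comp) / n)
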