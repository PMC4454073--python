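"""Sequence and alignment I/O, pairwise global alignment, redundancy filtering.

Protein sequences are restricted to the 20 standard amino-acid letters plus
``X`` for ambiguous residues.  All residue coordinates exposed by this module
are 1-based and inclusive, matching the convention of the structural
literature (e.g. "residues 96-107").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"


class MalformedInputError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class SequenceRecord:
    """One protein sequence with identifier and optional family label."""

    id: str
    residues: str
    description: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise MalformedInputError(f"record {self.id!r} has an empty sequence")
        self.residues = self.residues.upper()
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise MalformedInputError(
                f"record {self.id!r} contains letters outside the alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A gapped multiple sequence alignment with equal-length rows."""

    ids: list[str]
    rows: list[str]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            ragged = [i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])]
            raise MalformedInputError(f"ragged alignment rows: {ragged}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> SequenceRecord:
        """Ungapped SequenceRecord for row *i*."""
        return SequenceRecord(id=self.ids[i], residues=self.rows[i].replace(GAP, ""))

    def reference_row(self) -> int:
        """Index of the coordinate-reference row (first row when unset)."""
        if self.reference_id is None:
            return 0
        return self.ids.index(self.reference_id)


def _clean_residues(seq_id: str, raw: str) -> str:
    """Uppercase and map out-of-alphabet characters to X (with a warning)."""
    s = raw.upper()
    if not set(s) <= set(ALPHABET):
        bad = sorted(set(s) - set(ALPHABET))
        logger.warning("sequence %s: replacing %s with X", seq_id, bad)
        s = "".join(c if c in ALPHABET else "X" for c in s)
    return s


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Lowercase input is uppercased; characters outside the 21-letter alphabet
    are replaced by ``X`` with a logged warning.  Duplicate identifiers or
    empty entries raise :class:`MalformedInputError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise MalformedInputError(f"FASTA entry {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise MalformedInputError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(
                id=entry.id,
                residues=_clean_residues(entry.id, seq),
                description=entry.description,
            )
        )
    if not records:
        raise MalformedInputError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) TSV table; a header line is optional."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MalformedInputError(f"{path}:{ln}: expected two tab-separated columns")
            if ln == 1 and parts[0].lower() == "id":
                continue
            labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for k, v in labels.items():
            fh.write(f"{k}\t{v}\n")


def read_alignment(path: str | Path, fmt: str = "aligned-fasta") -> Alignment:
    """Read a multiple sequence alignment (aligned FASTA or Stockholm).

    ``.`` gap characters are normalised to ``-``; Stockholm annotation lines
    (``#=GC`` etc.) are ignored by the underlying parser.
    """
    bio_fmt = {"aligned-fasta": "fasta", "fasta": "fasta", "stockholm": "stockholm"}.get(fmt)
    if bio_fmt is None:
        raise ValueError(f"unknown alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), bio_fmt)
    except ValueError as exc:  # Biopython reports ragged rows as ValueError
        raise MalformedInputError(f"malformed alignment in {path}: {exc}") from exc
    ids = [r.id for r in msa]
    rows = [str(r.seq).upper().replace(".", GAP) for r in msa]
    for i, row in enumerate(rows):
        _ = SequenceRecord(id=ids[i], residues=row.replace(GAP, "") or "X")
    return Alignment(ids=ids, rows=rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


# --- pairwise global alignment -------------------------------------------

def default_substitution_matrix():
    """BLOSUM62 restricted to the package alphabet, with X scoring 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            if a == "X" or b == "X":
                mat[a, b] = 0.0
            else:
                mat[a, b] = blosum[a, b]
    return mat


_DEFAULT_MATRIX = None


def _matrix():
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = default_substitution_matrix()
    return _DEFAULT_MATRIX


def _aligner(matrix=None, gap_open: float = -10.0, gap_extend: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix if matrix is not None else _matrix()
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass
class PairwiseResult:
    """Optimal global alignment of a query against a reference."""

    alignment: Alignment  # two rows: query first, reference second
    score: float
    # 1-based reference position -> 1-based query position, or None at a gap
    reference_map: dict[int, int | None] = field(default_factory=dict)


def pairwise_global_align(
    query: SequenceRecord,
    reference: SequenceRecord,
    matrix=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> PairwiseResult:
    """Optimal Needleman-Wunsch alignment under affine gap costs.

    Returns the two-row alignment, its score, and a map from every 1-based
    reference position to the query position aligned to it (None when the
    reference residue faces a gap).  Ties between co-optimal alignments are
    broken deterministically by the aligner's canonical traceback order.
    """
    aligner = _aligner(matrix, gap_open, gap_extend)
    best = aligner.align(query.residues, reference.residues)[0]
    qrow, rrow = str(best[0]), str(best[1])
    mapping: dict[int, int | None] = {}
    qpos = rpos = 0
    for qc, rc in zip(qrow, rrow):
        if qc != GAP:
            qpos += 1
        if rc != GAP:
            rpos += 1
            mapping[rpos] = qpos if qc != GAP else None
    aln = Alignment(ids=[query.id, reference.id], rows=[qrow, rrow], reference_id=reference.id)
    return PairwiseResult(alignment=aln, score=float(best.score), reference_map=mapping)


def percent_identity(a: SequenceRecord, b: SequenceRecord, **kw) -> float:
    """Global-alignment identity: matches / alignment length (gaps count)."""
    res = pairwise_global_align(a, b, **kw)
    qrow, rrow = res.alignment.rows
    matches = sum(1 for x, y in zip(qrow, rrow) if x == y and x != GAP)
    return 100.0 * matches / len(qrow)


def redundancy_filter(records: Sequence[SequenceRecord], threshold: float = 60.0, **kw) -> list[SequenceRecord]:
    """Greedy longest-first redundancy reduction.

    A record is kept iff its global-alignment percent identity to every
    already-kept record is <= *threshold*.  This is a deterministic
    approximation of similarity-based clustering tools such as BLASTClust.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    kept: list[SequenceRecord] = []
    for rec in sorted(records, key=lambda r: (-len(r.residues), r.id)):
        if all(percent_identity(rec, other, **kw) <= threshold for other in kept):
            kept.append(rec)
    return kept


# --- star multiple alignment ---------------------------------------------

def star_align(records: Sequence[SequenceRecord], center: SequenceRecord | None = None) -> Alignment:
    """Progressive star alignment around a center sequence.

    Every member is aligned pairwise to the center (longest member by
    default) and the pairwise alignments are merged column-wise, padding
    insertions relative to the center with gaps.  Used to (re)derive seed
    alignments when no curated MSA is available, e.g. per cross-validation
    fold.
    """
    if not records:
        raise ValueError("star_align needs at least one record")
    if center is None:
        center = max(records, key=lambda r: (len(r.residues), r.id))
    others = [r for r in records if r.id != center.id]
    lc = len(center.residues)
    # per-sequence decomposition: emitted[j] = char aligned to center pos j+1
    # (or '-'), inserts[j] = residues inserted after center pos j (0 = before
    # the first center position)
    emitted: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    max_ins = [0] * (lc + 1)
    for rec in others:
        res = pairwise_global_align(rec, center)
        qrow, rrow = res.alignment.rows
        emit = [GAP] * lc
        ins = [""] * (lc + 1)
        rpos = 0
        for qc, rc in zip(qrow, rrow):
            if rc != GAP:
                rpos += 1
                emit[rpos - 1] = qc
            elif qc != GAP:
                ins[rpos] += qc
        emitted[rec.id] = emit
        inserts[rec.id] = ins
        for j in range(lc + 1):
            max_ins[j] = max(max_ins[j], len(ins[j]))

    def build_row(emit: list[str], ins: list[str]) -> str:
        parts = [ins[0].ljust(max_ins[0], GAP)]
        for j in range(lc):
            parts.append(emit[j])
            parts.append(ins[j + 1].ljust(max_ins[j + 1], GAP))
        return "".join(parts)

    ids = [center.id] + [r.id for r in others]
    rows = [build_row(list(center.residues), [""] * (lc + 1))]
    rows += [build_row(emitted[r.id], inserts[r.id]) for r in others]
    return Alignment(ids=ids, rows=rows, reference_id=center.id)
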