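"""Fic-motif extraction, consensus building, and isofunctional class assignment.

The catalytic Fic motif is a short window anchored at an invariant
histidine (glutamine in one divergent clade).  Subtle variants of the
window define isofunctional subfamilies; five consensus classes are
shipped, written in a PROSITE-like grammar:

* a plain letter is a fixed residue,
* ``x`` is a wildcard,
* ``[D|E]`` is an allowed set,
* ``[!R]`` is a forbidden set (any residue except those listed).

All shipped class patterns are anchored at the catalytic H/Q and are
pairwise mutually exclusive.  The canonical detection pattern
``HxFx[D|E]GN[G|K]R`` is also shipped for raw-sequence prescreening; it is
deliberately broader than the five classes and not used for class calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .phmm import ProfileHMM, viterbi_align
from .seqio import AMINO_ACIDS, SequenceRecord

WINDOW_LENGTH = 12


class TruncatedWindowError(ValueError):
    """The motif window would run past the end of the sequence."""


@dataclass(frozen=True)
class Position:
    """One motif position: fixed residue, allowed set, forbidden set or wildcard."""

    kind: str  # "fixed" | "allowed" | "forbidden" | "wildcard"
    residues: frozenset[str] = frozenset()

    def matches(self, c: str) -> bool:
        if self.kind == "wildcard":
            return True
        if self.kind == "fixed" or self.kind == "allowed":
            return c in self.residues
        return c not in self.residues  # forbidden


@dataclass(frozen=True)
class MotifClass:
    """A named positional pattern for one isofunctional motif group."""

    name: str
    pattern: tuple[Position, ...]
    clade_note: str = ""

    @classmethod
    def parse(cls, name: str, spec: str, clade_note: str = "") -> "MotifClass":
        """Parse a PROSITE-like pattern string, e.g. ``Hxxx[D|E]GNGRxxR``."""
        positions: list[Position] = []
        i = 0
        while i < len(spec):
            c = spec[i]
            if c == "[":
                j = spec.index("]", i)
                body = spec[i + 1 : j].replace("/", "|")
                if body.startswith("!"):
                    residues = frozenset(body[1:].split("|")) - {""}
                    positions.append(Position("forbidden", residues))
                else:
                    residues = frozenset(body.split("|")) - {""}
                    positions.append(Position("allowed", residues))
                i = j + 1
            elif c == "x":
                positions.append(Position("wildcard"))
                i += 1
            else:
                positions.append(Position("fixed", frozenset(c)))
                i += 1
        if len(positions) > WINDOW_LENGTH:
            raise ValueError(f"pattern {name!r} longer than {WINDOW_LENGTH} positions")
        return cls(name=name, pattern=tuple(positions), clade_note=clade_note)

    def matches(self, window: str) -> bool:
        """Anchored match at window position 1; trailing positions of a
        shorter pattern are unconstrained."""
        if len(window) < len(self.pattern):
            return False
        return all(p.matches(c) for p, c in zip(self.pattern, window))

    def to_string(self) -> str:
        parts = []
        for p in self.pattern:
            if p.kind == "wildcard":
                parts.append("x")
            elif p.kind == "fixed":
                parts.append(next(iter(p.residues)))
            elif p.kind == "allowed":
                parts.append("[" + "|".join(sorted(p.residues)) + "]")
            else:
                parts.append("[!" + "|".join(sorted(p.residues)) + "]")
        return "".join(parts)


def shipped_classes() -> list[MotifClass]:
    """The five isofunctional consensus motif classes.

    Named for the discriminating core of each pattern; the clade note says
    which part of the Fic/Doc phylogeny each group dominates.
    """
    return [
        MotifClass.parse(
            "doc-GNKR", "Hxxx[D|E]GNKRxx[!R]",
            "canonical Doc-like (phosphorylating) group",
        ),
        MotifClass.parse(
            "doc-N-GNKR", "HxxxN[A|G]NKRxx[!R]",
            "Doc-clade variant with the metal-binding Asp/Glu replaced by Asn",
        ),
        MotifClass.parse(
            "fic-GNGR", "Hxxx[D|E]GNGRxxR",
            "main Fic (AMPylating) group",
        ),
        MotifClass.parse(
            "fic-GNTR", "Hxxx[D|E]GNTRxx[!R]",
            "Fic variant with Thr in place of the second Gly and no final Arg",
        ),
        MotifClass.parse(
            "doc-Q-GNKR", "Qx[F|Y]x[D|E][G|V]NKR",
            "divergent Doc clade with the catalytic His replaced by Gln",
        ),
    ]


def canonical_fido_pattern() -> MotifClass:
    """The broad canonical Fido detection motif (prescreening only)."""
    return MotifClass.parse("fido-canonical", "HxFx[D|E]GN[G|K]R", "superfamily-wide detection pattern")


@dataclass
class MotifAssignment:
    seq_id: str
    window: str
    start: int  # 1-based position of the window on the query
    class_name: str  # class name or "unassigned"
    conflict: bool = False  # True when multiple classes matched


def extract_motif_window(
    seq: SequenceRecord,
    fic_profile: ProfileHMM,
    anchor_match_state: int,
    length: int = WINDOW_LENGTH,
) -> tuple[str, int] | None:
    """Read the motif window off the profile alignment of a query.

    The query is aligned to the family profile with Viterbi; the window is
    the *length* consecutive query residues starting at the residue aligned
    to the anchor match state (the catalytic His/Gln column).  Returns
    ``None`` when the anchor column is deleted in the query; raises
    :class:`TruncatedWindowError` when the window would run past the end.
    """
    va = viterbi_align(fic_profile, seq)
    start = va.correspondence.get(anchor_match_state)
    if start is None:
        return None
    if start + length - 1 > len(seq.residues):
        raise TruncatedWindowError(
            f"window at {start} exceeds sequence {seq.id!r} of length {len(seq.residues)}"
        )
    return seq.residues[start - 1 : start + length - 1], start


def assign_motif_class(
    window: str,
    classes: Sequence[MotifClass] | None = None,
    seq_id: str = "",
    start: int = 1,
) -> MotifAssignment:
    """Assign a window to exactly one motif class, else "unassigned".

    A window matched by more than one class (impossible for the shipped
    classes, which are mutually exclusive) is reported unassigned with the
    conflict flag set.
    """
    classes = list(classes) if classes is not None else shipped_classes()
    longest = max(len(c.pattern) for c in classes)
    if len(window) < longest:
        raise ValueError(f"window shorter than the longest pattern ({longest})")
    matched = [c for c in classes if c.matches(window)]
    if len(matched) == 1:
        return MotifAssignment(seq_id, window, start, matched[0].name)
    return MotifAssignment(seq_id, window, start, "unassigned", conflict=len(matched) > 1)


def match_many(pattern: MotifClass, windows: np.ndarray) -> np.ndarray:
    """Vectorised anchored matching of one pattern against many windows.

    *windows* is a (n, width) array of single-character strings (or bytes).
    """
    if windows.ndim != 2 or windows.shape[1] < len(pattern.pattern):
        raise ValueError("windows array narrower than the pattern")
    ok = np.ones(windows.shape[0], dtype=bool)
    for j, pos in enumerate(pattern.pattern):
        col = windows[:, j]
        if pos.kind == "wildcard":
            continue
        hit = np.zeros_like(ok)
        for r in pos.residues:
            hit |= col == r
        ok &= ~hit if pos.kind == "forbidden" else hit
    return ok


def consensus_motif(
    windows: Sequence[str],
    fix_threshold: float = 0.8,
    pair_threshold: float = 0.7,
    free_positions: tuple[int, ...] = (10, 11),
    forbidden_discriminators: dict[int, str] = {12: "R"},
) -> tuple[str, np.ndarray]:
    """Consensus pattern and per-position frequency matrix of a window stack.

    Per position (1-based): a residue at frequency >= *fix_threshold*
    becomes fixed; else the top two residues jointly >= *pair_threshold*
    become an allowed set; else a curated discriminating residue that never
    occurs (R at position 12 by default) becomes a forbidden set; otherwise
    the position is a wildcard.  Positions listed in *free_positions*
    (10-11 by default, the two positions the published logos leave out) are
    forced to wildcard.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("ragged windows")
    freq = np.zeros((width, 20))
    for w in windows:
        for j, c in enumerate(w):
            if c in AMINO_ACIDS:
                freq[j, AMINO_ACIDS.index(c)] += 1
    freq /= len(windows)
    parts = []
    for j in range(width):
        pos1 = j + 1
        if pos1 in free_positions:
            parts.append("x")
            continue
        order = np.argsort(-freq[j])
        top, second = order[0], order[1]
        if freq[j, top] >= fix_threshold:
            parts.append(AMINO_ACIDS[top])
        elif freq[j, top] + freq[j, second] >= pair_threshold:
            pair = sorted([AMINO_ACIDS[top], AMINO_ACIDS[second]])
            parts.append("[" + "|".join(pair) + "]")
        elif pos1 in forbidden_discriminators and freq[
            j, AMINO_ACIDS.index(forbidden_discriminators[pos1])
        ] == 0:
            parts.append("[!" + forbidden_discriminators[pos1] + "]")
        else:
            parts.append("x")
    return "".join(parts), freq
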