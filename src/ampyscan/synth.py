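"""Synthetic protein families: divergent sequences sharing a conserved motif.

Real AMPylation-domain families are highly divergent outside a short
catalytic motif.  The generator emulates that structure: each family is
derived from a random template carrying a class motif window; members
accumulate i.i.d. substitutions at non-conserved positions and
geometric-length indels, while the pattern-constrained motif positions are
preserved exactly (wildcard positions inside the window mutate like any
other).  Indels are never placed inside the motif window, so the
ground-truth class of every member stays well defined.  The true alignment
of every family is recorded during generation and doubles as its seed MSA.

Everything regenerates bit-identically from the recorded provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .motifs import MotifClass, assign_motif_class, shipped_classes
from .phmm import ProfileHMM
from .seqio import AMINO_ACIDS, GAP, Alignment, SequenceRecord

_AA = np.array(list(AMINO_ACIDS))


@dataclass
class FamilySpec:
    """Generation parameters of one synthetic family."""

    name: str
    template: str
    motif_anchor: int  # 1-based start of the motif window in the template
    motif_length: int = 12
    substitution_rate: float = 0.2
    indel_rate: float = 0.02  # per-position probability of starting an indel
    indel_length_p: float = 0.5  # geometric length parameter (mean 1/p)
    n: int = 60
    seed: int = 0
    motif_class: str | None = None  # shipped class name; None = auto-detect

    def window(self) -> str:
        return self.template[self.motif_anchor - 1 : self.motif_anchor - 1 + self.motif_length]


@dataclass
class SyntheticDataset:
    """Labeled records plus per-family true alignments and provenance."""

    records: list[SequenceRecord]
    labels: dict[str, str]
    alignments: dict[str, Alignment]
    provenance: dict

    def family_members(self, name: str) -> list[SequenceRecord]:
        return [r for r in self.records if self.labels[r.id] == name]


def _constrained_positions(spec: FamilySpec) -> set[int]:
    """1-based template positions whose motif-pattern slot is constrained."""
    window = spec.window()
    classes = shipped_classes()
    if spec.motif_class is not None:
        cls = next(c for c in classes if c.name == spec.motif_class)
        if not cls.matches(window):
            raise ValueError(
                f"template window {window!r} does not match class {spec.motif_class!r}"
            )
    else:
        assignment = assign_motif_class(window, classes)
        if assignment.class_name == "unassigned":
            raise ValueError(f"template window {window!r} matches no shipped motif class")
        cls = next(c for c in classes if c.name == assignment.class_name)
    return {
        spec.motif_anchor + j
        for j, pos in enumerate(cls.pattern)
        if pos.kind != "wildcard"
    }


def mutate_family(spec: FamilySpec) -> tuple[list[SequenceRecord], Alignment]:
    """Generate one family and its true alignment.

    The alignment's first row is the unmutated template (id
    ``<name>__template``), which serves as the coordinate reference for the
    family profile; generated members follow.
    """
    lt = len(spec.template)
    if lt < spec.motif_length + 20:
        raise ValueError("template must exceed motif length by at least 20 residues")
    if not 0 <= spec.substitution_rate < 1 or not 0 <= spec.indel_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    conserved = _constrained_positions(spec)
    in_window = set(range(spec.motif_anchor, spec.motif_anchor + spec.motif_length))
    rng = np.random.default_rng(spec.seed)

    emitted_rows: list[list[str]] = []
    insert_rows: list[list[str]] = []
    max_ins = [0] * (lt + 1)
    for _ in range(spec.n):
        emit = [""] * lt
        ins = [""] * (lt + 1)
        del_remaining = 0
        for pos in range(1, lt + 1):
            j = pos - 1
            c = spec.template[j]
            if pos in in_window:
                del_remaining = 0
                if pos in conserved or rng.random() >= spec.substitution_rate:
                    emit[j] = c
                else:
                    emit[j] = _substitute(c, rng)
            else:
                if del_remaining > 0:
                    emit[j] = GAP
                    del_remaining -= 1
                elif rng.random() < spec.indel_rate / 2:
                    length = rng.geometric(spec.indel_length_p)
                    emit[j] = GAP
                    del_remaining = length - 1
                elif rng.random() < spec.substitution_rate:
                    emit[j] = _substitute(c, rng)
                else:
                    emit[j] = c
            # insertions are allowed after any position outside the window
            # interior (i.e. never between two window residues)
            inside = spec.motif_anchor <= pos < spec.motif_anchor + spec.motif_length
            if not inside and rng.random() < spec.indel_rate / 2:
                length = int(rng.geometric(spec.indel_length_p))
                ins[pos] = "".join(rng.choice(_AA, size=length))
        emitted_rows.append(emit)
        insert_rows.append(ins)
        for p in range(lt + 1):
            max_ins[p] = max(max_ins[p], len(ins[p]))

    def build_row(emit: list[str], ins: list[str]) -> str:
        parts = [ins[0].ljust(max_ins[0], GAP)]
        for j in range(lt):
            parts.append(emit[j])
            parts.append(ins[j + 1].ljust(max_ins[j + 1], GAP))
        return "".join(parts)

    template_id = f"{spec.name}__template"
    ids = [template_id]
    rows = [build_row(list(spec.template), [""] * (lt + 1))]
    records: list[SequenceRecord] = []
    for i in range(spec.n):
        sid = f"{spec.name}_{i:03d}"
        row = build_row(emitted_rows[i], insert_rows[i])
        ids.append(sid)
        rows.append(row)
        records.append(
            SequenceRecord(id=sid, residues=row.replace(GAP, ""), label=spec.name)
        )
    return records, Alignment(ids=ids, rows=rows, reference_id=template_id)


def _substitute(c: str, rng: np.random.Generator) -> str:
    """Uniform draw over the 19 letters other than *c*."""
    i = AMINO_ACIDS.index(c)
    j = int(rng.integers(0, 19))
    return AMINO_ACIDS[j if j < i else j + 1]


def sample_from_profile(profile: ProfileHMM, n: int, seed: int = 0) -> list[SequenceRecord]:
    """Sample sequences by stochastic traversal of a profile HMM."""
    rng = np.random.default_rng(seed)
    L = profile.L
    records = []
    for i in range(n):
        out: list[str] = []
        # N flank
        while rng.random() < profile.flank_loop:
            out.append(str(rng.choice(_AA, p=profile.background)))
        state, k = "M", 0  # B
        while True:
            if state == "M":
                probs = [profile.t_mm[k], profile.t_mi[k], profile.t_md[k]]
            elif state == "I":
                probs = [profile.t_im[k], profile.t_ii[k], profile.t_id[k]]
            else:
                probs = [profile.t_dm[k], profile.t_di[k], profile.t_dd[k]]
            choice = rng.choice(3, p=np.array(probs) / sum(probs))
            if choice == 0:
                if k == L:
                    break  # to E
                state, k = "M", k + 1
                out.append(str(rng.choice(_AA, p=profile.match_emit[k])))
            elif choice == 1:
                state = "I"
                out.append(str(rng.choice(_AA, p=profile.insert_emit[k])))
            else:
                state, k = "D", k + 1
        # C flank
        while rng.random() < profile.flank_loop:
            out.append(str(rng.choice(_AA, p=profile.background)))
        records.append(SequenceRecord(id=f"{profile.name}_sample_{i:03d}", residues="".join(out) or "X"))
    return records


def make_benchmark(specs: Sequence[FamilySpec]) -> SyntheticDataset:
    """Union of generated families with per-family seed alignments."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate family names")
    if len(specs) < 2:
        raise ValueError("need at least 2 family specs")
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    alignments: dict[str, Alignment] = {}
    for spec in specs:
        fam_records, aln = mutate_family(spec)
        records.extend(fam_records)
        labels.update({r.id: spec.name for r in fam_records})
        alignments[spec.name] = aln
    return SyntheticDataset(
        records=records,
        labels=labels,
        alignments=alignments,
        provenance={"specs": [asdict(s) for s in specs]},
    )


def regenerate(provenance: dict) -> SyntheticDataset:
    """Rebuild a dataset bit-identically from its provenance."""
    return make_benchmark([FamilySpec(**s) for s in provenance["specs"]])


def _random_template(length: int, window: str, anchor: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    residues = list(rng.choice(_AA, size=length))
    residues[anchor - 1 : anchor - 1 + len(window)] = list(window)
    return "".join(residues)


DEFAULT_MOTIFS = {
    "fic-like": "HPFLEGNGRATR",
    "doc-like": "HPFAEGNKRAAQ",
    "qclass-like": "QAFYEGNKRAAA",
}


def default_benchmark_specs(
    seed: int = 0,
    n: int = 60,
    substitution_rate: float = 0.2,
    indel_rate: float = 0.02,
    template_length: int = 200,
    anchor: int = 90,
) -> list[FamilySpec]:
    """The shipped three-family benchmark configuration.

    Three families carry the motifs HPFLEGNGRATR (Fic-like), HPFAEGNKRAAQ
    (Doc-like) and QAFYEGNKRAAA (Q-class-like) on independent random
    templates of 200 residues, 60 members each, substitution rate 0.2 and
    indel rate 0.02.
    """
    specs = []
    for i, (name, motif) in enumerate(DEFAULT_MOTIFS.items()):
        template = _random_template(
            template_length, motif, anchor, seed=(seed * 7919 + i) % 2**31
        )
        specs.append(
            FamilySpec(
                name=name,
                template=template,
                motif_anchor=anchor,
                substitution_rate=substitution_rate,
                indel_rate=indel_rate,
                n=n,
                seed=(seed * 104729 + 1000 + i) % 2**31,
            )
        )
    return specs


def default_benchmark(seed: int = 0, **kw) -> SyntheticDataset:
    return make_benchmark(default_benchmark_specs(seed=seed, **kw))


def save_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write FASTA + TSV labels + per-family aligned FASTA + provenance."""
    from .seqio import write_alignment, write_fasta, write_labels

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.records, outdir / "sequences.fasta")
    write_labels(dataset.labels, outdir / "labels.tsv")
    for name, aln in dataset.alignments.items():
        write_alignment(aln, outdir / f"{name}.aln.fasta")
    (outdir / "provenance.json").write_text(json.dumps(dataset.provenance, indent=2))
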