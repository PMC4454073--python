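"""Rule-based detectors layered on profile hits.

Three screens reproduce the residue-level decision rules used to curate
AMPylation subfamilies:

* **AnkX phosphocholinators** — a permissive CMP-binding-domain profile
  search (E <= 1) crosschecked by conservation of the CDP-choline binding
  residues D28, R30, Y41, R44 (AnkX numbering): a hit is positive when at
  least 3 of the 4 residues are conserved AND a Fic domain co-occurs.
* **AR vs AT of GS-ATase** — the two domains are near-homologous; the
  competing-profile call (lower E-value) is crosschecked by the only two
  class-specific residues, Asn at the AR position 169 and Gly at the AT
  position 697.  Disagreement is a first-class ``conflict`` verdict.
* **DrrA substrate compatibility of Rab GTPases** — the query is mapped
  onto human Rab1b numbering by global alignment; it is compatible when
  the residue at position 77 is the AMPylatable tyrosine and the surface
  stretch 53-58 carries a net positive charge (K/R = +1, D/E = -1, all
  others including His = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .phmm import HmmHit, ProfileHMM
from .seqio import SequenceRecord, pairwise_global_align

logger = logging.getLogger(__name__)

ANKX_DIAGNOSTIC_RESIDUES: dict[int, str] = {28: "D", 30: "R", 41: "Y", 44: "R"}
ANKX_CMP_EVALUE_CUTOFF = 1.0
AR_DIAGNOSTIC_POSITION, AR_DIAGNOSTIC_RESIDUE = 169, "N"
AT_DIAGNOSTIC_POSITION, AT_DIAGNOSTIC_RESIDUE = 697, "G"
RAB_TYROSINE_POSITION = 77
RAB_STRETCH = (53, 58)

_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass
class RuleVerdict:
    seq_id: str
    rule: str
    verdict: str  # positive | negative | compatible | incompatible | AR | AT | conflict | none
    evidence: dict = field(default_factory=dict)


def _residue_at_reference_position(
    seq: SequenceRecord, hit: HmmHit, profile: ProfileHMM, ref_pos: int
) -> str | None:
    """Query residue aligned (via the hit's Viterbi correspondence) to a
    reference position of the profile, or None when unmappable."""
    try:
        k = profile.match_state_for_reference_position(ref_pos)
    except KeyError:
        return None
    qpos = hit.correspondence.get(k)
    if qpos is None:
        return None
    return seq.residues[qpos - 1]


def ankx_screen(
    seq: SequenceRecord,
    fic_hit: HmmHit | None,
    cmp_hit: HmmHit | None,
    cmp_profile: ProfileHMM | None = None,
    diagnostic_residues: Mapping[int, str] = ANKX_DIAGNOSTIC_RESIDUES,
) -> RuleVerdict:
    """3-of-4 conserved CMP-binding residues AND a co-occurring Fic domain.

    The conserved count is the number of diagnostic positions at which the
    query residue aligned to the CMP profile equals the AnkX residue; an
    unmappable position (deleted or outside the correspondence) counts as
    not conserved and is logged.
    """
    observed: dict[int, str | None] = {}
    if cmp_hit is not None and cmp_profile is not None:
        for pos in diagnostic_residues:
            observed[pos] = _residue_at_reference_position(seq, cmp_hit, cmp_profile, pos)
            if observed[pos] is None:
                logger.info("ankx_screen %s: position %d unmappable, counted not conserved", seq.id, pos)
    else:
        observed = {pos: None for pos in diagnostic_residues}
    conserved = sum(1 for pos, aa in diagnostic_residues.items() if observed.get(pos) == aa)
    positive = conserved >= 3 and fic_hit is not None
    return RuleVerdict(
        seq_id=seq.id,
        rule="ankx",
        verdict="positive" if positive else "negative",
        evidence={
            "conserved_count": conserved,
            "observed": {pos: observed.get(pos) for pos in diagnostic_residues},
            "expected": dict(diagnostic_residues),
            "fic_domain_present": fic_hit is not None,
            "cmp_evalue": cmp_hit.evalue if cmp_hit else None,
        },
    )


def arat_assign(
    seq: SequenceRecord,
    ar_hit: HmmHit | None,
    at_hit: HmmHit | None,
    ar_profile: ProfileHMM | None = None,
    at_profile: ProfileHMM | None = None,
) -> RuleVerdict:
    """Discriminate deAMPylating AR from AMPylating AT domains.

    Primary call: family of the lower E-value hit.  Crosscheck: Asn at the
    position equivalent to AR 169 supports AR; Gly at the position
    equivalent to AT 697 supports AT.  Agreement yields that family;
    disagreement yields ``conflict`` with both evidences; no passing hit
    yields ``none``.
    """
    evidence: dict = {
        "ar_evalue": ar_hit.evalue if ar_hit else None,
        "at_evalue": at_hit.evalue if at_hit else None,
    }
    if ar_hit is None and at_hit is None:
        return RuleVerdict(seq.id, "arat", "none", evidence)
    if at_hit is None or (ar_hit is not None and ar_hit.evalue <= at_hit.evalue):
        primary = "AR"
    else:
        primary = "AT"
    evidence["primary_call"] = primary

    res_ar = (
        _residue_at_reference_position(seq, ar_hit, ar_profile, AR_DIAGNOSTIC_POSITION)
        if ar_hit is not None and ar_profile is not None
        else None
    )
    res_at = (
        _residue_at_reference_position(seq, at_hit, at_profile, AT_DIAGNOSTIC_POSITION)
        if at_hit is not None and at_profile is not None
        else None
    )
    evidence["residue_at_ar169"] = res_ar
    evidence["residue_at_at697"] = res_at
    supports_ar = res_ar == AR_DIAGNOSTIC_RESIDUE
    supports_at = res_at == AT_DIAGNOSTIC_RESIDUE

    if primary == "AR" and supports_ar and not supports_at:
        verdict = "AR"
    elif primary == "AT" and supports_at and not supports_ar:
        verdict = "AT"
    elif primary == "AR" and not supports_at and res_ar is None:
        verdict = "AR"  # no residue evidence against the profile call
    elif primary == "AT" and not supports_ar and res_at is None:
        verdict = "AT"
    else:
        verdict = "conflict"
    return RuleVerdict(seq.id, "arat", verdict, evidence)


def stretch_net_charge(residues: str) -> int:
    """Net charge with K,R = +1 and D,E = -1; His and gaps contribute 0."""
    return sum(_CHARGE.get(c, 0) for c in residues)


def rab_compatibility(
    query: SequenceRecord,
    rab1b_reference: SequenceRecord,
) -> RuleVerdict:
    """DrrA-substrate compatibility of a Rab GTPase.

    Positions are mapped to human Rab1b numbering by global alignment.
    Compatible iff the residue mapped to position 77 is tyrosine and the
    net charge of the mapped 53-58 stretch is >= +1 (gaps contribute 0).
    """
    res = pairwise_global_align(query, rab1b_reference)
    mapping = res.reference_map
    start, end = RAB_STRETCH
    mapped = []
    coverage_warning = False
    for p in range(start, end + 1):
        q = mapping.get(p)
        mapped.append(query.residues[q - 1] if q is not None else "-")
    q77 = mapping.get(RAB_TYROSINE_POSITION)
    residue_77 = query.residues[q77 - 1] if q77 is not None else None
    if all(c == "-" for c in mapped) or residue_77 is None:
        coverage_warning = True
        logger.warning("rab_compatibility %s: reference positions unmappable", query.id)
    stretch = "".join(mapped)
    charge = stretch_net_charge(stretch)
    compatible = residue_77 == "Y" and charge >= 1 and not coverage_warning
    return RuleVerdict(
        seq_id=query.id,
        rule="rab",
        verdict="compatible" if compatible else "incompatible",
        evidence={
            "stretch_53_58": stretch,
            "net_charge": charge,
            "residue_at_77": residue_77,
            "coverage_warning": coverage_warning,
        },
    )


def synthetic_rab1b_reference(seed: int = 2024) -> SequenceRecord:
    """A synthetic stand-in for the human Rab1b reference sequence.

    Not a real Rab protein: a reproducible random small-GTPase-sized
    sequence constructed so that position 77 is the AMPylatable tyrosine
    and the 53-58 stretch is net positive, the two features the
    compatibility rule reads.  Use a curated Rab1b sequence in real
    analyses.
    """
    import numpy as np

    from .seqio import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    residues = list("".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=180)))
    residues[52:58] = list("KRTVKE")  # positions 53-58, net charge +2
    residues[76] = "Y"  # position 77
    return SequenceRecord(id="rab1b_synthetic", residues="".join(residues))
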