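import itertools

import numpy as np
import pytest

from ampyscan.phmm import HmmHit, build_profile
from ampyscan.rules import (
    ANKX_DIAGNOSTIC_RESIDUES,
    ankx_screen,
    arat_assign,
    rab_compatibility,
    stretch_net_charge,
    synthetic_rab1b_reference,
)
from ampyscan.seqio import AMINO_ACIDS, Alignment, SequenceRecord


def identity_profile(length, name="p", seed=0):
    """Profile whose reference map is the identity over 1..length."""
    rng = np.random.default_rng(seed)
    row = "".join(rng.choice(list(AMINO_ACIDS), length))
    return build_profile(Alignment(ids=["a", "b"], rows=[row, row]), name=name)


def hit_for(seq_id, family, evalue, correspondence):
    return HmmHit(seq_id=seq_id, family=family, bitscore=10.0, evalue=evalue,
                  correspondence=correspondence)


class TestAnkxScreen:
    PROFILE_LEN = 50

    def make_case(self, conserved_flags):
        """Query + CMP hit where diagnostic position i is conserved iff flagged."""
        profile = identity_profile(self.PROFILE_LEN, name="cmp")
        residues = list("A" * self.PROFILE_LEN)
        for flag, (pos, aa) in zip(conserved_flags, sorted(ANKX_DIAGNOSTIC_RESIDUES.items())):
            residues[pos - 1] = aa if flag else "W"
        seq = SequenceRecord("q", "".join(residues))
        cmp_hit = hit_for("q", "cmp", 0.5, {k: k for k in range(1, self.PROFILE_LEN + 1)})
        return seq, cmp_hit, profile

    def test_full_truth_table(self):
        """All 16 conservation patterns x Fic present/absent: positive iff
        >= 3 of 4 residues conserved AND the Fic domain co-occurs."""
        fic = hit_for("q", "fic", 1e-6, {})
        for flags in itertools.product([True, False], repeat=4):
            seq, cmp_hit, profile = self.make_case(flags)
            for fic_hit in (fic, None):
                v = ankx_screen(seq, fic_hit, cmp_hit, profile)
                expected = sum(flags) >= 3 and fic_hit is not None
                assert (v.verdict == "positive") == expected, (flags, fic_hit)
                assert v.evidence["conserved_count"] == sum(flags)

    def test_no_cmp_hit_is_negative_even_with_fic(self):
        seq, _, profile = self.make_case((True,) * 4)
        fic = hit_for("q", "fic", 1e-6, {})
        v = ankx_screen(seq, fic, None, profile)
        assert v.verdict == "negative" and v.evidence["conserved_count"] == 0

    def test_unmappable_position_counts_not_conserved(self, caplog):
        seq, cmp_hit, profile = self.make_case((True,) * 4)
        del cmp_hit.correspondence[profile.match_state_for_reference_position(28)]
        with caplog.at_level("INFO"):
            v = ankx_screen(seq, hit_for("q", "fic", 1e-6, {}), cmp_hit, profile)
        assert v.evidence["conserved_count"] == 3
        assert v.verdict == "positive"  # 3 of 4 still passes
        assert any("unmappable" in r.message for r in caplog.records)

    def test_evidence_records_observed_and_expected(self):
        seq, cmp_hit, profile = self.make_case((True, False, True, True))
        v = ankx_screen(seq, None, cmp_hit, profile)
        assert v.evidence["expected"] == ANKX_DIAGNOSTIC_RESIDUES
        assert v.evidence["observed"][30] == "W"
        assert v.evidence["cmp_evalue"] == 0.5
        assert v.evidence["fic_domain_present"] is False


class TestAratAssign:
    def setup_profiles(self):
        ar = identity_profile(10, name="AR", seed=1)
        at = identity_profile(10, name="AT", seed=2)
        ar.reference_map = {5: 169}
        at.reference_map = {5: 697}
        return ar, at

    def seq_with(self, res5):
        return SequenceRecord("q", "AAAA" + res5 + "AAAAA")

    def test_no_hits_is_none(self):
        v = arat_assign(SequenceRecord("q", "AAAA"), None, None)
        assert v.verdict == "none"

    def test_agreeing_ar_call(self):
        ar, at = self.setup_profiles()
        seq = self.seq_with("N")  # Asn at the AR-169-equivalent position
        ar_hit = hit_for("q", "AR", 1e-8, {5: 5})
        at_hit = hit_for("q", "AT", 1e-2, {5: 5})
        v = arat_assign(seq, ar_hit, at_hit, ar, at)
        assert v.verdict == "AR"
        assert v.evidence["primary_call"] == "AR"
        assert v.evidence["residue_at_ar169"] == "N"

    def test_agreeing_at_call(self):
        ar, at = self.setup_profiles()
        seq = self.seq_with("G")  # Gly at the AT-697-equivalent position
        ar_hit = hit_for("q", "AR", 1e-2, {5: 5})
        at_hit = hit_for("q", "AT", 1e-8, {5: 5})
        assert arat_assign(seq, ar_hit, at_hit, ar, at).verdict == "AT"

    def test_profile_and_residue_disagree_is_conflict(self):
        ar, at = self.setup_profiles()
        seq = self.seq_with("G")  # residue evidence says AT...
        ar_hit = hit_for("q", "AR", 1e-8, {5: 5})  # ...profile says AR
        at_hit = hit_for("q", "AT", 1e-2, {5: 5})
        assert arat_assign(seq, ar_hit, at_hit, ar, at).verdict == "conflict"

    def test_single_hit_with_unmappable_residue_keeps_profile_call(self):
        ar, at = self.setup_profiles()
        seq = self.seq_with("A")
        ar_hit = hit_for("q", "AR", 1e-8, {})  # anchor deleted: no residue evidence
        v = arat_assign(seq, ar_hit, None, ar, at)
        assert v.verdict == "AR" and v.evidence["residue_at_ar169"] is None

    def test_equal_evalues_prefer_ar(self):
        ar, at = self.setup_profiles()
        seq = self.seq_with("N")
        ar_hit = hit_for("q", "AR", 1e-4, {5: 5})
        at_hit = hit_for("q", "AT", 1e-4, {5: 5})
        v = arat_assign(seq, ar_hit, at_hit, ar, at)
        assert v.evidence["primary_call"] == "AR"


class TestStretchCharge:
    @pytest.mark.parametrize(
        "stretch,charge",
        [("KRTVKE", 2), ("DDEEAA", -4), ("HHHHHH", 0), ("--K--D", 0), ("", 0)],
    )
    def test_values(self, stretch, charge):
        assert stretch_net_charge(stretch) == charge


class TestRabCompatibility:
    def test_reference_is_self_compatible(self):
        ref = synthetic_rab1b_reference()
        v = rab_compatibility(ref, ref)
        assert v.verdict == "compatible"
        assert v.evidence["residue_at_77"] == "Y"
        assert v.evidence["stretch_53_58"] == "KRTVKE"
        assert v.evidence["net_charge"] == 2

    def test_phenylalanine_at_77_is_incompatible(self):
        ref = synthetic_rab1b_reference()
        mutant = list(ref.residues)
        mutant[76] = "F"
        v = rab_compatibility(SequenceRecord("m", "".join(mutant)), ref)
        assert v.verdict == "incompatible" and v.evidence["residue_at_77"] == "F"

    def test_negative_stretch_is_incompatible(self):
        ref = synthetic_rab1b_reference()
        mutant = list(ref.residues)
        mutant[52:58] = list("DDEEAA")
        v = rab_compatibility(SequenceRecord("m", "".join(mutant)), ref)
        assert v.verdict == "incompatible" and v.evidence["net_charge"] == -4

    def test_charge_monotone_under_d_to_k_substitutions(self):
        ref = synthetic_rab1b_reference()
        base = list(ref.residues)
        base[52:58] = list("DDDVAA")  # charge -3
        charges = []
        for n_k in range(4):
            s = base.copy()
            for i in range(n_k):
                s[52 + i] = "K"
            v = rab_compatibility(SequenceRecord(f"m{n_k}", "".join(s)), ref)
            charges.append(v.evidence["net_charge"])
        assert charges == [-3, -1, 1, 3]
        # compatibility flips exactly when the charge reaches +1

    def test_unrelated_sequence_warns_and_is_incompatible(self, caplog):
        ref = synthetic_rab1b_reference()
        short = SequenceRecord("tiny", "MK")
        with caplog.at_level("WARNING"):
            v = rab_compatibility(short, ref)
        assert v.verdict == "incompatible"
        assert v.evidence["coverage_warning"] is True
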