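"""Novelty annotation, substitution notation, skip alignment, naming."""

import itertools
import random

import pytest

import peptaibiomics as pb
from peptaibiomics import annotate
from peptaibiomics.annotate import (
    ReferenceEntry,
    annotate_compound,
    assign_names,
    nearest_reference,
    roman,
    skip_alignment,
    substitution_notation,
)
from peptaibiomics.chemistry import SequenceModel


def _ref(name, seq_string):
    return ReferenceEntry(name=name, sequence=pb.parse_sequence(seq_string))


class TestNearestReference:
    def test_single_substitution_variant(self, by_name, reference_db):
        """The most produced 19-residue compound of its strain is the
        position-1 Aib->Vxx variant of a known reference."""
        hits = nearest_reference(by_name("Strigaibol-like XII"), reference_db)
        names = [e.name for e, _ in hits]
        assert "Strigaibol C" in names
        subs = dict((e.name, s) for e, s in hits)["Strigaibol C"]
        assert subs == [(1, "Aib", "Vxx")]

    def test_known_compound_identity(self, by_name, reference_db):
        ann = annotate_compound(by_name("Strigaibol-like V"), reference_db)
        assert ann.status == "known"
        assert "Strigaibol B" in [e.name for e, _ in ann.nearest]
        assert ann.substitutions == []

    def test_self_match(self, by_name, reference_db):
        seq = by_name("Strigaibol-like XII")
        db = reference_db + [ReferenceEntry(name="Self", sequence=seq)]
        hits = nearest_reference(seq, db)
        assert [e.name for e, _ in hits] == ["Self"]
        assert hits[0][1] == []

    def test_ambiguity_codes_match_members(self):
        db = [_ref("Concrete", "Ac-Leu-Pro-Leuol")]
        obs = pb.parse_sequence("Ac-Lxx-Pro-Lxxol")
        hits = nearest_reference(obs, db)
        assert hits[0][1] == []

    def test_max_dist_cutoff(self, by_name, reference_db):
        assert nearest_reference(by_name("Strigaibol-like XII"), reference_db, max_dist=0) == []

    def test_empty_db_rejected(self, by_name):
        with pytest.raises(ValueError, match="empty"):
            nearest_reference(by_name("Strigaibol-like XII"), [])

    def test_metric_properties_on_random_pairs(self, lib):
        """Identity of indiscernibles and symmetry of the substitution
        distance on random equal-length token strings."""
        rng = random.Random(3)
        toks = ["Aib", "Gly", "Ala", "Lxx", "Vxx", "Gln"]
        for _ in range(30):
            a = tuple(rng.choice(toks) for _ in range(10))
            b = tuple(rng.choice(toks) for _ in range(10))
            sa = SequenceModel(cap="Ac", residues=a, terminus="Lxxol")
            sb = SequenceModel(cap="Ac", residues=b, terminus="Lxxol")
            d_ab = len(nearest_reference(sa, [ReferenceEntry("x", sb)])[0][1])
            d_ba = len(nearest_reference(sb, [ReferenceEntry("x", sa)])[0][1])
            assert d_ab == d_ba
            assert (d_ab == 0) == (a == b)


class TestSubstitutionNotation:
    def test_two_position_variant(self, by_name, reference_db):
        ref = next(e for e in reference_db if e.name == "Strigaibol B")
        assert (
            substitution_notation(ref, by_name("Strigaibol-like II"))
            == "[Aib]^1 → [Vxx]^1; [Aib]^8 → [Ala]^8"
        )

    def test_identity_is_empty(self, by_name, reference_db):
        ref = next(e for e in reference_db if e.name == "Strigaibol B")
        assert substitution_notation(ref, by_name("Strigaibol-like V")) == ""

    def test_positions_ascend(self):
        ref = pb.parse_sequence("Ac-Aib-Aib-Aib-Lxxol")
        obs = pb.parse_sequence("Ac-Gly-Ala-Ser-Lxxol")
        s = substitution_notation(ref, obs)
        assert s == "[Aib]^1 → [Gly]^1; [Aib]^2 → [Ala]^2; [Aib]^3 → [Ser]^3"

    def test_terminal_alcohol_counts_as_position(self):
        ref = pb.parse_sequence("Ac-Aib-Pro-Lxxol")
        obs = pb.parse_sequence("Ac-Aib-Pro-Vxxol")
        assert substitution_notation(ref, obs) == "[Lxxol]^3 → [Vxxol]^3"

    def test_length_mismatch_points_to_skip_alignment(self):
        ref = pb.parse_sequence("Ac-Aib-Aib-Pro-Lxxol")
        obs = pb.parse_sequence("Ac-Aib-Pro-Lxxol")
        with pytest.raises(ValueError, match="skip_alignment"):
            substitution_notation(ref, obs)

    def test_compositional_isomer_flag(self):
        ref = pb.parse_sequence("Ac-Aib-Gly-Phe-Lxxol")
        obs = pb.parse_sequence("Ac-Phe-Gly-Aib-Lxxol")
        assert annotate.is_compositional_isomer(ref, obs)
        assert not annotate.is_compositional_isomer(ref, ref)


class TestSkipAlignment:
    def test_single_gap_at_position_9(self, by_name):
        """The 18-residue variant aligns on the 19-residue template with
        one skipped module, printed at position 9 (end of the Aib run)."""
        sols = skip_alignment(
            by_name("Dorothopsin A-b I").without_gaps(), by_name("Dorothopsin A-a I")
        )
        assert sols[0].gap_positions == (9,)
        assert sols[0].substitutions == ()

    def test_triple_skip_at_9_16_17(self, by_name):
        sols = skip_alignment(
            by_name("Dorothopsin A-e I").without_gaps(), by_name("Dorothopsin A-a I")
        )
        assert sols[0].gap_positions == (9, 16, 17)

    def test_truncation_gap_lands_at_final_position(self):
        tpl = pb.parse_sequence("Ac-Aib-Gly-Ala-Ser-Pro-Lxxol")
        short = pb.parse_sequence("Ac-Aib-Gly-Ala-Ser-Lxxol")
        sols = skip_alignment(short, tpl)
        assert (5,) in [s.gap_positions for s in sols]
        assert all(s.n_substitutions == 0 for s in sols)

    def test_deficit_cap_refused(self):
        tpl = pb.parse_sequence("Ac-Aib-Gly-Ala-Ser-Pro-Aib-Lxxol")
        short = pb.parse_sequence("Ac-Aib-Gly-Lxxol")
        with pytest.raises(ValueError, match="deficit"):
            skip_alignment(short, tpl)

    def test_gapped_model_renders_skip_tokens(self, by_name):
        sols = skip_alignment(
            by_name("Dorothopsin A-b I").without_gaps(), by_name("Dorothopsin A-a I")
        )
        assert "(skip)" in sols[0].gapped.token_string()
        assert sols[0].gapped.length() == 18

    @pytest.mark.parametrize("deficit", [1, 2, 3])
    def test_agrees_with_exhaustive_enumeration(self, lib, deficit):
        """Oracle equivalence: the minimal substitution count over all gap
        placements matches an independent brute-force enumeration on
        random 19-token templates."""
        rng = random.Random(deficit * 101)
        toks = ["Aib", "Gly", "Ala", "Ser", "Lxx", "Vxx", "Gln", "Pro"]
        for trial in range(10):
            tpl_tokens = [rng.choice(toks) for _ in range(18)]
            tpl = SequenceModel(cap="Ac", residues=tuple(tpl_tokens), terminus="Lxxol")
            # build the short sequence by deleting `deficit` positions and
            # mutating one surviving position half the time
            drop = sorted(rng.sample(range(18), deficit))
            short_tokens = [t for i, t in enumerate(tpl_tokens) if i not in drop]
            if trial % 2:
                k = rng.randrange(len(short_tokens))
                short_tokens[k] = rng.choice([t for t in toks if t != short_tokens[k]])
            short = SequenceModel(
                cap="Ac", residues=tuple(short_tokens), terminus="Lxxol"
            )

            # independent brute force over all placements
            def brute_min():
                tplp = tpl.positions()
                obsp = short.positions()
                best = None
                for gaps in itertools.combinations(range(1, len(tplp) + 1), deficit):
                    kept = [t for i, t in enumerate(tplp, 1) if i not in gaps]
                    subs = sum(
                        0 if lib.equivalent(a, b) else 1 for a, b in zip(kept, obsp)
                    )
                    best = subs if best is None else min(best, subs)
                return best

            sols = skip_alignment(short, tpl)
            assert sols[0].n_substitutions == brute_min()


class TestNaming:
    def test_elution_order_roman_numerals(self):
        seqs = [
            pb.parse_sequence("Oc-Aib-Gly-Lxx-Gly-Lxx-Lxxol", rt=rt)
            for rt in [9.3, 6.57, 10.54, 7.23]
        ]
        names = assign_names(seqs, "Lipostrigosellin")
        # ranks follow rt: 6.57 -> I, 7.23 -> II, 9.3 -> III, 10.54 -> IV
        assert names == [
            "Lipostrigosellin III",
            "Lipostrigosellin I",
            "Lipostrigosellin IV",
            "Lipostrigosellin II",
        ]

    def test_single_compound(self):
        seqs = [pb.parse_sequence("Ac-Aib-Pro-Lxxol", rt=5.0)]
        assert assign_names(seqs, "Dorothopsin") == ["Dorothopsin I"]

    def test_roman_against_independent_oracle(self):
        def oracle(n):  # additive composition, independent of the encoder
            table = {
                1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII",
                8: "VIII", 9: "IX",
            }
            tens = {0: "", 1: "X", 2: "XX", 3: "XXX", 4: "XL", 5: "L"}
            return tens[n // 10] + table.get(n % 10, "")

        for n in range(1, 60):
            assert roman(n) == oracle(n), n

    def test_empty_stem_rejected(self):
        with pytest.raises(ValueError, match="stem"):
            assign_names([pb.parse_sequence("Ac-Aib-Pro-Lxxol", rt=1.0)], "")
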