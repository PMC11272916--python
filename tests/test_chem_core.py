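"""Parsing, canonicalization, tokenization, scope filter, enumerator."""

import pytest
from hypothesis import given, settings, strategies as st

from inkmol import chem_core as cc


class TestParse:
    @pytest.mark.parametrize("smiles,n_heavy,n_rings", [
        ("CCO", 3, 0),
        ("CCC(C)COC(=O)C(C)CC", 12, 0),  # the branched-ester drawing example
        ("c1ccccc1", 6, 1),
        ("C", 1, 0),
    ])
    def test_heavy_atom_and_ring_counts(self, smiles, n_heavy, n_rings):
        g = cc.parse_smiles(smiles)
        assert g.n_heavy_atoms == n_heavy
        assert g.ring_count == n_rings
        assert g.elements() <= {"C", "O"}

    def test_unbalanced_parenthesis_reports_position(self):
        with pytest.raises(cc.SmilesParseError) as exc:
            cc.parse_smiles("C(C")
        assert exc.value.position == 1

    def test_empty_string_rejected(self):
        with pytest.raises(cc.SmilesParseError):
            cc.parse_smiles("")

    def test_valence_violation_is_chemistry_error(self):
        with pytest.raises(cc.ChemistryError):
            cc.parse_smiles("C(=O)(=O)(=O)O")  # 7 bonds on one carbon

    def test_aromatic_atoms_flagged(self):
        g = cc.parse_smiles("c1ccccc1")
        assert all(arom for _, arom in g.atoms)

    def test_ring_count_matches_cyclomatic_number(self, corpus5):
        for smi in corpus5:
            g = cc.parse_smiles(smi)
            assert g.ring_count == len(g.bonds) - g.n_heavy_atoms + 1


class TestCanonicalize:
    def test_atom_order_invariance(self):
        assert cc.canonicalize("OCC") == cc.canonicalize("CCO")

    def test_single_atom_fixed_point(self):
        assert cc.canonicalize("C") == "C"

    def test_idempotent_on_corpus(self, corpus5):
        for smi in corpus5:
            assert cc.canonicalize(smi) == smi

    def test_canonical_invariance_of_randomized_forms(self, corpus5):
        for smi in corpus5[::7]:
            forms = {cc.canonicalize(cc.randomized_smiles(smi, s))
                     for s in range(10)}
            assert forms == {smi}

    def test_randomization_explores_orderings(self):
        decane = cc.parse_smiles("CCCCCCCCCC")
        raw = {cc.randomized_smiles(decane, s) for s in range(20)}
        assert len(raw) >= 2

    def test_randomization_deterministic_per_seed(self):
        assert (cc.randomized_smiles("CCC(C)CO", 7)
                == cc.randomized_smiles("CCC(C)CO", 7))


class TestTokenizer:
    def test_framing(self, vocab):
        ids = cc.tokenize("C=O", vocab)
        assert ids[0] == vocab.bos_id and ids[-1] == vocab.eos_id
        assert [vocab.tokens[i] for i in ids[1:-1]] == ["C", "=", "O"]

    def test_empty_string(self, vocab):
        assert cc.tokenize("", vocab) == [vocab.bos_id, vocab.eos_id]

    def test_out_of_vocabulary_names_the_character(self, vocab):
        with pytest.raises(cc.TokenizationError, match="'N'"):
            cc.tokenize("CCN", vocab)

    @given(st.text(alphabet=list(cc.DEFAULT_ALPHABET), max_size=30))
    @settings(deadline=None, max_examples=200)
    def test_round_trip_any_alphabet_string(self, text):
        assert cc.detokenize(cc.tokenize(text)) == text

    def test_round_trip_on_corpus(self, corpus5, vocab):
        for smi in corpus5:
            assert cc.detokenize(cc.tokenize(smi, vocab), vocab) == smi

    def test_vocabulary_json_round_trip(self, vocab):
        assert cc.Vocabulary.from_json(vocab.to_json()) == vocab

    def test_reserved_symbols_disjoint_from_alphabet(self, vocab):
        assert not {cc.PAD, cc.BOS, cc.EOS} & set(cc.DEFAULT_ALPHABET)


class TestScopeFilter:
    @pytest.mark.parametrize("smiles,expected", [
        ("c1ccccc1", True),          # one aromatic ring
        ("CCN", False),              # nitrogen out of scope
        ("C1CC2(CC1)CC2", False),    # spiro bicycle: two rings
        ("C(C", False),              # unparseable
        ("C" * 31, False),           # over the length cap
    ])
    def test_scope_decisions(self, smiles, expected):
        assert cc.passes_scope_filter(smiles) is expected

    def test_enumerator_output_is_fixed_point(self, corpus5):
        assert all(cc.passes_scope_filter(s) for s in corpus5)


class TestEnumerator:
    def test_single_heavy_atom_is_methane_and_water(self):
        assert cc.enumerate_cho(1, 1) == ["C", "O"]

    def test_two_heavy_atoms(self):
        # hand-verifiable: ethane, ethene, ethyne, methanol, formaldehyde,
        # peroxide, dioxygen + the two single-atom molecules
        assert cc.enumerate_cho(2, 1) == [
            "C", "O", "CC", "CO", "OO", "C#C", "C=C", "C=O", "O=O"]

    def test_frozen_counts(self):
        # values computed once by this exhaustive enumeration and pinned
        assert len(cc.enumerate_cho(3, 1)) == 34
        assert len(cc.enumerate_cho(4, 1)) == 130

    def test_acyclic_subset(self):
        acyclic = cc.enumerate_cho(3, 0)
        assert all(cc.parse_smiles(s).ring_count == 0 for s in acyclic)
        assert set(acyclic) < set(cc.enumerate_cho(3, 1))

    def test_no_duplicates_by_canonical_form(self, corpus5):
        assert len(corpus5) == len(set(corpus5))

    def test_guard_rejects_large_requests(self):
        with pytest.raises(ValueError):
            cc.enumerate_cho(9, 1)


def test_smiles_file_round_trip(tmp_path, corpus4):
    path = tmp_path / "corpus.smi"
    cc.write_smiles_file(path, corpus4)
    path.write_text("# comment line\n\n" + path.read_text())
    assert cc.read_smiles_file(path) == list(corpus4)
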