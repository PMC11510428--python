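"""Molecular substrate: parsing, canonicalization, ring perception,
the acyclic N–N criterion, descriptors and fingerprints."""

import numpy as np
import pytest

from azogen.chem import (
    SmilesSyntaxError,
    ValenceError,
    canonicalize,
    descriptors,
    has_bonded_nn,
    morgan_fingerprint,
    parse_smiles,
    tanimoto,
)


class TestParsing:
    def test_ethanol_graph(self):
        m = parse_smiles("CCO")
        assert m.n_heavy_atoms == 3
        assert len(m.bonds) == 2
        assert m.n_rings == 0
        assert all(not in_ring for *_, in_ring in m.bonds)

    def test_unclosed_ring_is_syntax_error(self):
        with pytest.raises(SmilesSyntaxError):
            parse_smiles("C1CC")

    @pytest.mark.parametrize("bad", ["", "   ", "C(C", "X~Q"])
    def test_malformed_inputs(self, bad):
        with pytest.raises(SmilesSyntaxError):
            parse_smiles(bad)

    def test_valence_violation(self):
        with pytest.raises(ValenceError):
            parse_smiles("C(C)(C)(C)(C)C")  # pentavalent carbon

    def test_seven_heavy_atom_ring_molecule(self):
        # one of the packaged recommendation molecules
        m = parse_smiles("NC1=CSN=C=C1")
        assert m.n_heavy_atoms == 7
        assert m.n_rings == 1

    def test_ring_flags_match_bruteforce_cycle_check(self, small_corpus):
        # a bond is a ring bond iff removing it leaves its endpoints connected
        for smi in small_corpus.smiles()[:60]:
            m = parse_smiles(smi)
            adj = {i: set() for i in range(m.n_heavy_atoms)}
            for i, j, *_ in m.bonds:
                adj[i].add(j)
                adj[j].add(i)
            for i, j, _, in_ring in m.bonds:
                adj[i].discard(j)
                adj[j].discard(i)
                seen, stack = {i}, [i]
                while stack:
                    u = stack.pop()
                    for v in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                assert (j in seen) == in_ring, f"{smi} bond {i}-{j}"
                adj[i].add(j)
                adj[j].add(i)


class TestCanonicalization:
    def test_spellings_converge(self):
        assert canonicalize("OCC") == canonicalize("CCO")

    @pytest.mark.parametrize("smi", ["CC1C(O)C1O", "c1ccccc1/N=N/c1ccccc1", "CCO"])
    def test_idempotent(self, smi):
        once = canonicalize(smi)
        assert canonicalize(once) == once

    def test_methane(self):
        assert canonicalize("C") == "C"

    def test_roundtrip_fixed_point_on_corpus(self, small_corpus):
        for smi in small_corpus.smiles()[:50]:
            c1 = canonicalize(smi)
            assert canonicalize(c1) == c1


# (SMILES, relaxed, strict) — labels derived by hand from ring membership
# and bond order of every N–N bond in the structure.
NN_TRUTH_TABLE = [
    ("c1ccccc1/N=N/c1ccccc1", True, True),  # azobenzene
    ("CC1C=CON=N1", False, False),  # N=N inside the ring
    ("CC1=C=CC1C=NN=C", True, False),  # acyclic N–N single bond
    ("N=CN1CCCN1", False, False),  # the only N–N bond closes the ring
    ("N=N", True, True),
    ("NN", True, False),
    ("CN=NC", True, True),
    ("CNNC", True, False),
    ("C/N=N/C", True, True),
    ("N1CC1", False, False),  # single nitrogen
    ("C1NN1", False, False),  # diaziridine: N–N in ring
    ("C1CNNC1", False, False),
    ("NN=O", True, False),  # N–N single; the double bond is N=O
    ("CCO", False, False),
    ("c1ccccc1", False, False),
    ("NC=O", False, False),
    ("N#N", True, False),  # triple bond: relaxed only
    ("CN(C)N=O", True, False),
    ("c1cc[nH]n1", False, False),  # aromatic ring N–N
    ("NCCN", False, False),  # nitrogens not bonded to each other
    ("NN1CCCC1", True, False),  # exocyclic N–N: bond acyclic, atom in ring
    ("C[N+](C)(C)C", False, False),
    ("N=NC1CC1", True, True),
    ("C1CC1N=NC1CC1", True, True),
]


class TestBondedNNCriterion:
    @pytest.mark.parametrize("smi,relaxed,strict", NN_TRUTH_TABLE)
    def test_truth_table(self, smi, relaxed, strict):
        m = parse_smiles(smi)
        assert has_bonded_nn(m) is relaxed
        assert has_bonded_nn(m, strict=True) is strict

    def test_strict_implies_relaxed(self, small_corpus, table2_smiles):
        for smi in small_corpus.smiles() + table2_smiles:
            m = parse_smiles(smi)
            if has_bonded_nn(m, strict=True):
                assert has_bonded_nn(m)


class TestDescriptors:
    def test_methane(self):
        d = descriptors(parse_smiles("C"))
        assert (d.hbond_donors, d.hbond_acceptors, d.rotatable_bonds,
                d.aromatic_rings) == (0, 0, 0, 0)

    def test_ethanol_hbonding(self):
        d = descriptors(parse_smiles("CCO"))
        assert d.hbond_donors == 1
        assert d.hbond_acceptors == 1

    def test_benzene(self):
        d = descriptors(parse_smiles("c1ccccc1"))
        assert d.aromatic_rings == 1
        assert d.tpsa == 0.0

    def test_counts_nonnegative_and_mw_positive(self, table2_smiles):
        for smi in table2_smiles:
            d = descriptors(parse_smiles(smi))
            assert d.molecular_weight > 0
            assert min(d.hbond_donors, d.hbond_acceptors, d.rotatable_bonds,
                       d.aromatic_rings, d.structural_alerts) >= 0


class TestMorganFingerprint:
    def test_canonical_invariance(self, small_corpus):
        for smi in small_corpus.smiles()[:20]:
            m = parse_smiles(smi)
            m2 = parse_smiles(m.canonical_smiles)
            f1 = morgan_fingerprint(m, 2, 1024)
            f2 = morgan_fingerprint(m2, 2, 1024)
            assert np.array_equal(f1.bits, f2.bits)

    def test_radius0_environments_are_distinct_atom_types(self):
        # CCO has two element-level radius-0 environments: carbon, oxygen
        fp = morgan_fingerprint(parse_smiles("CCO"), radius=0, n_bits=2048)
        assert fp.popcount() == 2

    def test_self_tanimoto_is_one(self):
        fp = morgan_fingerprint(parse_smiles("CCO"), 2, 256)
        assert tanimoto(fp, fp) == 1.0

    def test_any_molecule_sets_a_bit(self, table2_smiles):
        for smi in table2_smiles:
            assert morgan_fingerprint(parse_smiles(smi), 2, 256).popcount() >= 1

    def test_invalid_nbits_rejected(self):
        m = parse_smiles("CCO")
        with pytest.raises(ValueError):
            morgan_fingerprint(m, 2, 100)  # not a power of two
        with pytest.raises(ValueError):
            morgan_fingerprint(m, 2, 32)  # too small
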