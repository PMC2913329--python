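import math
import random

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from amescade.atomtypes import TypeTableError, atom_type_counts, load_type_table
from amescade.crippen import UnclassifiableAtomError, alogp
from amescade.descriptors import (
    apply_scaling,
    compute_all,
    compute_vector,
    descriptor_names,
    fit_scaling,
)
from amescade.estate import estate_values, gmin, intrinsic_state
from amescade.records import record_from_smiles
from amescade.synth import FixtureSpec, generate
from amescade.topology import idwbar, nrings


def mol(smi):
    return Chem.MolFromSmiles(smi)


class TestEState:
    def test_ethane_hand_values(self):
        # both carbons: delta=1, deltav=1 -> I=2.0; symmetric -> S=I
        s = estate_values(mol("CC"))
        assert np.allclose(s, [2.0, 2.0])

    def test_propane_hand_values(self):
        # terminal CH3: I=2.0; central CH2: I=1.5
        # S(term) = 2 + 0.5/4 = 2.125 ; S(centr) = 1.5 - 2*0.5/4 = 1.25
        s = estate_values(mol("CCC"))
        assert np.allclose(s, [2.125, 1.25, 2.125])

    def test_symmetric_atoms_get_equal_values(self):
        s = estate_values(mol("c1ccccc1"))
        assert np.allclose(s, s[0])

    def test_sum_rule_perturbations_cancel(self):
        for smi in ["CC(N)C(=O)O", "c1ccc2ccccc2c1", "CCOC(=O)c1ccccc1[N+](=O)[O-]"]:
            m = mol(smi)
            total_i = sum(intrinsic_state(a) for a in m.GetAtoms())
            assert math.isclose(estate_values(m).sum(), total_i, rel_tol=1e-9)

    def test_single_heavy_atom_is_finite(self):
        assert math.isfinite(gmin(mol("C")))
        assert math.isfinite(gmin(mol("O")))

    def test_gmin_values(self):
        assert gmin(mol("CC")) == pytest.approx(2.0)
        assert gmin(mol("CCC")) == pytest.approx(1.25)


class TestTopology:
    @pytest.mark.parametrize(
        "smi,expected",
        [("CC", 0.0), ("CCC", 1.5), ("CC(C)C", (9 * math.log2(9) - 6) / 9)],
    )
    def test_idwbar_hand_values(self, smi, expected):
        assert idwbar(mol(smi)) == pytest.approx(expected, abs=1e-9)

    def test_idwbar_single_atom_and_fragments(self):
        assert idwbar(mol("C")) == 0.0
        # multi-fragment: largest fragment (propane) wins
        assert idwbar(mol("CCC.O")) == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "smi,expected",
        [("CCC", 0), ("c1ccccc1", 1), ("c1ccc2ccccc2c1", 2), ("C1CC2(CC1)CCCC2", 2)],
    )
    def test_nrings_cyclomatic(self, smi, expected):
        assert nrings(mol(smi)) == expected


class TestAtomTypes:
    def test_propane_has_two_methyl_groups(self):
        assert atom_type_counts(mol("CCC"))["sCH3"] == 2

    def test_benzene_six_aromatic_ch(self):
        assert atom_type_counts(mol("c1ccccc1"))["aaCH"] == 6

    def test_ethanol_one_hydroxyl(self):
        assert atom_type_counts(mol("CCO"))["sOH"] == 1

    def test_nitro_counted_once_in_both_resonance_forms(self):
        charged = atom_type_counts(mol("c1ccccc1[N+](=O)[O-]"))
        neutral = atom_type_counts(mol("c1ccccc1N(=O)=O"))
        assert charged["ddsN"] == neutral["ddsN"] == 1
        assert charged["dO"] == neutral["dO"] == 2

    def test_overlapping_table_rejected(self, tmp_path):
        bad = tmp_path / "types.yaml"
        bad.write_text(
            "types:\n"
            "  - {name: a, smarts: '[CX4H3]'}\n"
            "  - {name: b, smarts: '[CX4]'}\n"
        )
        with pytest.raises(TypeTableError, match="overlap"):
            load_type_table(str(bad))


class TestAlogp:
    def test_additivity_over_fragments(self):
        assert alogp(mol("CCO.CCC")) == pytest.approx(
            alogp(mol("CCO")) + alogp(mol("CCC")), abs=1e-9
        )

    def test_ethanol_less_lipophilic_than_ethane(self):
        assert alogp(mol("CCO")) < alogp(mol("CC"))

    def test_unclassifiable_atom_raises(self):
        m = Chem.MolFromSmiles("[U]")
        with pytest.raises(UnclassifiableAtomError):
            alogp(m)


class TestVectorAndScaling:
    def test_vector_length_is_25_by_default(self):
        assert len(descriptor_names()) == 25
        vec = compute_vector(record_from_smiles("m", "CCO"))
        assert len(vec.values) == 25 and vec.computed_ok

    def test_failed_record_flagged_others_unaffected(self):
        records = [
            record_from_smiles("good1", "CCO"),
            record_from_smiles("bad", "not_a_smiles"),
            record_from_smiles("good2", "c1ccccc1"),
        ]
        table = compute_all(records)
        assert list(table.ok) == [True, False, True]
        assert len(table.frame) == 3

    def test_count_descriptors_are_nonnegative_integers(self):
        table = compute_all([record_from_smiles("m", s) for s in ["CCO", "CCN", "CCCl"]])
        counts = table.frame[[c for c in table.frame.columns if c not in ("Gmin", "idwbar", "ALOGP")]]
        assert (counts >= 0).all().all()
        assert np.allclose(counts, counts.round())

    def test_maxabs_scaling_examples(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [-2.0, 1.0, 0.0]})
        sf = fit_scaling(m)
        scaled = apply_scaling(m, sf)
        assert list(scaled["a"]) == [0.25, 0.5, 1.0]
        assert list(scaled["b"]) == [-1.0, 0.5, 0.0]

    def test_all_zero_column_gets_identity_factor(self):
        m = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 2.0]})
        sf = fit_scaling(m)
        assert sf.factors["a"] == 1.0

    def test_training_matrix_scaled_by_own_factors_in_unit_box(self):
        records = generate(FixtureSpec(n=60, seed=3))
        table = compute_all(records)
        scaled = apply_scaling(table.valid_matrix(), fit_scaling(table.valid_matrix()))
        assert (scaled.abs() <= 1.0 + 1e-12).all().all()

    def test_column_mismatch_rejected(self):
        m = pd.DataFrame({"a": [1.0]})
        sf = fit_scaling(pd.DataFrame({"b": [1.0]}))
        with pytest.raises(ValueError, match="column mismatch"):
            apply_scaling(m, sf)

    def test_csv_roundtrip(self, tmp_path):
        table = compute_all([record_from_smiles("m1", "CCO"), record_from_smiles("m2", "CCC")])
        path = tmp_path / "desc.csv"
        table.to_csv(path)
        from amescade.descriptors import DescriptorTable

        again = DescriptorTable.from_csv(path)
        assert np.allclose(again.frame.to_numpy(), table.frame.to_numpy())
        assert list(again.ok) == list(table.ok)


def test_descriptors_invariant_to_atom_renumbering():
    rng = random.Random(0)
    for smi in ["CC(=O)Nc1ccc(O)cc1", "c1ccc2ccccc2c1", "CCOC(=O)C(N)CCl"]:
        m = mol(smi)
        order = list(range(m.GetNumAtoms()))
        rng.shuffle(order)
        perm = Chem.RenumberAtoms(m, order)
        assert gmin(perm) == pytest.approx(gmin(m), abs=1e-9)
        assert idwbar(perm) == pytest.approx(idwbar(m), abs=1e-9)
        assert alogp(perm) == pytest.approx(alogp(m), abs=1e-9)
        assert nrings(perm) == nrings(m)
        assert atom_type_counts(perm) == atom_type_counts(m)
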