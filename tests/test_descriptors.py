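"""Descriptor values against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from tyroqsar import (
    Molecule,
    QuantumRecord,
    build_descriptor_table,
    carbon_scaled_weights,
    compute_descriptor,
    gats,
    geom_distance_matrix,
    getaway_autocorr,
    ic1,
    molecular_influence_leverages,
    morse_signal,
    parse_descriptor_name,
    quantum_indices,
    rdf_value,
    shape_profile,
    topo_distance_matrix,
    whim_set,
)
from tyroqsar.descriptors import PUBLISHED_DESCRIPTORS
from conftest import atom


# ---------------------------------------------------------------------------
# name parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name,family,index,weight", [
    ("IC1", "IC", 1, None),
    ("Mor24m", "MoRSE", 24, "m"),
    ("RDF115e", "RDF", 115, "e"),
    ("GATS8p", "GATS", 8, "p"),
    ("HATS3p", "HATS", 3, "p"),
    ("R7e0", "Rmax", 7, "e"),
    ("R7e", "R", 7, "e"),
    ("SP20", "SP", 20, None),
    ("G3p", "WHIM_G", 3, "p"),
    ("E3u", "WHIM_E", 3, "u"),
    ("dipx", "dipole", 0, None),
])
def test_name_parses_to_family_index_weight(name, family, index, weight):
    spec = parse_descriptor_name(name)
    assert (spec.family, spec.index, spec.weight) == (family, index, weight)
    assert spec.name == name


@pytest.mark.parametrize("bad", ["Mor99q", "RDF11m", "XYZ3", "Mor33m", "IC", ""])
def test_unknown_names_rejected(bad):
    with pytest.raises(ValueError):
        parse_descriptor_name(bad)


def test_paper_preset_names_all_parse():
    assert len(PUBLISHED_DESCRIPTORS) == 26
    for name in PUBLISHED_DESCRIPTORS:
        parse_descriptor_name(name)


# ---------------------------------------------------------------------------
# IC1
# ---------------------------------------------------------------------------

class TestIC1:
    def test_heteronuclear_diatomic_is_one_bit(self, diatomic_cn):
        assert ic1(diatomic_cn) == pytest.approx(1.0)

    def test_homonuclear_diatomic_is_zero(self):
        mol = Molecule("cc", [atom("C", 0, 0, 0), atom("C", 1.5, 0, 0)],
                       [(0, 1, 1.0)])
        assert ic1(mol) == pytest.approx(0.0)

    def test_methane_star_entropy(self, methane_star):
        # partition {1 carbon, 4 hydrogens}: -(1/5)log2(1/5) - (4/5)log2(4/5)
        expected = -(0.2 * math.log2(0.2) + 0.8 * math.log2(0.8))
        assert ic1(methane_star) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7219, abs=5e-5)

    @pytest.mark.parametrize("seed", range(6))
    def test_bounds_and_singleton_condition(self, seed, cloud_factory):
        mol = cloud_factory(seed, n_atoms=7)
        val = ic1(mol)
        assert 0.0 <= val <= math.log2(7) + 1e-12


# ---------------------------------------------------------------------------
# pairwise descriptors vs closed forms
# ---------------------------------------------------------------------------

def two_atoms(distance, e1="C", e2="C"):
    return Molecule("pair", [atom(e1, 0, 0, 0), atom(e2, distance, 0, 0)],
                    [(0, 1, 1.0)])


class TestMorse:
    def test_signal_one_counts_pairs(self, cloud_factory):
        mol = cloud_factory(2, n_atoms=9)
        assert morse_signal(mol, 1, "u") == pytest.approx(9 * 8 / 2)

    def test_sine_zero_at_pi(self):
        # s = 1 (signal 2); r = pi -> sin(pi)/pi = 0
        mol = two_atoms(math.pi)
        assert morse_signal(mol, 2, "u") == pytest.approx(0.0, abs=1e-12)

    def test_equilateral_closed_form(self):
        r = 1.8
        h = r * math.sqrt(3) / 2
        mol = Molecule("tri", [atom("C", 0, 0, 0), atom("C", r, 0, 0),
                               atom("C", r / 2, h, 0)],
                       [(0, 1, 1.0), (1, 2, 1.0)])
        s = 4.0  # signal 5
        expected = 3 * math.sin(s * r) / (s * r)
        assert morse_signal(mol, 5, "u") == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("scheme", ["u", "m", "e", "p", "v"])
    def test_s_zero_equals_weighted_pair_sum(self, scheme, cloud_factory):
        mol = cloud_factory(3, n_atoms=8)
        w = carbon_scaled_weights(mol, scheme)
        expected = sum(w[i] * w[j] for i in range(8) for j in range(i + 1, 8))
        assert morse_signal(mol, 1, scheme) == pytest.approx(expected, rel=1e-12)


class TestRDF:
    def test_pair_at_radius_is_one(self):
        assert rdf_value(two_atoms(3.5), 3.5, "u") == pytest.approx(1.0)

    def test_gaussian_decay(self):
        assert rdf_value(two_atoms(3.5), 3.6, "u", smoothing=100.0) == \
            pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_single_atom_is_zero(self):
        mol = Molecule("one", [atom("C", 0, 0, 0)], [])
        assert rdf_value(mol, 2.0, "u") == 0.0

    def test_vanishes_at_large_radius_and_nonnegative(self, cloud_factory):
        mol = cloud_factory(4)
        assert rdf_value(mol, 150.0, "m") == pytest.approx(0.0, abs=1e-12)
        for radius in (1.0, 3.5, 6.5, 11.5, 15.5):
            assert rdf_value(mol, radius, "v") >= 0.0


class TestGATS:
    def test_equal_weights_undefined(self, path4):
        assert math.isnan(gats(path4, 1, "u"))

    def test_no_pairs_at_lag_undefined(self, diatomic_cn):
        assert math.isnan(gats(diatomic_cn, 5, "m"))

    @pytest.mark.parametrize("seed,lag", [(0, 1), (1, 2), (2, 3), (3, 1), (4, 2)])
    def test_matches_double_loop_oracle(self, seed, lag, cloud_factory):
        mol = cloud_factory(seed, n_atoms=9)
        w = carbon_scaled_weights(mol, "m")
        topo = topo_distance_matrix(mol)
        n = mol.n_atoms
        num = 0.0
        delta = 0
        for i in range(n):
            for j in range(n):
                if i != j and topo[i, j] == lag:
                    num += (w[i] - w[j]) ** 2
                    delta += 1
        var = sum((x - w.mean()) ** 2 for x in w)
        expected = (n - 1) * num / (2 * delta * var)
        assert gats(mol, lag, "m") == pytest.approx(expected, rel=1e-12)

    def test_iid_weights_expectation_near_one(self):
        # Geary coefficient of i.i.d. values on a fixed graph averages ~1
        rng = np.random.default_rng(42)
        from tyroqsar import make_point_cloud_molecule
        mol = make_point_cloud_molecule(10, seed=7)
        topo = topo_distance_matrix(mol)
        n = 10
        vals = []
        mask = topo == 2
        delta = int(mask.sum())
        for _ in range(2000):
            w = rng.standard_normal(n)
            num = (n - 1) * float(((w[:, None] - w[None, :]) ** 2)[mask].sum())
            vals.append(num / (2 * delta * float(np.sum((w - w.mean()) ** 2))))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)


class TestGETAWAY:
    def test_leverages_sum_to_rank(self, cloud_factory, methane_star):
        assert molecular_influence_leverages(cloud_factory(9)).sum() == \
            pytest.approx(3.0)
        planar = Molecule("sq", [atom("C", 0, 0, 0), atom("C", 1, 0, 0),
                                 atom("C", 1, 1, 0), atom("C", 0, 1, 0)],
                          [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        assert molecular_influence_leverages(planar).sum() == pytest.approx(2.0)

    def test_leverages_match_hat_matrix_oracle(self, cloud_factory):
        mol = cloud_factory(13, n_atoms=5)
        M = mol.coords - mol.coords.mean(axis=0)
        H = M @ np.linalg.inv(M.T @ M) @ M.T
        np.testing.assert_allclose(molecular_influence_leverages(mol),
                                   np.diag(H), rtol=1e-9)

    def test_lag_beyond_diameter_is_zero(self, path4):
        assert getaway_autocorr(path4, 9, "u", "HATS") == 0.0
        assert getaway_autocorr(path4, 9, "u", "R") == 0.0

    def test_two_atom_r_and_rmax_agree(self):
        mol = two_atoms(2.0, "C", "N")
        h = molecular_influence_leverages(mol)
        expected = math.sqrt(h[0] * h[1]) / 2.0
        assert getaway_autocorr(mol, 1, "u", "R") == pytest.approx(expected)
        assert getaway_autocorr(mol, 1, "u", "Rmax") == pytest.approx(expected)

    @pytest.mark.parametrize("seed,kind", [(0, "HATS"), (1, "HATS"), (2, "R"),
                                           (3, "R"), (4, "Rmax")])
    def test_matches_double_loop_oracle(self, seed, kind, cloud_factory):
        mol = cloud_factory(seed, n_atoms=8)
        lag = 2
        h = molecular_influence_leverages(mol)
        w = carbon_scaled_weights(mol, "p")
        topo = topo_distance_matrix(mol)
        geom = geom_distance_matrix(mol)
        terms = []
        for i in range(8):
            for j in range(i + 1, 8):
                if topo[i, j] == lag:
                    if kind == "HATS":
                        terms.append(w[i] * math.sqrt(h[i]) * w[j] * math.sqrt(h[j]))
                    else:
                        terms.append(math.sqrt(h[i] * h[j]) / geom[i, j] * w[i] * w[j])
        expected = max(terms) if kind == "Rmax" else sum(terms)
        assert getaway_autocorr(mol, lag, "p", kind) == pytest.approx(expected, rel=1e-10)


class TestWHIM:
    def test_linear_molecule_only_first_axis(self):
        mol = Molecule("lin", [atom("C", float(i), 0, 0) for i in range(4)],
                       [(i, i + 1, 1.0) for i in range(3)])
        vals = whim_set(mol, "u")
        assert vals["L1"] > 0
        assert vals["L2"] == pytest.approx(0.0, abs=1e-12)
        assert vals["L3"] == pytest.approx(0.0, abs=1e-12)

    def test_centrosymmetric_pair_full_symmetry(self):
        mol = Molecule("pair", [atom("C", -1, 0, 0), atom("C", 1, 0, 0)],
                       [(0, 1, 1.0)])
        assert whim_set(mol, "m")["G1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("scheme", ["u", "p"])
    def test_rotation_invariance(self, scheme, cloud_factory):
        from conftest import random_rotation
        mol = cloud_factory(21)
        rotated = mol.transformed(rotation=random_rotation(3),
                                  translation=np.array([1.0, -2.0, 0.5]))
        a, b = whim_set(mol, scheme), whim_set(rotated, scheme)
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-8, abs=1e-10), key


class TestShapeProfile:
    def test_unit_pair_high_order(self):
        assert shape_profile(two_atoms(1.0), 20) == pytest.approx(1.0 / math.factorial(20))

    def test_first_order_is_distance(self):
        assert shape_profile(two_atoms(2.7), 1) == pytest.approx(2.7)

    def test_single_atom_zero(self):
        assert shape_profile(Molecule("one", [atom("C", 0, 0, 0)], []), 3) == 0.0

    def test_matches_moment_oracle(self, cloud_factory):
        mol = cloud_factory(17, n_atoms=6)
        k = 4
        d = geom_distance_matrix(mol)
        pairs = [d[i, j] for i in range(6) for j in range(i + 1, 6)]
        expected = (sum(r**k for r in pairs) / len(pairs)) / math.factorial(k)
        assert shape_profile(mol, k) == pytest.approx(expected, rel=1e-12)


class TestQuantumIndices:
    def test_printed_convention(self):
        qi = quantum_indices(QuantumRecord(-9.0, -1.0))
        assert qi.eta == pytest.approx(-5.0)
        assert qi.softness == pytest.approx(-0.2)
        assert qi.chi == pytest.approx(-4.0)
        assert qi.omega == pytest.approx(-1.6)

    def test_zero_hardness_undefined(self):
        qi = quantum_indices(QuantumRecord(0.0, 0.0))
        assert qi.eta == 0.0
        assert math.isnan(qi.softness) and math.isnan(qi.omega)

    def test_textbook_convention(self):
        qi = quantum_indices(QuantumRecord(-9.0, -1.0), convention="textbook")
        assert qi.eta == pytest.approx(4.0)
        assert qi.chi == pytest.approx(5.0)

    def test_inverted_orbitals_warn(self):
        with pytest.warns(UserWarning, match="E_HOMO"):
            QuantumRecord(1.0, -1.0)


class TestDescriptorTable:
    def test_preset_shape_and_names(self, cloud_factory):
        mols = [cloud_factory(1), cloud_factory(2)]
        q = {m.id: QuantumRecord(-9.0, -1.0, (0.5, 0.1, 0.0)) for m in mols}
        table = build_descriptor_table(mols, quantum=q)
        assert table.shape == (2, 26)
        assert list(table.columns) == PUBLISHED_DESCRIPTORS

    def test_rdf_name_routing(self, cloud_factory):
        mol = cloud_factory(6)
        table = build_descriptor_table([mol], ["RDF115m"])
        assert table.iloc[0, 0] == pytest.approx(rdf_value(mol, 11.5, "m"))

    def test_unknown_name_rejected(self, cloud_factory):
        with pytest.raises(ValueError, match="Mor99q"):
            build_descriptor_table([cloud_factory(1)], ["Mor99q"])

    def test_missing_quantum_record_named(self, cloud_factory):
        mol = cloud_factory(1)
        with pytest.raises(ValueError, match=mol.id):
            build_descriptor_table([mol], ["IC1", "dipx"], quantum={})

    def test_hydrogen_depleted_mode(self, cloud_factory):
        mol = cloud_factory(8, n_atoms=9)
        full = build_descriptor_table([mol], ["SP01" if False else "SP20", "Mor05m"])
        bare = build_descriptor_table([mol], ["SP20", "Mor05m"], hydrogens=False)
        if "H" in mol.elements:
            assert not np.allclose(full.to_numpy(), bare.to_numpy())
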