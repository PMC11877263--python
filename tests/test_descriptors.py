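"""Coulomb matrix and SLATM: formulas, invariances, oracle equivalence."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import special_ortho_group

from mflearn.descriptors import ANGSTROM_TO_BOHR, CoulombMatrix, SLATM, make_descriptor
from mflearn.molecules import Molecule


def _mol(zs, coords, id="m"):
    return Molecule(id=id, atomic_numbers=zs, coordinates=np.asarray(coords, float))


H2 = _mol([1, 1], [[0, 0, 0], [0, 0, 0.74]])
CH4 = _mol([6, 1, 1, 1, 1], [[0, 0, 0], [0.629, 0.629, 0.629], [-0.629, -0.629, 0.629],
                             [-0.629, 0.629, -0.629], [0.629, -0.629, -0.629]])
H2O = _mol([8, 1, 1], [[0, 0, 0.119], [0, 0.763, -0.477], [0, -0.763, -0.477]])


class TestCoulombMatrix:
    def test_single_atom_diagonal_formula(self):
        cm = CoulombMatrix(max_atoms=1).fit([_mol([1], [[0, 0, 0]])])
        vec = cm.transform([_mol([1], [[0, 0, 0]])])[0]
        assert vec.tolist() == [0.5]  # 0.5 * 1**2.4

    def test_h2_off_diagonal_in_bohr(self):
        cm = CoulombMatrix(max_atoms=2, sort_rows=False).fit([H2])
        M = cm.transform([H2])[0].reshape(2, 2)
        expected = 1.0 / (0.74 * ANGSTROM_TO_BOHR)
        assert M[0, 1] == pytest.approx(expected, abs=1e-12)
        assert M[0, 1] == pytest.approx(0.7151, abs=1e-4)
        assert M[0, 0] == M[1, 1] == 0.5

    def test_sorted_cm_is_index_invariant(self):
        perm = np.array([3, 0, 4, 2, 1])
        permuted = _mol(CH4.atomic_numbers[perm], CH4.coordinates[perm])
        cm = CoulombMatrix(max_atoms=5, sort_rows=True).fit([CH4])
        assert np.array_equal(cm.transform([CH4])[0], cm.transform([permuted])[0])

    def test_unsorted_cm_permutation_witness(self):
        # swapping a C against an H changes the unsorted CM
        perm = np.array([1, 0, 2, 3, 4])
        permuted = _mol(CH4.atomic_numbers[perm], CH4.coordinates[perm])
        cm = CoulombMatrix(max_atoms=5, sort_rows=False).fit([CH4])
        diff = cm.transform([CH4])[0] - cm.transform([permuted])[0]
        assert np.max(np.abs(diff)) > 1.0

    def test_padding_and_fixed_width(self):
        cm = CoulombMatrix().fit([CH4, H2O])
        X = cm.transform([CH4, H2O])
        assert X.shape == (2, 25)
        M = X[1].reshape(5, 5)
        assert np.all(M[3:, :] == 0) and np.all(M[:, 3:] == 0)

    def test_errors(self):
        cm = CoulombMatrix(max_atoms=2).fit([H2])
        with pytest.raises(ValueError, match="max_atoms"):
            cm.transform([CH4])
        clash = _mol([1, 1], [[0, 0, 0], [0, 0, 1e-8]])
        with pytest.raises(ValueError, match="coincident"):
            cm.transform([clash])
        with pytest.raises(ValueError, match="max_atoms"):
            CoulombMatrix(max_atoms=2).fit([CH4])


class TestSLATM:
    def test_single_atom_only_one_body(self):
        atom = _mol([6], [[0, 0, 0]])
        sl = SLATM(elements=[1, 6]).fit([atom])
        v = sl.transform([atom])[0]
        assert v[sl.channel_slice("one", 6)] == [1.0]
        assert v[sl.channel_slice("one", 1)] == [0.0]
        n_el = len(sl.elements_)
        assert np.all(v[n_el:] == 0.0)

    def test_dimer_beyond_cutoff_has_empty_spectrum(self):
        far = _mol([1, 1], [[0, 0, 0], [0, 0, 5.5]])
        sl = SLATM(elements=[1]).fit([far])
        v = sl.transform([far])[0]
        assert np.all(v[sl.channel_slice("two", (1, 1))] == 0.0)

    def test_index_invariance(self):
        perm = np.array([4, 2, 0, 1, 3])
        permuted = _mol(CH4.atomic_numbers[perm], CH4.coordinates[perm])
        sl = SLATM().fit([CH4])
        a, b = sl.transform([CH4, permuted])
        assert np.max(np.abs(a - b)) <= 1e-12

    def test_two_body_quadrature_oracle(self):
        d = 1.0
        mol = _mol([1, 1], [[0, 0, 0], [0, 0, d]])
        sl = SLATM(elements=[1]).fit([mol])
        v = sl.transform([mol])[0][sl.channel_slice("two", (1, 1))]
        smear = sl.radial_smear

        def integrand(r):
            gauss = np.exp(-((r - d) ** 2) / (2 * smear**2)) / (smear * np.sqrt(2 * np.pi))
            return gauss * 0.5 / (r * ANGSTROM_TO_BOHR) ** 6

        oracle, _ = quad(integrand, 0.0, sl.cutoff, epsabs=1e-14)
        assert float(np.sum(v)) == pytest.approx(oracle, rel=1e-6)
        # the integral concentrates at d, so it is ~ the London weight there
        # (the curvature of r**-6 over the smear width adds ~21*smear**2/d**2)
        assert float(np.sum(v)) == pytest.approx(0.5 / (d * ANGSTROM_TO_BOHR) ** 6, rel=0.1)

    def test_small_molecule_oracle_equivalence(self):
        """Direct sum-of-Gaussians evaluation reproduces the spectra to 1e-10."""
        sl = SLATM().fit([H2O, H2])
        for mol in (H2O, H2):
            v = sl.transform([mol])[0]
            Z = mol.atomic_numbers
            n = mol.n_atoms
            ref = np.zeros_like(v)
            for z in Z:
                ref[sl.channel_slice("one", int(z))] += 1.0
            for i in range(n):
                for j in range(i + 1, n):
                    d = np.linalg.norm(mol.coordinates[i] - mol.coordinates[j])
                    if d > sl.cutoff:
                        continue
                    za, zb = sorted((int(Z[i]), int(Z[j])))
                    g = np.exp(-((sl.r_grid_ - d) ** 2) / (2 * sl.radial_smear**2))
                    g /= sl.radial_smear * np.sqrt(2 * np.pi)
                    w = 0.5 * za * zb / (sl.r_grid_ * ANGSTROM_TO_BOHR) ** 6
                    ref[sl.channel_slice("two", (za, zb))] += g * w * sl.radial_step
            for apex in range(n):
                others = [i for i in range(n) if i != apex]
                for ii in range(len(others)):
                    for kk in range(ii + 1, len(others)):
                        i, k = others[ii], others[kk]
                        ri = mol.coordinates[i] - mol.coordinates[apex]
                        rk = mol.coordinates[k] - mol.coordinates[apex]
                        dij, djk = np.linalg.norm(ri), np.linalg.norm(rk)
                        dik = np.linalg.norm(mol.coordinates[i] - mol.coordinates[k])
                        if max(dij, djk, dik) > sl.cutoff:
                            continue
                        theta = np.arccos(np.clip(ri @ rk / (dij * djk), -1, 1))
                        rai = mol.coordinates[apex] - mol.coordinates[i]
                        rki = mol.coordinates[k] - mol.coordinates[i]
                        cos_i = rai @ rki / (dij * dik)
                        rak = mol.coordinates[apex] - mol.coordinates[k]
                        rik = mol.coordinates[i] - mol.coordinates[k]
                        cos_k = rak @ rik / (djk * dik)
                        za, zc = sorted((int(Z[i]), int(Z[k])))
                        zb = int(Z[apex])
                        g = np.exp(-((sl.t_grid_ - theta) ** 2) / (2 * sl.angular_smear**2))
                        g /= sl.angular_smear * np.sqrt(2 * np.pi)
                        atm = za * zb * zc * (1 + np.cos(sl.t_grid_) * cos_i * cos_k)
                        atm /= (dij * djk * dik * ANGSTROM_TO_BOHR**3) ** 3
                        ref[sl.channel_slice("three", (za, zb, zc))] += g * atm * sl.angular_step
            assert np.max(np.abs(v - ref)) <= 1e-10

    def test_element_outside_universe_rejected(self):
        sl = SLATM(elements=[1, 6]).fit([H2])
        with pytest.raises(ValueError, match="universe"):
            sl.transform([H2O])


@pytest.mark.parametrize("kind", ["unsorted_cm", "sorted_cm", "slatm"])
def test_rigid_motion_invariance(kind):
    rng = np.random.default_rng(7)
    desc = make_descriptor(kind).fit([CH4, H2O])
    for mol in (CH4, H2O):
        ref = desc.transform([mol])[0]
        for k in range(3):
            R = special_ortho_group.rvs(3, random_state=rng)
            shift = rng.normal(scale=5.0, size=3)
            moved = _mol(mol.atomic_numbers, mol.coordinates @ R.T + shift)
            assert np.max(np.abs(desc.transform([moved])[0] - ref)) <= 1e-10


def test_fixed_dimensionality_across_dataset(benchmark):
    mols = benchmark["ds"].molecules[:20]
    for kind in ("sorted_cm", "slatm"):
        X = make_descriptor(kind).fit(mols).transform(mols)
        assert X.ndim == 2 and np.all(np.isfinite(X))


def test_descriptor_cache_roundtrip(tmp_path):
    from mflearn.descriptors import descriptor_config_hash, load_descriptors, save_descriptors

    desc = CoulombMatrix().fit([CH4, H2O])
    X = desc.transform([CH4, H2O])
    h = descriptor_config_hash(desc)
    path = tmp_path / "cache.h5"
    save_descriptors(path, ["a", "b"], X, h)
    ids, X2 = load_descriptors(path, expected_hash=h)
    assert ids == ["a", "b"] and np.array_equal(X, X2)
    with pytest.raises(ValueError, match="hash"):
        load_descriptors(path, expected_hash="deadbeef")
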