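"""Matching pursuit: recovery, monotonicity, kappa and eta statistics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strfkit as sk
from strfkit.pursuit import MPEntry, MPResults, _shifted_patch


def _atom_id(bank, pred):
    return next(i for i, a in enumerate(bank.atoms) if pred(a))


class TestExactRecovery:
    def test_dictionary_member_recovered_in_one_iteration(self, small_bank):
        for aid in range(0, len(small_bank.atoms), 3):
            target = 2.5 * small_bank.atoms[aid].patch
            dec = sk.mp_decompose(target, small_bank, theta=0.8)
            assert dec.n_iter == 1
            assert dec.entries[0].atom_id == aid
            assert abs(dec.entries[0].weight - 2.5) < 1e-9
            assert dec.recon_correlation[-1] == pytest.approx(1.0, abs=1e-12)
            assert dec.converged

    def test_two_disjoint_atoms_recovered(self, small_bank):
        # a narrow high-frequency temporal atom placed at two disjoint shifts
        aid = _atom_id(small_bank, lambda a: a.omega_t == 125.0 and a.omega_s == 0.0
                       and a.part == "real")
        a = small_bank.atoms[aid].patch
        target = 2.0 * _shifted_patch(a, -12, 0) + 1.0 * _shifted_patch(a, 12, 0)
        dec = sk.mp_decompose(target, small_bank, theta=0.999)
        assert dec.n_iter == 2
        got = {(e.atom_id, e.time_shift): e.weight for e in dec.entries}
        assert got[(aid, -12)] == pytest.approx(2.0, abs=1e-9)
        assert got[(aid, 12)] == pytest.approx(1.0, abs=1e-9)
        assert dec.recon_correlation[-1] > 0.999


@pytest.fixture(scope="module")
def random_decs(small_bank):
    rng = np.random.default_rng(7)
    decs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for _ in range(15):
            t = rng.standard_normal(small_bank.shape)
            decs.append(sk.mp_decompose(t, small_bank, theta=0.9, max_iter=25))
    return decs


class TestMPInvariants:

    def test_recon_correlation_nondecreasing(self, random_decs):
        for dec in random_decs:
            assert np.all(np.diff(dec.recon_correlation) >= -1e-10)

    def test_residual_orthogonal_to_last_atom(self, small_bank, random_decs):
        for dec in random_decs:
            e = dec.entries[-1]
            p = _shifted_patch(small_bank.atoms[e.atom_id].patch,
                               e.time_shift, e.freq_shift)
            p = p / np.linalg.norm(p)
            assert abs(np.sum(dec.residual * p)) < 1e-8

    def test_residual_norm_decreases(self, small_bank):
        rng = np.random.default_rng(3)
        target = rng.standard_normal(small_bank.shape)
        norms = [np.linalg.norm(target)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for max_iter in (1, 3, 6, 10):
                dec = sk.mp_decompose(target, small_bank, theta=0.9999,
                                      max_iter=max_iter)
                norms.append(np.linalg.norm(dec.residual))
        assert np.all(np.diff(norms) < 0)

    def test_energy_bookkeeping(self, random_decs):
        for dec in random_decs:
            recon = dec.reconstruct()
            total = np.sum(dec.target ** 2)
            parts = (np.sum(recon ** 2) + np.sum(dec.residual ** 2)
                     + 2.0 * np.sum(recon * dec.residual))
            assert total == pytest.approx(parts, rel=1e-9)

    def test_zero_target_rejected(self, small_bank):
        with pytest.raises(ValueError):
            sk.mp_decompose(np.zeros(small_bank.shape), small_bank)

    def test_invalid_theta_rejected(self, small_bank, rng):
        t = rng.standard_normal(small_bank.shape)
        for theta in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                sk.mp_decompose(t, small_bank, theta=theta)

    def test_nonconvergence_warns(self, small_bank, rng):
        t = rng.standard_normal(small_bank.shape)
        with pytest.warns(UserWarning, match="matching pursuit stopped"):
            dec = sk.mp_decompose(t, small_bank, theta=0.999, max_iter=2)
        assert not dec.converged


class TestReconstruct:
    def test_empty_entries_give_zero_patch(self, small_bank, rng):
        dec = MPResults(entries=[], residual=np.zeros(small_bank.shape),
                        recon_correlation=np.array([]), theta=0.8, converged=False,
                        bank=small_bank, target=rng.standard_normal(small_bank.shape))
        assert np.all(sk.reconstruct(dec) == 0.0)

    def test_single_entry_places_weighted_atom(self, small_bank):
        a = small_bank.atoms[2]
        dec = MPResults(entries=[MPEntry(2, a.part, 0, 0, -1.5)],
                        residual=np.zeros(small_bank.shape),
                        recon_correlation=np.array([1.0]), theta=0.8, converged=True,
                        bank=small_bank, target=-1.5 * a.patch)
        np.testing.assert_allclose(sk.reconstruct(dec), -1.5 * a.patch)

    def test_unknown_atom_id_rejected(self, small_bank):
        dec = MPResults(entries=[MPEntry(10_000, "real", 0, 0, 1.0)],
                        residual=np.zeros(small_bank.shape),
                        recon_correlation=np.array([1.0]), theta=0.8, converged=True,
                        bank=small_bank, target=np.ones(small_bank.shape))
        with pytest.raises(KeyError):
            sk.reconstruct(dec)

    def test_reconstruction_complements_residual(self, small_bank, rng):
        target = rng.standard_normal(small_bank.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            dec = sk.mp_decompose(target, small_bank, theta=0.95, max_iter=20)
        np.testing.assert_allclose(dec.reconstruct() + dec.residual, target, atol=1e-10)

    def test_span_member_recovered_to_high_correlation(self, small_bank, rng):
        ids = rng.choice(len(small_bank.atoms), 3, replace=False)
        target = sum(rng.standard_normal() * small_bank.atoms[i].patch for i in ids)
        dec = sk.mp_decompose(target, small_bank, theta=0.999, max_iter=50)
        c = np.corrcoef(dec.reconstruct().ravel(), target.ravel())[0, 1]
        assert c >= 0.999


class TestKappa:
    def test_axis_aligned_is_one(self):
        assert sk.kappa_modulation(3.7, 0.0) == pytest.approx(1.0, abs=1e-12)
        assert sk.kappa_modulation(0.0, -0.2) == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_is_sqrt_two(self):
        assert sk.kappa_modulation(1.0, 1.0) == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert sk.kappa_modulation(-0.3, 0.3) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_zero_vector_policy_returns_one(self):
        assert sk.kappa_modulation(0.0, 0.0) == 1.0

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None)
    def test_scale_and_sign_invariance(self, wt, ws, scale):
        k = sk.kappa_modulation(wt, ws)
        assert 1.0 - 1e-9 <= k <= np.sqrt(2.0) + 1e-9
        assert sk.kappa_modulation(scale * wt, scale * ws) == pytest.approx(k, rel=1e-9)
        assert sk.kappa_modulation(-wt, ws) == pytest.approx(k, rel=1e-12)

    def test_decomposition_mean(self, small_bank):
        temporal = _atom_id(small_bank, lambda a: a.omega_s == 0 and a.omega_t > 0)
        dec = MPResults(
            entries=[MPEntry(temporal, small_bank.atoms[temporal].part, 0, 0, 1.0)] * 3,
            residual=np.zeros(small_bank.shape), recon_correlation=np.ones(3),
            theta=0.8, converged=True, bank=small_bank,
            target=np.ones(small_bank.shape))
        assert sk.kappa_decomposition(dec) == pytest.approx(1.0, abs=1e-12)

    def test_empty_decomposition_rejected(self, small_bank):
        dec = MPResults(entries=[], residual=np.zeros(small_bank.shape),
                        recon_correlation=np.array([]), theta=0.8, converged=False,
                        bank=small_bank, target=np.ones(small_bank.shape))
        with pytest.raises(ValueError):
            sk.kappa_decomposition(dec)

    def test_random_decompositions_within_bounds(self, small_bank):
        rng = np.random.default_rng(11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for _ in range(5):
                dec = sk.mp_decompose(rng.standard_normal(small_bank.shape),
                                      small_bank, theta=0.9, max_iter=15)
                assert 1.0 - 1e-12 <= dec.kappa <= np.sqrt(2.0) + 1e-12


class TestImportanceAndCurves:
    def _dec(self, bank, entries):
        return MPResults(entries=entries, residual=np.zeros(bank.shape),
                         recon_correlation=np.ones(max(len(entries), 1)), theta=0.8,
                         converged=True, bank=bank, target=np.ones(bank.shape))

    def test_single_negative_weight(self, small_bank):
        dec = self._dec(small_bank, [MPEntry(0, small_bank.atoms[0].part, 0, 0, -0.9)])
        table = sk.atom_importance([dec], small_bank)
        assert table.eta[0] == pytest.approx(0.9)
        assert table.n_strfs == 1

    def test_additivity_across_decompositions(self, small_bank):
        part = small_bank.atoms[3].part
        decs = [self._dec(small_bank, [MPEntry(3, part, 0, 0, 0.5)]),
                self._dec(small_bank, [MPEntry(3, part, 2, 0, 0.25)])]
        table = sk.atom_importance(decs, small_bank)
        assert table.eta[3] == pytest.approx(0.75)
        assert table.eta[[i for i in range(len(small_bank.atoms)) if i != 3]].sum() == 0

    def test_empty_input_all_zero(self, small_bank):
        table = sk.atom_importance([], small_bank)
        assert np.all(table.eta == 0.0)
        assert set(table.to_frame().columns) >= {"atom_id", "omega_t", "omega_s", "eta"}

    def test_atom_count_histogram(self, small_bank):
        part = small_bank.atoms[0].part
        decs = [self._dec(small_bank, [MPEntry(0, part, 0, 0, 1.0)]),
                self._dec(small_bank, [MPEntry(0, part, 0, 0, 1.0)]),
                self._dec(small_bank, [MPEntry(0, part, 0, 0, 1.0)] * 2)]
        assert sk.atom_count_histogram(decs) == {1: 2, 2: 1}
        assert sk.atom_count_histogram([]) == {}

    def test_dictionary_targets_need_one_atom_at_theta_08(self, small_bank):
        targets = [small_bank.atoms[i].patch * 1.3 for i in (0, 4, 8)]
        decs = [sk.mp_decompose(t, small_bank, theta=0.8) for t in targets]
        assert sk.atom_count_histogram(decs) == {1: 3}

    def test_kappa_vs_theta_separable_targets_stay_at_one(self, small_bank):
        rng = np.random.default_rng(5)
        axis_ids = [i for i, a in enumerate(small_bank.atoms)
                    if (a.omega_t == 0) != (a.omega_s == 0)]
        targets = [sum(rng.uniform(0.5, 2.0) * small_bank.atoms[i].patch
                       for i in rng.choice(axis_ids, 2, replace=False))
                   for _ in range(4)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            curve = sk.kappa_vs_theta(targets, small_bank, [0.7, 0.8, 0.9])
        np.testing.assert_allclose(curve["kappa"], 1.0, atol=1e-9)

    def test_single_theta_matches_direct_decomposition(self, small_bank, rng):
        target = small_bank.atoms[1].patch + 0.3 * small_bank.atoms[6].patch
        curve = sk.kappa_vs_theta([target], small_bank, [0.85])
        dec = sk.mp_decompose(target, small_bank, theta=0.85)
        assert curve["kappa"].iloc[0] == pytest.approx(sk.kappa_decomposition(dec))

    def test_nonincreasing_theta_grid_rejected(self, small_bank, rng):
        with pytest.raises(ValueError):
            sk.kappa_vs_theta([small_bank.atoms[0].patch], small_bank, [0.9, 0.8])
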