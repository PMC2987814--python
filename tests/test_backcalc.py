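"""S2, Karplus couplings, shift averaging and RDC tensor fits."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import tiny_ensemble
from ensval.backcalc import (
    DEFAULT_KARPLUS,
    KarplusCoefficients,
    SaupeTensor,
    dipolar_constant,
    ensemble_couplings,
    ensemble_rdc,
    ensemble_shifts,
    karplus_coupling,
    rdc_from_tensor,
    s2_from_vectors,
    s2_order_parameters,
    svd_fit_rdc,
)
from ensval.core import ParameterRecord, ParameterSet
from ensval.fixtures import FixtureSpec, build_peptide_ensemble


def _nh_ensemble(vectors):
    """One N-H bond per conformer from the supplied (unit) vectors."""
    frames = [np.array([[0.0, 0.0, 0.0], np.asarray(v, dtype=float)]) for v in vectors]
    return tiny_ensemble(frames, names=["N", "H"], resids=[2, 2], resnames=["ALA", "ALA"])


class TestOrderParameters:
    def test_identical_conformers_give_one(self):
        ens = _nh_ensemble([[1, 0, 0]] * 5)
        result = s2_order_parameters(ens, "N-H")
        assert result.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_orientations_at_ninety_degrees(self):
        """Closed form for a two-orientation ensemble: S2 = (3cos^2(t)+1)/4."""
        ens = _nh_ensemble([[1, 0, 0], [0, 1, 0]])
        result = s2_order_parameters(ens, "N-H")
        assert result.values[0] == pytest.approx(0.25, abs=1e-9)
        # independent dyadic-sum oracle
        mus = np.array([[1, 0, 0], [0, 1, 0]], dtype=float)
        dyad = sum(np.outer(m, m) for m in mus) / 2
        assert result.values[0] == pytest.approx(1.5 * (dyad**2).sum() - 0.5, abs=1e-12)

    def test_isotropic_limit(self):
        rng = np.random.default_rng(42)
        v = rng.normal(size=(10_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert s2_from_vectors(v) < 0.02

    def test_invariant_under_common_rotation_only(self):
        spec = FixtureSpec(seed=5, n_conformers=6)
        ens = build_peptide_ensemble(spec)
        base = s2_order_parameters(ens, "N-H")
        common = Rotation.from_rotvec([0.3, -0.8, 0.5])
        rotated = ens.with_coords(np.array([common.apply(c) for c in ens.coords]))
        same = s2_order_parameters(rotated, "N-H")
        assert np.allclose(base.values, same.values, atol=1e-9)
        # per-conformer rotations change S2 (it is not fit-invariant)
        rng = np.random.default_rng(0)
        scrambled = ens.with_coords(
            np.array([Rotation.from_rotvec(rng.normal(scale=1.0, size=3)).apply(c) for c in ens.coords])
        )
        assert not np.allclose(base.values, s2_order_parameters(scrambled, "N-H").values, atol=1e-3)

    def test_proline_and_missing_atoms_skipped(self):
        spec = FixtureSpec(sequence="AAPAA", seed=1, n_conformers=3)
        ens = build_peptide_ensemble(spec)
        result = s2_order_parameters(ens, "N-H")
        assert 3 not in result.resids  # proline has no amide proton


class TestKarplus:
    def test_pure_cosine_square_term(self):
        c = KarplusCoefficients("x", 1.0, 0.0, 0.0, 0.0)
        assert karplus_coupling(0.0, c) == pytest.approx(1.0)

    def test_constant_term(self):
        c = KarplusCoefficients("x", 0.0, 0.0, 3.3, 0.0)
        for phi in (-150.0, 0.0, 77.0):
            assert karplus_coupling(phi, c) == pytest.approx(3.3)

    def test_generic_value_matches_trig_oracle(self):
        c = DEFAULT_KARPLUS["3J_HNHA"]
        phi = -60.0
        theta = np.radians(phi + c.delta)
        oracle = c.A * np.cos(theta) ** 2 + c.B * np.cos(theta) + c.C
        assert karplus_coupling(phi, c) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("phi", [-170.0, -60.0, 45.0, 120.0])
    def test_periodicity(self, phi):
        c = DEFAULT_KARPLUS["3J_HNC'"]
        assert karplus_coupling(phi, c) == pytest.approx(karplus_coupling(phi + 360.0, c), abs=1e-9)


class TestEnsembleCouplings:
    def test_identical_conformers_equal_single_conformer(self):
        spec = FixtureSpec(seed=2, n_conformers=4, rotation_mode="none")
        ens = build_peptide_ensemble(spec)
        results = {r.subtype: r for r in ensemble_couplings(ens)}
        assert set(results) == set(DEFAULT_KARPLUS)
        r = results["3J_HNHA"]
        assert np.allclose(r.per_conformer, r.per_conformer[0])

    def test_average_matches_per_conformer_oracle(self):
        rng = np.random.default_rng(3)
        phis = [list(rng.uniform(-180, 0, size=6)) for _ in range(5)]
        psis = [list(rng.uniform(-90, 170, size=6)) for _ in range(5)]
        spec = FixtureSpec(sequence="ARNDLE", n_conformers=5, phi=phis, psi=psis,
                           rotation_mode="none", seed=0)
        ens = build_peptide_ensemble(spec)
        from ensval.geometry import phi_dihedral

        result = {r.subtype: r for r in ensemble_couplings(ens)}["3J_HNHA"]
        coeff = DEFAULT_KARPLUS["3J_HNHA"]
        for col, resid in enumerate(result.resids):
            oracle = np.mean(
                [karplus_coupling(phi_dihedral(conf, resid), coeff) for conf in ens]
            )
            assert result.values[col] == pytest.approx(oracle, abs=1e-12)

    def test_duplicating_a_conformer_set_leaves_mean_unchanged(self):
        spec = FixtureSpec(seed=4, n_conformers=3)
        ens = build_peptide_ensemble(spec)
        doubled = ens.with_coords(np.concatenate([ens.coords, ens.coords]))
        a = {r.subtype: r.values for r in ensemble_couplings(ens)}
        b = {r.subtype: r.values for r in ensemble_couplings(doubled)}
        for key in a:
            assert np.allclose(a[key], b[key], atol=1e-12)


class TestEnsembleShifts:
    def test_two_conformer_average(self, peptide_ensemble):
        calls = {"n": 0}

        def predictor(conformer):
            calls["n"] += 1
            value = 1.0 if calls["n"] % 2 else 3.0
            return [(2, "CA", value)]

        two = peptide_ensemble.with_coords(peptide_ensemble.coords[:2])
        (result,) = ensemble_shifts(two, predictor)
        assert result.values[0] == pytest.approx(2.0)

    def test_glycine_protons_averaged_before_ensemble_mean(self):
        def predictor(conformer):
            return [(5, "HA2", 4.0), (5, "HA3", 3.0), (5, "CA", 45.0)]

        spec = FixtureSpec(seed=0, n_conformers=2)
        ens = build_peptide_ensemble(spec)
        results = {r.subtype: r for r in ensemble_shifts(ens, predictor)}
        assert results["HA"].values[0] == pytest.approx(3.5)

    def test_builtin_predictor_covers_supported_nuclei(self, peptide_ensemble):
        results = {r.subtype for r in ensemble_shifts(peptide_ensemble)}
        assert results == {"CA", "CB", "HA", "H", "N"}

    def test_predictor_failure_aborts_with_model_id(self, peptide_ensemble):
        from ensval.backcalc import ExternalToolError

        def predictor(conformer):
            raise RuntimeError("boom")

        with pytest.raises(ExternalToolError, match="model 1"):
            ensemble_shifts(peptide_ensemble, predictor)


def _rdc_observations(ensemble, tensor, pairs=(("N", "H"), ("CA", "HA"))):
    records = []
    conf = ensemble[0]
    for pair in pairs:
        dmax = dipolar_constant(*pair)
        for _, row in ensemble.residues().iterrows():
            resid = int(row["resid"])
            try:
                i = ensemble.atom_index(resid, pair[0])
                j = ensemble.atom_index(resid, pair[1])
            except KeyError:
                continue
            mu = conf.coords[j] - conf.coords[i]
            mu /= np.linalg.norm(mu)
            records.append(ParameterRecord(resid, pair, rdc_from_tensor(mu, tensor, dmax)))
    return ParameterSet("rdc", "N-H", records, unit="Hz")


class TestRdc:
    tensor = SaupeTensor(3e-4, -1e-4, 2e-4, -2e-4, 1e-4)

    def test_tensor_recovered_from_noise_free_data(self):
        spec = FixtureSpec(seed=6, n_conformers=1, rotation_mode="none")
        ens = build_peptide_ensemble(spec)
        obs = _rdc_observations(ens, self.tensor)
        fitted, calc = svd_fit_rdc(ens[0], obs)
        assert np.allclose(fitted.matrix, self.tensor.matrix, atol=1e-8)
        residual = [calc[(r.resid, r.atoms)] - r.value for r in obs.records]
        assert np.allclose(residual, 0.0, atol=1e-8)

    def test_fit_is_least_squares_optimal(self):
        """No perturbed tensor may beat the SVD solution's residual."""
        spec = FixtureSpec(seed=8, n_conformers=1, rotation_mode="none")
        ens = build_peptide_ensemble(spec)
        obs = _rdc_observations(ens, self.tensor)
        noisy = ParameterSet(
            "rdc", "N-H",
            [ParameterRecord(r.resid, r.atoms, r.value + 0.5 * np.sin(float(k)))
             for k, r in enumerate(obs.records)],
        )
        conf = ens[0]
        fitted, _ = svd_fit_rdc(conf, noisy)

        def ssr(tensor):
            total = 0.0
            for rec in noisy.records:
                i = ens.atom_index(rec.resid, rec.atoms[0])
                j = ens.atom_index(rec.resid, rec.atoms[1])
                mu = conf.coords[j] - conf.coords[i]
                mu /= np.linalg.norm(mu)
                calc = rdc_from_tensor(mu, tensor, dipolar_constant(*rec.atoms))
                total += (calc - rec.value) ** 2
            return total

        best = ssr(fitted)
        base = np.array([fitted.sxx, fitted.syy, fitted.sxy, fitted.sxz, fitted.syz])
        for k in range(5):
            for sign in (-1, 1):
                perturbed = base.copy()
                perturbed[k] += sign * 2e-5
                assert ssr(SaupeTensor(*perturbed)) >= best - 1e-12

    def test_all_zero_observations_give_zero_tensor(self):
        spec = FixtureSpec(seed=9, n_conformers=1, rotation_mode="none")
        ens = build_peptide_ensemble(spec)
        obs = _rdc_observations(ens, SaupeTensor(0, 0, 0, 0, 0))
        fitted, calc = svd_fit_rdc(ens[0], obs)
        assert np.allclose(fitted.matrix, 0.0, atol=1e-15)
        assert all(abs(v) < 1e-12 for v in calc.values())

    def test_fewer_than_five_observations_rejected(self):
        spec = FixtureSpec(seed=9, n_conformers=1, rotation_mode="none")
        ens = build_peptide_ensemble(spec)
        obs = _rdc_observations(ens, self.tensor)
        short = ParameterSet("rdc", "N-H", obs.records[:4])
        with pytest.raises(ValueError, match="5"):
            svd_fit_rdc(ens[0], short)

    def test_identical_conformers_equal_single_fit(self):
        spec = FixtureSpec(seed=10, n_conformers=3, rotation_mode="none")
        ens = build_peptide_ensemble(spec)
        obs = _rdc_observations(ens, self.tensor)
        result = ensemble_rdc(ens, obs, mode="svd")
        _, single = svd_fit_rdc(ens[0], obs)
        for key, value in zip(sorted(single), result.values):
            assert value == pytest.approx(single[key], abs=1e-10)

    def test_external_mode_without_tool_is_a_config_error(self, peptide_ensemble):
        from ensval.backcalc import ExternalToolError

        obs = _rdc_observations(peptide_ensemble, self.tensor)
        with pytest.raises(ExternalToolError):
            ensemble_rdc(peptide_ensemble, obs, mode="external_steric")
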