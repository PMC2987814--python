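"""Distance averaging, dihedrals and superposition."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import tiny_ensemble
from ensval.core import AtomSelector, DistanceRestraint
from ensval.geometry import (
    UnresolvableSelectorError,
    dihedral,
    effective_distance,
    ensemble_effective_distance,
    mean_pairwise_rmsd,
    phi_dihedral,
    restraint_distance_in_conformer,
    superpose,
)

distance_lists = st.lists(
    st.floats(min_value=0.5, max_value=25.0, allow_nan=False), min_size=1, max_size=12
)


class TestEffectiveDistance:
    def test_equal_distances_are_identity(self):
        assert effective_distance([4.2, 4.2, 4.2], 6) == pytest.approx(4.2)
        assert effective_distance([4.2], 3) == pytest.approx(4.2)

    def test_against_direct_arithmetic_oracle(self):
        expected = ((2.0**-6 + 4.0**-6) / 2) ** (-1 / 6)
        assert effective_distance([2.0, 4.0], 6) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [[], [0.0, 1.0], [-1.0]])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            effective_distance(bad, 6)

    def test_exponent_validation(self):
        with pytest.raises(ValueError):
            effective_distance([1.0], 2)

    @settings(derandomize=True, max_examples=200)
    @given(distance_lists)
    def test_generalized_mean_ordering(self, distances):
        """r^-6 averaging never exceeds r^-3, which never exceeds the mean."""
        d6 = effective_distance(distances, 6)
        d3 = effective_distance(distances, 3)
        assert d6 <= d3 + 1e-9
        assert d3 <= np.mean(distances) + 1e-9
        assert min(distances) - 1e-9 <= d6 <= max(distances) + 1e-9

    def test_ensemble_mode_r3_matches_oracle(self):
        values = [6.82, 6.80, 6.82, 6.67, 6.75, 6.85, 6.83, 6.43, 5.90, 6.91]
        oracle = (np.mean([v**-3 for v in values])) ** (-1 / 3)
        assert ensemble_effective_distance(values, "r3") == pytest.approx(oracle, abs=1e-12)
        with pytest.raises(ValueError):
            ensemble_effective_distance(values, "r4")


class TestRestraintDistance:
    def test_single_pair_is_euclidean(self):
        ens = tiny_ensemble(
            [[[0, 0, 0], [3, 0, 0]]], names=["HA", "H"], resids=[1, 2]
        )
        r = DistanceRestraint(AtomSelector.single(1, "HA"), AtomSelector.single(2, "H"), 3.0, 0.5, 0.5)
        assert restraint_distance_in_conformer(ens[0], r) == pytest.approx(3.0)

    def test_equidistant_methyl_group(self):
        # three methyl protons all 4 A from the partner: pooling changes nothing
        ens = tiny_ensemble(
            [[[4, 0, 0], [0, 4, 0], [0, 0, 4], [0, 0, 0]]],
            names=["HD11", "HD12", "HD13", "H"],
            resids=[1, 1, 1, 2],
        )
        r = DistanceRestraint(AtomSelector.single(1, "HD1#"), AtomSelector.single(2, "H"), 4.0, 1.0, 1.0)
        assert restraint_distance_in_conformer(ens[0], r) == pytest.approx(4.0)

    def test_two_pair_pooling_matches_printed_convention(self):
        # 6.35 and 7.73 A pool to 6.82 A under r^-6 weighting
        ens = tiny_ensemble(
            [[[0, 0, 0], [6.35, 0, 0], [7.73, 0, 0]]],
            names=["HA", "HB2", "HB3"],
            resids=[1, 2, 2],
        )
        r = DistanceRestraint(AtomSelector.single(1, "HA"), AtomSelector.single(2, "HB#"), 6.0, 1.0, 1.0)
        assert restraint_distance_in_conformer(ens[0], r) == pytest.approx(6.816, abs=5e-3)

    def test_unresolvable_selector_raises(self):
        ens = tiny_ensemble([[[0, 0, 0]]], names=["HA"], resids=[1])
        r = DistanceRestraint(AtomSelector.single(1, "HA"), AtomSelector.single(9, "H"), 3.0, 0.5, 0.5)
        with pytest.raises(UnresolvableSelectorError):
            restraint_distance_in_conformer(ens[0], r)


def _rotation(axis, degrees):
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.radians(degrees) * np.asarray(axis) / np.linalg.norm(axis))


class TestPhiDihedral:
    def test_trans_arrangement_is_180(self):
        p = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]
        assert abs(dihedral(*p)) == pytest.approx(180.0)

    def test_mirrored_conformer_negates_phi(self, peptide_ensemble):
        conf = peptide_ensemble[0]
        mirrored = tiny_ensemble(
            [conf.coords * np.array([1, 1, -1])],
            names=list(conf.atom_table["name"]),
            resids=list(conf.atom_table["resid"]),
            resnames=list(conf.atom_table["resname"]),
        )
        for resid in (3, 8):
            assert phi_dihedral(mirrored[0], resid) == pytest.approx(
                -phi_dihedral(conf, resid), abs=1e-9
            )

    def test_first_residue_is_undefined(self, peptide_ensemble):
        with pytest.raises(KeyError):
            phi_dihedral(peptide_ensemble[0], 1)

    def test_invariant_under_rigid_motion(self, peptide_ensemble):
        conf = peptide_ensemble[0]
        rot = _rotation([1, 2, 3], 77.0)
        moved = tiny_ensemble(
            [rot.apply(conf.coords) + np.array([5.0, -3.0, 2.0])],
            names=list(conf.atom_table["name"]),
            resids=list(conf.atom_table["resid"]),
            resnames=list(conf.atom_table["resname"]),
        )
        assert phi_dihedral(moved[0], 5) == pytest.approx(phi_dihedral(conf, 5), abs=1e-9)


class TestSuperpose:
    def _backbone_ensemble(self, n_res=5, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=3.0, size=(n_res * 3, 3))
        names = ["N", "CA", "C"] * n_res
        resids = [i // 3 + 1 for i in range(n_res * 3)]
        return tiny_ensemble([coords], names=names, resids=resids)

    def test_rigid_motion_gives_zero_rmsd(self):
        ens = self._backbone_ensemble()
        ref = ens[0]
        rot = _rotation([0, 0, 1], 90.0)
        moved = tiny_ensemble(
            [rot.apply(ref.coords) + 7.0],
            names=list(ref.atom_table["name"]),
            resids=list(ref.atom_table["resid"]),
        )
        _, rmsd = superpose(ref, moved[0])
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_closed_form(self):
        # all atoms identical except one moved 1 A: after optimal fit the
        # RMSD cannot exceed the un-fitted value 1/sqrt(N) and the un-fitted
        # value is exactly that
        ens = self._backbone_ensemble(n_res=4)
        ref = ens[0]
        shifted = ref.coords.copy()
        shifted[0] += [1.0, 0, 0]
        n = len(shifted)
        unfitted = np.sqrt(np.mean(np.sum((shifted - ref.coords) ** 2, axis=1)))
        assert unfitted == pytest.approx(1 / np.sqrt(n))
        moved = tiny_ensemble([shifted], names=list(ref.atom_table["name"]),
                              resids=list(ref.atom_table["resid"]))
        _, rmsd = superpose(ref, moved[0])
        assert rmsd <= unfitted + 1e-12
        assert rmsd == pytest.approx(unfitted, rel=0.2)

    def test_rmsd_symmetry(self):
        a = self._backbone_ensemble(seed=1)[0]
        b_coords = a.coords + np.random.default_rng(2).normal(scale=0.3, size=a.coords.shape)
        b = tiny_ensemble([b_coords], names=list(a.atom_table["name"]),
                          resids=list(a.atom_table["resid"]))[0]
        assert superpose(a, b)[1] == pytest.approx(superpose(b, a)[1], abs=1e-9)

    def test_collinear_geometry_rejected(self):
        coords = np.array([[i, 0.0, 0.0] for i in range(6)])
        ens = tiny_ensemble([coords], names=["N", "CA", "C"] * 2, resids=[1, 1, 1, 2, 2, 2])
        with pytest.raises(ValueError):
            superpose(ens[0], ens[0])


class TestMeanPairwiseRmsd:
    def test_identical_conformers_give_zero(self, default_spec):
        from ensval.fixtures import FixtureSpec, build_peptide_ensemble

        spec = FixtureSpec(sequence=default_spec.sequence, n_conformers=3,
                           rotation_mode="none", seed=0)
        ens = build_peptide_ensemble(spec)
        mean, sd = mean_pairwise_rmsd(ens)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_matches_directly_computed_pair_values(self, peptide_ensemble):
        import itertools

        sub = peptide_ensemble.with_coords(peptide_ensemble.coords[:4])
        mean, sd = mean_pairwise_rmsd(sub)
        pairs = [
            superpose(sub[i], sub[j])[1]
            for i, j in itertools.combinations(range(4), 2)
        ]
        assert mean == pytest.approx(np.mean(pairs))
        assert sd == pytest.approx(np.std(pairs, ddof=1))

    def test_needs_two_conformers(self, peptide_ensemble):
        single = peptide_ensemble.with_coords(peptide_ensemble.coords[:1])
        with pytest.raises(ValueError):
            mean_pairwise_rmsd(single)
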