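"""Deterministic synthetic ensembles and observables with known ground truth.

The generator builds ideal-geometry peptide backbones (fixed bond lengths
and angles, user-supplied phi/psi torsions, protons placed by ideal
geometry) and synthesizes every supported observable from the generated
coordinates: S2 from the exact dyadic formula on the bond vectors,
couplings from the Karplus configuration on the realized phi angles, RDCs
from a prescribed alignment tensor, shifts from the built-in predictor and
distance restraints from realized inter-proton distances.  With zero noise
the full evaluation pipeline must reproduce the synthesis inputs exactly;
that closed loop is the module's purpose.

Two ensemble-variation modes are supported: per-conformer torsion lists
(internal flexibility) and rigid per-conformer rotations of a single
geometry (orientational scatter, which controls the target S2).  The
rigid-rotation mode is the one under which per-conformer SVD alignment
fitting is exactly self-consistent, so it is the default for end-to-end
pipeline checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .backcalc import (
    DEFAULT_KARPLUS,
    SaupeTensor,
    dipolar_constant,
    ensemble_couplings,
    ensemble_shifts,
    rdc_from_tensor,
    s2_order_parameters,
)
from .core import AtomSelector, DistanceRestraint, Ensemble
from .geometry import effective_distance

__all__ = ["FixtureSpec", "SyntheticData", "build_peptide_ensemble", "synthesize_observables"]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# ideal backbone geometry (Angstrom / degrees), standard values
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_N_H, _B_CA_HA, _B_CA_CB, _B_C_O = 1.01, 1.09, 1.53, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_N_H, _A_N_CA_HA, _A_N_CA_CB, _A_CA_C_O = 118.2, 108.9, 110.5, 120.8


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from reference frame (a, b, c): |c-D| = bond,
    angle(b, c, D) = ``angle`` deg, torsion(a, b, c, D) = ``torsion`` deg."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class FixtureSpec:
    """Specification of a synthetic ensemble and its observables.

    ``phi``/``psi`` may be a single per-residue list (shared geometry; the
    first phi and the torsions of absent neighbours are ignored where
    undefined) or one list per conformer.  Rigid per-conformer rotations
    lower S2 without touching internal geometry; two modes exist:

    * ``axis_aligned`` (default): a seeded draw from the 24 proper
      axis-permutation rotations.  These are exact at PDB coordinate
      precision, so every observable survives the write/read round trip
      bit-exactly — the mode used for closed-loop pipeline checks.
    * ``random``: continuous seeded rotations with axis-angle magnitude
      ``rotation_scatter`` (radians), the dial that controls the target
      S2 level.

    Noise standard deviations are per observable kind, in the
    observable's own units.
    """

    sequence: str = "MQIFVKTLTGKE"
    n_conformers: int = 10
    phi: list = field(default_factory=list)   # degrees
    psi: list = field(default_factory=list)   # degrees
    rotation_mode: str = "axis_aligned"
    rotation_scatter: float = 0.35
    alignment_tensor: SaupeTensor = field(
        default_factory=lambda: SaupeTensor(4e-4, -1.5e-4, 2e-4, -1e-4, 3e-4)
    )
    noise: dict = field(default_factory=dict)  # kind -> sd
    restraint_margin: float = 0.5  # Angstrom, both directions
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError("sequence must have at least 3 residues")
        n = len(self.sequence)
        if not self.phi:
            # mixed secondary structure: helical N-half, extended C-half
            half = n // 2
            self.phi = [-60.0] * half + [-120.0] * (n - half)
            self.psi = [-45.0] * half + [130.0] * (n - half)
        if not isinstance(self.phi[0], (list, tuple, np.ndarray)):
            self.phi = [list(self.phi)] * self.n_conformers
            self.psi = [list(self.psi)] * self.n_conformers
        if len(self.phi) != self.n_conformers or len(self.psi) != self.n_conformers:
            raise ValueError("need one phi/psi list per conformer")
        for p, s in zip(self.phi, self.psi):
            if len(p) != n or len(s) != n:
                raise ValueError("torsion lists must match the sequence length")
        if self.rotation_mode not in ("axis_aligned", "random", "none"):
            raise ValueError(f"unknown rotation mode {self.rotation_mode!r}")
        if self.rotation_mode == "axis_aligned" and self.n_conformers > 24:
            raise ValueError(
                "axis_aligned mode supports at most 24 conformers; use rotation_mode='random'"
            )


def _build_conformer(sequence: str, phi: list[float], psi: list[float]) -> tuple[list[tuple], np.ndarray]:
    """One ideal-geometry conformer; returns (atom rows, coordinates)."""
    n = len(sequence)
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    N[0] = np.zeros(3)
    CA[0] = np.array([_B_N_CA, 0.0, 0.0])
    theta = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(1, n):
        N[i] = nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])

    rows: list[tuple] = []
    coords: list[np.ndarray] = []

    def add(resid: int, resname: str, name: str, pos: np.ndarray) -> None:
        rows.append(("A", resid, resname, name))
        coords.append(pos)

    for i, letter in enumerate(sequence):
        resname = _AA3[letter.upper()]
        resid = i + 1
        add(resid, resname, "N", N[i])
        if resname != "PRO":
            if i == 0:
                add(resid, resname, "H", nerf(C[0], CA[0], N[0], _B_N_H, _A_CA_N_H, 180.0))
            else:
                add(resid, resname, "H", nerf(C[i], CA[i], N[i], _B_N_H, _A_CA_N_H, phi[i] + 180.0))
        add(resid, resname, "CA", CA[i])
        # side-chain branch positions off CA, L-configuration
        if i == 0:
            ref = (C[0] + np.array([0.0, 0.0, 1.0]), N[0], CA[0])
            tau_cb, tau_ha = 122.5, -118.5
        else:
            ref = (C[i - 1], N[i], CA[i])
            tau_cb, tau_ha = phi[i] + 122.5, phi[i] - 118.5
        if resname == "GLY":
            add(resid, resname, "HA2", nerf(*ref, _B_CA_HA, _A_N_CA_CB, tau_cb))
            add(resid, resname, "HA3", nerf(*ref, _B_CA_HA, _A_N_CA_HA, tau_ha))
        else:
            add(resid, resname, "CB", nerf(*ref, _B_CA_CB, _A_N_CA_CB, tau_cb))
            add(resid, resname, "HA", nerf(*ref, _B_CA_HA, _A_N_CA_HA, tau_ha))
        add(resid, resname, "C", C[i])
        add(resid, resname, "O", nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0))
    return rows, np.array(coords)


def build_peptide_ensemble(spec: FixtureSpec) -> Ensemble:
    """Build the synthetic ensemble described by ``spec``.

    Torsion variation and the seeded rigid rotations compose; with shared
    torsions and ``rotation_scatter`` of 0 all conformers coincide.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.rotation_mode == "axis_aligned":
        # exact signed-permutation matrices; stable under coordinate rounding
        group = Rotation.create_group("O").as_matrix().round()
        matrices = group[rng.permutation(len(group))[: spec.n_conformers]]
    rows0 = None
    frames = []
    for conf in range(spec.n_conformers):
        rows, coords = _build_conformer(spec.sequence, spec.phi[conf], spec.psi[conf])
        if rows0 is None:
            rows0 = rows
        elif rows != rows0:
            raise ValueError("conformers produced differing atom tables")
        centered = coords - coords.mean(axis=0)
        if spec.rotation_mode == "axis_aligned":
            coords = centered @ matrices[conf].T
        elif spec.rotation_mode == "random" and spec.rotation_scatter > 0:
            rotvec = rng.normal(0.0, spec.rotation_scatter, size=3)
            coords = Rotation.from_rotvec(rotvec).apply(centered)
        frames.append(coords)
    atom_table = pd.DataFrame(rows0, columns=["chain", "resid", "resname", "name"])
    return Ensemble(atom_table, np.array(frames), source_id="synthetic")


@dataclass
class SyntheticData:
    """Generator output: input texts plus the exact ground-truth values."""

    pdb_text: str
    restraint_text: str
    star_text: str
    truth: dict  # (kind, subtype) -> {resid: value}


def _noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    return rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)


def synthesize_observables(ensemble: Ensemble, spec: FixtureSpec) -> SyntheticData:
    """Synthesize NMR-STAR and X-PLOR restraint text for ``ensemble``.

    All values derive from the generated coordinates through the same
    physical conventions the evaluators use (exact self-consistency at
    zero noise); Gaussian noise, when requested, is seeded from the spec.
    """
    from .report import write_multi_model_pdb  # deferred: report imports core only

    # Quantize to PDB coordinate precision (0.001 A) up front so the
    # ground truth matches what a consumer reads back from the file.
    ensemble = ensemble.with_coords(np.round(ensemble.coords, 3))

    rng = np.random.default_rng(spec.seed + 1)
    truth: dict = {}
    star: list[str] = ["data_synthetic_observables", ""]

    # S2 order parameters (exact ensemble property of the bond vectors)
    s2_rows: list[str] = []
    for kind, atom in (("N-H", "H"), ("CA-HA", "HA")):
        result = s2_order_parameters(ensemble, kind)
        noisy = result.values + _noise(rng, spec.noise.get("s2", 0.0), len(result.values))
        truth[("s2", kind)] = dict(zip(result.resids, noisy))
        s2_rows += [
            f"  {resid} {atom} {value:.17g}"
            for resid, value in zip(result.resids, noisy)
        ]
    star += ["loop_", "  _Residue_seq_code", "  _Atom_name", "  _S2_value", *s2_rows, "stop_", ""]

    # chemical shifts via the built-in predictor (glycine emits HA2/HA3)
    shift_rows: list[str] = []
    for result in ensemble_shifts(ensemble):
        sd = spec.noise.get("chemical_shift", 0.0)
        noisy = result.values + _noise(rng, sd, len(result.values))
        truth[("chemical_shift", result.subtype)] = dict(zip(result.resids, noisy))
        gly = set(
            ensemble.atom_table.loc[ensemble.atom_table["resname"] == "GLY", "resid"]
        )
        for resid, value in zip(result.resids, noisy):
            if result.subtype == "HA" and resid in gly:
                # archive files carry the two glycine protons separately
                shift_rows.append(f"  {resid} HA2 {value:.17g}")
                shift_rows.append(f"  {resid} HA3 {value:.17g}")
            else:
                shift_rows.append(f"  {resid} {result.subtype} {value:.17g}")
    star += ["loop_", "  _Residue_seq_code", "  _Atom_name", "  _Chem_shift_value",
             *shift_rows, "stop_", ""]

    # RDCs from the prescribed alignment tensor, per conformer then averaged
    rdc_rows: list[str] = []
    for pair in (("N", "H"), ("CA", "HA")):
        dmax = dipolar_constant(*pair)
        resids: list[int] = []
        for _, row in ensemble.residues().iterrows():
            try:
                i = ensemble.atom_index(int(row["resid"]), pair[0])
                j = ensemble.atom_index(int(row["resid"]), pair[1])
            except KeyError:
                continue
            resids.append(int(row["resid"]))
        values = []
        for resid in resids:
            i = ensemble.atom_index(resid, pair[0])
            j = ensemble.atom_index(resid, pair[1])
            vec = ensemble.coords[:, j, :] - ensemble.coords[:, i, :]
            vec /= np.linalg.norm(vec, axis=1, keepdims=True)
            values.append(
                np.mean([rdc_from_tensor(v, spec.alignment_tensor, dmax) for v in vec])
            )
        noisy = np.array(values) + _noise(rng, spec.noise.get("rdc", 0.0), len(values))
        truth[("rdc", f"{pair[0]}-{pair[1]}")] = dict(zip(resids, noisy))
        rdc_rows += [
            f"  {resid} {pair[0]} {resid} {pair[1]} {value:.17g}"
            for resid, value in zip(resids, noisy)
        ]
    star += ["loop_", "  _Atom_one_residue_seq_code", "  _Atom_one_atom_name",
             "  _Atom_two_residue_seq_code", "  _Atom_two_atom_name",
             "  _Residual_dipolar_coupling_value", *rdc_rows, "stop_", ""]

    # J couplings from the Karplus configuration on the realized phi angles
    j_rows: list[str] = []
    code_of = {"3J_HNHA": "3JHNHA", "3J_HAC'": "3JHAC", "3J_HNCB": "3JHNCB", "3J_HNC'": "3JHNC"}
    for result in ensemble_couplings(ensemble, DEFAULT_KARPLUS):
        sd = spec.noise.get("jcoupling", 0.0)
        noisy = result.values + _noise(rng, sd, len(result.values))
        truth[("jcoupling", result.subtype)] = dict(zip(result.resids, noisy))
        j_rows += [
            f"  {code_of[result.subtype]} {resid} {value:.17g}"
            for resid, value in zip(result.resids, noisy)
        ]
    star += ["loop_", "  _Coupling_constant_code", "  _Atom_one_residue_seq_code",
             "  _Coupling_constant_value", *j_rows, "stop_", ""]

    # distance restraints at the realized ensemble-averaged distances
    restraints: list[str] = []
    protons = [
        (int(r["resid"]), r["name"])
        for _, r in ensemble.atom_table.iterrows()
        if r["name"] in ("H", "HA", "HA2")
    ]
    rid = 0
    for a in range(len(protons)):
        for b in range(a + 1, len(protons)):
            (ri, ni), (rj, nj) = protons[a], protons[b]
            sep = abs(ri - rj)
            if sep < 1 or sep > 8 or (sep > 4 and (ri + rj) % 3):
                continue
            i = ensemble.atom_index(ri, ni)
            j = ensemble.atom_index(rj, nj)
            dists = np.linalg.norm(ensemble.coords[:, i, :] - ensemble.coords[:, j, :], axis=1)
            d_eff = effective_distance(dists, 6)
            if d_eff > 9.0:
                continue
            d_noisy = d_eff + float(_noise(rng, spec.noise.get("restraint", 0.0), 1)[0])
            rid += 1
            restraints.append(
                DistanceRestraint(
                    AtomSelector.single(ri, ni), AtomSelector.single(rj, nj),
                    d=round(d_noisy, 3), dminus=spec.restraint_margin,
                    dplus=spec.restraint_margin, restraint_id=rid,
                ).to_xplor()
            )
    return SyntheticData(
        pdb_text=write_multi_model_pdb(ensemble),
        restraint_text="\n".join(restraints) + "\n",
        star_text="\n".join(star) + "\n",
        truth=truth,
    )
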