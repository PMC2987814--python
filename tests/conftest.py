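"""Shared fixtures: small synthetic ensembles and input files.

Everything is generated programmatically at test time; expensive fixtures
are session-scoped so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ensval.core import Ensemble
from ensval.fixtures import FixtureSpec, build_peptide_ensemble, synthesize_observables


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def peptide_ensemble(default_spec) -> Ensemble:
    return build_peptide_ensemble(default_spec)


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory, default_spec, peptide_ensemble):
    """Zero-noise fixture data written out as the three standard files."""
    data = synthesize_observables(peptide_ensemble, default_spec)
    root = tmp_path_factory.mktemp("synthetic")
    (root / "ensemble.pdb").write_text(data.pdb_text)
    (root / "restraints.tbl").write_text(data.restraint_text)
    (root / "parameters.str").write_text(data.star_text)
    return root, data


def tiny_ensemble(coords_per_model, names=None, resids=None, resnames=None) -> Ensemble:
    """Hand-built ensemble helper for geometry-level tests."""
    coords = np.asarray(coords_per_model, dtype=float)
    n_atoms = coords.shape[1]
    names = names or [f"X{i}" for i in range(n_atoms)]
    resids = resids or [1] * n_atoms
    resnames = resnames or ["ALA"] * n_atoms
    table = pd.DataFrame(
        {"chain": ["A"] * n_atoms, "resid": resids, "resname": resnames, "name": names}
    )
    return Ensemble(table, coords)
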