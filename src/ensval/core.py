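"""Domain types shared across the package.

An :class:`Ensemble` is an ordered set of conformers (models) of one
molecule sharing a single harmonized atom table.  Experimental data are
held in :class:`ParameterSet` objects keyed by residue (and atom names
where the observable is bond-specific), and NOE-derived distance bounds
in :class:`DistanceRestraint` objects whose sides are X-PLOR-style atom
selectors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Ensemble",
    "Conformer",
    "AtomSelector",
    "DistanceRestraint",
    "ParameterRecord",
    "ParameterSet",
    "PARAMETER_KINDS",
]

PARAMETER_KINDS = ("chemical_shift", "s2", "rdc", "jcoupling")


@dataclass(frozen=True)
class Conformer:
    """One model of an ensemble: coordinates over the shared atom table."""

    atom_table: pd.DataFrame
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    model_number: int = 1

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.atom_table), 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"atom table of length {len(self.atom_table)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


@dataclass
class Ensemble:
    """Ordered conformers with a single harmonized atom table.

    ``atom_table`` columns: ``chain``, ``resid`` (author numbering),
    ``resname`` (3-letter), ``name`` (PDB v3 atom name).
    """

    atom_table: pd.DataFrame
    coords: np.ndarray  # (n_models, n_atoms, 3)
    model_numbers: list[int] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one conformer")
        if self.coords.shape[1] != len(self.atom_table):
            raise ValueError("coords second axis must match the atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not self.model_numbers:
            self.model_numbers = list(range(1, self.coords.shape[0] + 1))
        if len(self.model_numbers) != self.coords.shape[0]:
            raise ValueError("one model number per conformer required")
        self.atom_table = self.atom_table.reset_index(drop=True)

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def conformers(self) -> list[Conformer]:
        return [self[i] for i in range(self.n_conformers)]

    def __len__(self) -> int:
        return self.n_conformers

    def __getitem__(self, i: int) -> Conformer:
        return Conformer(self.atom_table, self.coords[i], self.model_numbers[i])

    def __iter__(self) -> Iterator[Conformer]:
        return iter(self.conformers)

    def residues(self) -> pd.DataFrame:
        """Unique (chain, resid, resname) rows in table order."""
        return self.atom_table[["chain", "resid", "resname"]].drop_duplicates().reset_index(drop=True)

    def atom_index(self, resid: int, name: str, chain: str | None = None) -> int:
        """Index of a single named atom; raises ``KeyError`` when absent."""
        t = self.atom_table
        mask = (t["resid"] == resid) & (t["name"] == name)
        if chain is not None:
            mask &= t["chain"] == chain
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"no atom {name!r} in residue {resid}")
        return int(idx[0])

    def with_coords(self, coords: np.ndarray, source_id: str | None = None) -> "Ensemble":
        coords = np.asarray(coords, dtype=float)
        numbers = list(self.model_numbers) if coords.shape[0] == self.n_conformers else []
        return Ensemble(
            self.atom_table.copy(),
            coords,
            numbers,
            self.source_id if source_id is None else source_id,
        )


def _pattern_to_regex(pattern: str) -> re.Pattern:
    # X-PLOR wildcards: '*' any string, '%' one character, '#' digit string,
    # '+' one digit.  Everything else is literal.
    out = []
    for ch in pattern.upper():
        if ch == "*":
            out.append(".*")
        elif ch == "%":
            out.append(".")
        elif ch == "#":
            out.append("[0-9]+")
        elif ch == "+":
            out.append("[0-9]")
        else:
            out.append(re.escape(ch))
    return re.compile("^" + "".join(out) + "$")


@dataclass(frozen=True)
class AtomSelector:
    """One side of a distance restraint.

    ``alternatives`` is an OR-list of (resid, atom-name pattern) clauses;
    a plain selector has exactly one clause.  Patterns keep the X-PLOR
    wildcards (``# * % +``).
    """

    alternatives: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("selector needs at least one (resid, name) clause")

    @classmethod
    def single(cls, resid: int, name: str) -> "AtomSelector":
        return cls(((resid, name),))

    @property
    def is_compound(self) -> bool:
        return len(self.alternatives) > 1

    def resolve(self, atom_table: pd.DataFrame) -> np.ndarray:
        """Indices of all atoms matched by any alternative (may be empty)."""
        names = atom_table["name"].str.upper().to_numpy()
        resids = atom_table["resid"].to_numpy()
        hit = np.zeros(len(atom_table), dtype=bool)
        for resid, pattern in self.alternatives:
            rx = _pattern_to_regex(pattern)
            sub = resids == resid
            if sub.any():
                matched = np.fromiter((bool(rx.match(n)) for n in names[sub]), bool, count=int(sub.sum()))
                idx = np.flatnonzero(sub)
                hit[idx[matched]] = True
        return np.flatnonzero(hit)

    def to_xplor(self) -> str:
        parts = [f"resid {r} and name {n}" for r, n in self.alternatives]
        if len(parts) == 1:
            return f"({parts[0]})"
        return "(" + " or ".join(f"({p})" for p in parts) + ")"


@dataclass(frozen=True)
class DistanceRestraint:
    """An X-PLOR/CNS ``assign`` distance restraint.

    Bounds are ``d - dminus`` (lower) and ``d + dplus`` (upper), Angstrom.
    ``is_ambiguous`` marks restraints whose source line contained "or".
    """

    left: AtomSelector
    right: AtomSelector
    d: float
    dminus: float
    dplus: float
    is_ambiguous: bool = False
    restraint_id: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("target distance must be positive")
        if self.dminus < 0 or self.dplus < 0:
            raise ValueError("margins must be non-negative")
        if self.d - self.dminus < 0:
            raise ValueError("lower bound must be non-negative")

    @property
    def upper(self) -> float:
        return self.d + self.dplus

    @property
    def lower(self) -> float:
        return self.d - self.dminus

    def to_xplor(self) -> str:
        return (
            f"assign {self.left.to_xplor()}{self.right.to_xplor()} "
            f"{self.d:.2f} {self.dminus:.2f} {self.dplus:.2f}"
        )


@dataclass(frozen=True)
class ParameterRecord:
    """One experimental observation: residue, optional atoms, value."""

    resid: int
    atoms: tuple[str, ...]
    value: float


@dataclass
class ParameterSet:
    """A homogeneous block of experimental observations.

    ``kind`` is one of ``chemical_shift``, ``s2``, ``rdc``, ``jcoupling``;
    ``subtype`` names the nucleus, bond vector or coupling (e.g. ``CA``,
    ``N-H``, ``3J_HNHA``).
    """

    kind: str
    subtype: str
    records: list[ParameterRecord]
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PARAMETER_KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resid": [r.resid for r in self.records],
                "atoms": ["-".join(r.atoms) for r in self.records],
                "value": [r.value for r in self.records],
            }
        )

    def values_by_resid(self) -> dict[int, float]:
        return {r.resid: r.value for r in self.records}
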