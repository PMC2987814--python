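"""Ensemble-averaged NOE restraint violation analysis.

For each restraint the distance is pooled r^-6 over degenerate atom pairs
within each conformer, then averaged r^-3 or r^-6 across conformers
(default r^-6), and compared with the restraint's upper bound.  Only
upper-bound violations are reported by default; NOE bounds are
predominantly upper limits.  Ambiguous ("or") restraints are excluded by
default, optionally pooled branch-wise with r^-6 weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import DistanceRestraint, Ensemble
from .geometry import (
    UnresolvableSelectorError,
    ensemble_effective_distance,
    restraint_distance_in_conformer,
)

logger = logging.getLogger("ensval")

__all__ = ["ViolationRecord", "ViolationReport", "evaluate_noe"]


@dataclass(frozen=True)
class ViolationRecord:
    restraint_id: int
    effective_distance: float
    bound: float
    violation: float
    bound_side: str = "upper"

    def __post_init__(self) -> None:
        if self.violation <= 0:
            raise ValueError("only actual violations are recorded")


@dataclass
class ViolationReport:
    mode: str
    n_restraints: int
    n_unresolved: int
    n_ambiguous_excluded: int
    violations: list[ViolationRecord] = field(default_factory=list)
    bin_width: float = 0.1
    effective_distances: dict[int, float] = field(default_factory=dict)

    @property
    def n_violated(self) -> int:
        return len(self.violations)

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, counts) over [0, max violation] at ``bin_width``."""
        if not self.violations:
            return np.array([0.0, self.bin_width]), np.array([0])
        vmax = max(v.violation for v in self.violations)
        n_bins = max(1, int(np.ceil(vmax / self.bin_width - 1e-12)))
        edges = np.arange(n_bins + 1) * self.bin_width
        counts, _ = np.histogram([v.violation for v in self.violations], bins=edges)
        return edges, counts


def evaluate_noe(
    ensemble: Ensemble,
    restraints: list[DistanceRestraint],
    mode: str = "r6",
    include_ambiguous: bool = False,
    check_lower: bool = False,
    bin_width: float = 0.1,
) -> ViolationReport:
    """Evaluate ensemble-averaged restraint violations.

    ``include_ambiguous`` pools the atom selections of "or" restraints with
    r^-6 weighting instead of excluding them.  ``check_lower`` additionally
    reports lower-bound violations.
    """
    report = ViolationReport(mode=mode, n_restraints=0, n_unresolved=0,
                             n_ambiguous_excluded=0, bin_width=bin_width)
    n_resolved = 0
    for restraint in restraints:
        if restraint.is_ambiguous and not include_ambiguous:
            report.n_ambiguous_excluded += 1
            continue
        try:
            per_conf = [restraint_distance_in_conformer(c, restraint) for c in ensemble]
        except UnresolvableSelectorError as exc:
            logger.warning("UNRESOLVED restraint %d: %s", restraint.restraint_id, exc)
            report.n_unresolved += 1
            continue
        d_eff = ensemble_effective_distance(per_conf, mode)
        report.effective_distances[restraint.restraint_id] = d_eff
        n_resolved += 1
        over = d_eff - restraint.upper
        if over > 0:
            report.violations.append(
                ViolationRecord(restraint.restraint_id, d_eff, restraint.upper, over)
            )
        if check_lower:
            under = restraint.lower - d_eff
            if under > 0:
                report.violations.append(
                    ViolationRecord(restraint.restraint_id, d_eff, restraint.lower, under, "lower")
                )
    report.n_restraints = n_resolved
    if n_resolved == 0 and restraints:
        raise UnresolvableSelectorError("no restraint could be resolved against the ensemble")
    return report
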