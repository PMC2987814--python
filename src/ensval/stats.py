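"""Correspondence statistics between experimental and back-calculated data.

For every parameter type the package reports the Pearson correlation R,
the Q-factor ``q = sqrt(sum((calc - exp)^2) / sum(exp^2))`` (the standard
RDC-validation convention; a squared variant is available behind a flag)
and the RMSD, plus per-model-vs-ensemble correlation diagnostics.
Statistics are computed only over records present on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .backcalc import BackCalcResult
from .core import ParameterSet

logger = logging.getLogger("ensval")

__all__ = [
    "pearson_r",
    "q_factor",
    "rmsd_values",
    "per_model_correlation",
    "CorrespondenceSummary",
    "compare",
]


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises on <3 pairs or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(_scipy_stats.pearsonr(x, y).statistic)


def q_factor(calc, exp, squared: bool = False) -> float:
    """Normalized mismatch ``sqrt(sum((calc-exp)^2)/sum(exp^2))``.

    ``squared=True`` returns the un-rooted variant.
    """
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if calc.shape != exp.shape or calc.size == 0:
        raise ValueError("need paired, non-empty vectors")
    denom = float(np.sum(exp**2))
    if denom == 0:
        raise ValueError("Q-factor undefined for an all-zero experimental vector")
    ratio = float(np.sum((calc - exp) ** 2)) / denom
    return ratio if squared else float(np.sqrt(ratio))


def rmsd_values(calc, exp) -> float:
    """Root-mean-square deviation, same units as the inputs."""
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if calc.shape != exp.shape or calc.size == 0:
        raise ValueError("need paired, non-empty vectors")
    return float(np.sqrt(np.mean((calc - exp) ** 2)))


def per_model_correlation(per_conformer_matrix, exp) -> tuple[list[float], float, float]:
    """Correlation of each conformer's back-calculated vector with experiment.

    Returns ``(per_model_R, mean_per_model_R, ensemble_R)`` where the
    ensemble value is the correlation of the conformer-averaged vector —
    the quantity that reveals whether ensemble averaging itself improves
    the agreement.
    """
    matrix = np.asarray(per_conformer_matrix, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != exp.size:
        raise ValueError("matrix rows must be conformers over the experimental records")
    per_model = [pearson_r(row, exp) for row in matrix]
    ensemble_r = pearson_r(matrix.mean(axis=0), exp)
    return per_model, float(np.mean(per_model)), ensemble_r


@dataclass
class CorrespondenceSummary:
    """Per-parameter correspondence: n, R, Q-factor, RMSD (+ per-model R)."""

    kind: str
    subtype: str
    n: int
    r: float | None
    q: float
    rmsd: float
    per_model_r: list[float] | None = None
    unit: str = ""

    @property
    def ensemble_r(self) -> float | None:
        return self.r


def compare(
    experimental: ParameterSet,
    calculated: BackCalcResult,
    squared_q: bool = False,
) -> CorrespondenceSummary:
    """Match records by residue and compute the correspondence statistics.

    Records present on only one side never enter any statistic.  R is
    reported as ``None`` when undefined (fewer than 3 common records or
    zero variance).
    """
    exp_map = experimental.values_by_resid()
    calc_map = calculated.values_by_resid()
    common = sorted(set(exp_map) & set(calc_map))
    dropped = sorted(set(exp_map) - set(calc_map))
    if dropped:
        logger.warning(
            "SKIPPED %d experimental %s/%s record(s) without a calculated "
            "counterpart: residues %s",
            len(dropped), experimental.kind, experimental.subtype, dropped,
        )
    if not common:
        raise ValueError(
            f"no common records for {experimental.kind}/{experimental.subtype}"
        )
    exp = np.array([exp_map[r] for r in common])
    calc = np.array([calc_map[r] for r in common])
    try:
        r = pearson_r(calc, exp)
    except ValueError:
        r = None
    per_model_r: list[float] | None = None
    if calculated.per_conformer is not None and r is not None:
        col = {resid: i for i, resid in enumerate(calculated.resids)}
        sub = calculated.per_conformer[:, [col[resid] for resid in common]]
        try:
            per_model_r, _, _ = per_model_correlation(sub, exp)
        except ValueError:
            per_model_r = None
    return CorrespondenceSummary(
        kind=experimental.kind,
        subtype=experimental.subtype,
        n=len(common),
        r=r,
        q=q_factor(calc, exp, squared=squared_q),
        rmsd=rmsd_values(calc, exp),
        per_model_r=per_model_r,
        unit=experimental.unit,
    )
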