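"""Probability-of-identity (PRIDE-style) per-conformer NOE compliance score.

The restraint set and a conformer are each summarized by normalized
histograms of distances, one histogram per sequence-separation class
|i - j| = k.  The per-class probability of identity is the histogram
intersection sum(min(h_restraint, h_conformer)); the score is the
unweighted mean over non-empty classes.  Because the conformers and the
restraint list describe the same chain, no cross-length weighting is
needed.  All parameters (class range, bin width, distance cap) are
explicit configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Conformer, DistanceRestraint, Ensemble
from .geometry import UnresolvableSelectorError, restraint_distance_in_conformer

logger = logging.getLogger("ensval")

__all__ = ["PrideConfig", "PrideSummary", "pride_score", "pride_stats"]


@dataclass(frozen=True)
class PrideConfig:
    """Histogram configuration for the probability-of-identity score."""

    k_min: int = 3
    k_max: int = 30
    bin_width: float = 0.5  # Angstrom
    d_max: float = 15.0  # Angstrom; distances beyond fall outside every bin
    score_bins: int = 20  # histogram of per-conformer scores over [0, 1]


@dataclass
class PrideSummary:
    """Per-conformer scores with min/max/mean/sd and a score histogram."""

    scores: list[float]
    model_numbers: list[int]
    config: PrideConfig = field(default_factory=PrideConfig)

    @property
    def minimum(self) -> float:
        return float(np.min(self.scores))

    @property
    def maximum(self) -> float:
        return float(np.max(self.scores))

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1)) if len(self.scores) > 1 else 0.0

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        edges = np.linspace(0.0, 1.0, self.config.score_bins + 1)
        counts, _ = np.histogram(self.scores, bins=edges)
        return edges, counts


def _separation(restraint: DistanceRestraint) -> int:
    """Sequence separation of a restraint: |resid_left - resid_right|,
    taking the first alternative of each selector."""
    return abs(restraint.left.alternatives[0][0] - restraint.right.alternatives[0][0])


def _class_histogram(values: list[float], edges: np.ndarray) -> np.ndarray | None:
    counts, _ = np.histogram(values, bins=edges)
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def pride_score(
    conformer: Conformer,
    restraints: list[DistanceRestraint],
    config: PrideConfig | None = None,
) -> float:
    """Probability-of-identity score of one conformer against the restraints.

    Restraint target distances and the distances realized in the conformer
    (r^-6 effective distance for wildcard/multi-atom selections) are binned
    per sequence-separation class; the score is the mean histogram
    intersection over classes that contain at least one restraint whose
    target distance falls inside [0, d_max].
    """
    config = config or PrideConfig()
    edges = np.arange(0.0, config.d_max + config.bin_width * 0.5, config.bin_width)
    targets: dict[int, list[float]] = {}
    realized: dict[int, list[float]] = {}
    n_resolved = 0
    for restraint in restraints:
        k = _separation(restraint)
        if not (config.k_min <= k <= config.k_max):
            continue
        try:
            d_conf = restraint_distance_in_conformer(conformer, restraint)
        except UnresolvableSelectorError:
            logger.warning("UNRESOLVED restraint %d skipped in scoring", restraint.restraint_id)
            continue
        n_resolved += 1
        targets.setdefault(k, []).append(restraint.d)
        realized.setdefault(k, []).append(d_conf)
    if n_resolved == 0:
        raise UnresolvableSelectorError(
            "no resolvable restraint within the configured separation classes"
        )
    poi = []
    for k, target_values in targets.items():
        h_target = _class_histogram(target_values, edges)
        if h_target is None:  # all targets beyond d_max: class carries no signal
            continue
        h_real = _class_histogram(realized[k], edges)
        if h_real is None:
            poi.append(0.0)
            continue
        poi.append(float(np.minimum(h_target, h_real).sum()))
    if not poi:
        raise UnresolvableSelectorError("every separation class was empty")
    return float(np.mean(poi))


def pride_stats(
    ensemble: Ensemble,
    restraints: list[DistanceRestraint],
    config: PrideConfig | None = None,
) -> PrideSummary:
    """Apply :func:`pride_score` to every conformer and summarize."""
    config = config or PrideConfig()
    scores = [pride_score(conf, restraints, config) for conf in ensemble]
    return PrideSummary(scores, list(ensemble.model_numbers), config)
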