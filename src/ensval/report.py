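"""Run orchestration and report emission.

``run_evaluation`` wires the parsers and evaluators together: every
evaluator for which data exist is executed, missing parameter categories
are skipped with a logged notice, and all results are written as
tab-separated tables with a stable schema (summary, per-residue series,
violation list, per-conformer scores, histograms).  Plots are emitted as
data tables; nothing here is stochastic, so a run is reproducible from
its configuration alone.

Exit-status convention: 0 success, 2 usage error, 3 parse error,
4 numerical/evaluator failure (partial outputs are still written).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backcalc import (
    ExternalRdcPredictor,
    ExternalShiftPredictor,
    ExternalToolError,
    ensemble_couplings,
    ensemble_rdc,
    ensemble_shifts,
    s2_order_parameters,
)
from .core import Conformer, Ensemble, ParameterSet
from .io_formats import (
    ParseError,
    parse_nmr_star,
    parse_xplor_restraints,
    read_text,
)
from .noe import evaluate_noe
from .pride import PrideConfig, pride_stats
from .stats import CorrespondenceSummary, compare

logger = logging.getLogger("ensval")

__all__ = [
    "RunConfig",
    "RunResult",
    "run_evaluation",
    "write_multi_model_pdb",
    "write_single_model_pdb",
    "EXIT_OK",
    "EXIT_USAGE",
    "EXIT_PARSE",
    "EXIT_NUMERICAL",
]

EXIT_OK, EXIT_USAGE, EXIT_PARSE, EXIT_NUMERICAL = 0, 2, 3, 4


# --- PDB writing -------------------------------------------------------------

def _format_atom_line(serial: int, name: str, resname: str, chain: str,
                      resid: int, pos) -> str:
    pad_name = name if len(name) >= 4 else f" {name}"
    element = name[1] if name[0].isdigit() else name[0]
    return (
        f"ATOM  {serial:5d} {pad_name:<4s} {resname:>3s} {chain:1s}{resid:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_single_model_pdb(conformer: Conformer) -> str:
    lines = []
    for serial, ((_, row), pos) in enumerate(
        zip(conformer.atom_table.iterrows(), conformer.coords), start=1
    ):
        lines.append(
            _format_atom_line(serial, row["name"], row["resname"], row["chain"],
                              int(row["resid"]), pos)
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_multi_model_pdb(ensemble: Ensemble) -> str:
    lines = []
    for conf in ensemble:
        lines.append(f"MODEL     {conf.model_number:4d}")
        body = write_single_model_pdb(conf).splitlines()
        lines.extend(body[:-1])  # drop END
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- configuration -----------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a reproducible evaluation run needs.

    The steric (first-principles) RDC mode mirrors the server default but
    requires an external predictor command; when none is configured the
    run falls back to the native SVD fit with a logged notice.
    """

    pdb_path: str | Path = ""
    restraints_path: str | Path | None = None
    star_path: str | Path | None = None
    out_dir: str | Path = "ensval_out"
    avg_mode: str = "r6"  # ensemble averaging for NOE violations
    violations: bool = True
    rdc_mode: str = "external_steric"
    shift_predictor: str = "builtin"
    external_shift_command: str = ""
    external_rdc_command: str = ""
    violation_bin_width: float = 0.1
    pride: PrideConfig = field(default_factory=PrideConfig)
    squared_q: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.avg_mode not in ("r3", "r6"):
            raise ValueError(f"avg mode must be r3 or r6, got {self.avg_mode!r}")
        if self.rdc_mode not in ("svd", "external_steric"):
            raise ValueError(f"rdc mode must be svd or external_steric, got {self.rdc_mode!r}")
        if self.shift_predictor not in ("builtin", "external"):
            raise ValueError(f"shift predictor must be builtin or external")
        if not self.pdb_path or not Path(self.pdb_path).exists():
            raise FileNotFoundError(f"PDB file not found: {self.pdb_path}")
        for path in (self.restraints_path, self.star_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")
        if self.restraints_path is None and self.star_path is None:
            raise ValueError("at least one parameter source (restraints or STAR) is required")


@dataclass
class RunResult:
    exit_status: int
    summaries: list[CorrespondenceSummary] = field(default_factory=list)
    output_files: list[Path] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


# --- table emission ----------------------------------------------------------

def _write_tsv(frame: pd.DataFrame, path: Path, result: RunResult) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    result.output_files.append(path)


def _hist_frame(edges: np.ndarray, counts: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def _slug(kind: str, subtype: str) -> str:
    clean = subtype.replace("'", "p").replace("-", "_").lower()
    return f"{kind}_{clean}"


# --- the run -----------------------------------------------------------------

def _backcalc_for(
    ensemble: Ensemble, pset: ParameterSet, config: RunConfig, cache: dict
):
    """Back-calculate the observable matching one experimental set."""
    if pset.kind == "s2":
        return s2_order_parameters(ensemble, pset.subtype)
    if pset.kind == "jcoupling":
        if "couplings" not in cache:
            cache["couplings"] = {r.subtype: r for r in ensemble_couplings(ensemble)}
        result = cache["couplings"].get(pset.subtype)
        if result is None:
            raise ValueError(f"no Karplus coefficients for {pset.subtype!r}")
        return result
    if pset.kind == "chemical_shift":
        if "shifts" not in cache:
            predictor = None
            if config.shift_predictor == "external":
                predictor = ExternalShiftPredictor(config.external_shift_command)
            cache["shifts"] = {r.subtype: r for r in ensemble_shifts(ensemble, predictor)}
        result = cache["shifts"].get(pset.subtype)
        if result is None:
            raise ValueError(f"nucleus {pset.subtype!r} not covered by the shift predictor")
        return result
    if pset.kind == "rdc":
        mode = config.rdc_mode
        external = None
        if mode == "external_steric":
            if config.external_rdc_command.strip():
                external = ExternalRdcPredictor(config.external_rdc_command)
            else:
                logger.info("no external steric predictor configured; falling back to SVD mode")
                mode = "svd"
        return ensemble_rdc(ensemble, pset, mode=mode, external=external)
    raise ValueError(f"unknown parameter kind {pset.kind!r}")


def run_evaluation(config: RunConfig) -> RunResult:
    """Execute every applicable evaluator and write the report bundle."""
    result = RunResult(exit_status=EXIT_OK)
    try:
        config.validate()
    except (ValueError, FileNotFoundError) as exc:
        logger.error("usage error: %s", exc)
        return RunResult(exit_status=EXIT_USAGE, errors=[str(exc)])

    out = Path(config.out_dir)
    try:
        from .io_formats import parse_multi_model_pdb

        ensemble = parse_multi_model_pdb(read_text(config.pdb_path), source_id=str(config.pdb_path))
        restraints = (
            parse_xplor_restraints(read_text(config.restraints_path), on_error="skip")
            if config.restraints_path is not None
            else []
        )
        parameter_sets = (
            parse_nmr_star(read_text(config.star_path))
            if config.star_path is not None
            else []
        )
    except ParseError as exc:
        logger.error("parse error: %s", exc)
        return RunResult(exit_status=EXIT_PARSE, errors=[str(exc)])
    if not restraints and not parameter_sets:
        return RunResult(exit_status=EXIT_USAGE,
                         errors=["no usable parameter source in the inputs"])

    summary_rows = []
    cache: dict = {}

    if restraints:
        try:
            pride_summary = pride_stats(ensemble, restraints, config.pride)
            _write_tsv(
                pd.DataFrame({"model": pride_summary.model_numbers,
                              "score": pride_summary.scores}),
                out / "pride.tsv", result,
            )
            edges, counts = pride_summary.histogram()
            _write_tsv(_hist_frame(edges, counts), out / "histograms" / "pride_scores.tsv", result)
        except Exception as exc:
            logger.error("PRIDE scoring failed: %s", exc)
            result.errors.append(f"pride: {exc}")
        if config.violations:
            try:
                report = evaluate_noe(
                    ensemble, restraints, mode=config.avg_mode,
                    bin_width=config.violation_bin_width,
                )
                _write_tsv(
                    pd.DataFrame(
                        [
                            {
                                "restraint_id": v.restraint_id,
                                "d_eff": v.effective_distance,
                                "bound": v.bound,
                                "side": v.bound_side,
                                "violation": v.violation,
                            }
                            for v in report.violations
                        ],
                        columns=["restraint_id", "d_eff", "bound", "side", "violation"],
                    ),
                    out / "violations.tsv", result,
                )
                edges, counts = report.histogram()
                _write_tsv(_hist_frame(edges, counts), out / "histograms" / "violations.tsv", result)
            except Exception as exc:
                logger.error("violation analysis failed: %s", exc)
                result.errors.append(f"violations: {exc}")
    else:
        logger.info("SKIPPED: no distance restraints supplied")

    for pset in parameter_sets:
        label = f"{pset.kind}/{pset.subtype}"
        try:
            calc = _backcalc_for(ensemble, pset, config, cache)
            summary = compare(pset, calc, squared_q=config.squared_q)
        except (ValueError, ExternalToolError) as exc:
            logger.error("evaluator failed for %s: %s", label, exc)
            result.errors.append(f"{label}: {exc}")
            continue
        result.summaries.append(summary)
        summary_rows.append(
            {
                "kind": summary.kind, "subtype": summary.subtype, "n": summary.n,
                "R": np.nan if summary.r is None else summary.r,
                "q": summary.q, "rmsd": summary.rmsd, "unit": summary.unit,
            }
        )
        exp_map = pset.values_by_resid()
        calc_map = calc.values_by_resid()
        common = sorted(set(exp_map) & set(calc_map))
        _write_tsv(
            pd.DataFrame(
                {
                    "resid": common,
                    "experimental": [exp_map[r] for r in common],
                    "calculated": [calc_map[r] for r in common],
                }
            ),
            out / f"per_residue_{_slug(pset.kind, pset.subtype)}.tsv", result,
        )
        if summary.per_model_r is not None:
            _write_tsv(
                pd.DataFrame(
                    {
                        "model": ensemble.model_numbers,
                        "R": summary.per_model_r,
                        "ensemble_R": summary.r,
                    }
                ),
                out / f"per_model_r_{_slug(pset.kind, pset.subtype)}.tsv", result,
            )

    _write_tsv(
        pd.DataFrame(summary_rows, columns=["kind", "subtype", "n", "R", "q", "rmsd", "unit"]),
        out / "summary.tsv", result,
    )
    if result.errors:
        result.exit_status = EXIT_NUMERICAL
    return result
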