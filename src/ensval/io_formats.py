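"""Readers and writers for the three standard inputs.

* multi-model PDB  -> :class:`~ensval.core.Ensemble` (parsed with gemmi)
* X-PLOR/CNS ``assign`` distance restraints -> :class:`DistanceRestraint` list
* NMR-STAR loops (shifts, S2, RDC, J couplings) -> :class:`ParameterSet` list

All readers accept plain or gzipped files; the text-level entry points take
strings so they compose with in-memory fixtures.  Proton names are
normalized to the PDB v3 dialect (HB2/HB3); v2 names (1HB / HB1) are
accepted on input through a mapping table.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .core import AtomSelector, DistanceRestraint, Ensemble, ParameterRecord, ParameterSet

logger = logging.getLogger("ensval")

__all__ = [
    "parse_multi_model_pdb",
    "load_ensemble",
    "parse_xplor_restraints",
    "drop_ambiguous_lines",
    "write_xplor_restraints",
    "parse_nmr_star",
    "normalize_atom_name",
    "read_text",
    "ParseError",
]


class ParseError(ValueError):
    """Raised when one of the three input formats cannot be parsed."""


def read_text(path: str | Path) -> str:
    """Read a text file, transparently decompressing gzip."""
    data = Path(path).read_bytes()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode("utf-8", errors="replace")


# --- atom-name normalization -------------------------------------------------

# Methylene/amine proton groups whose v2 names run 1/2 where v3 runs 2/3.
_SHIFTED_GROUPS: dict[str, set[str]] = {
    "GLY": {"HA"},
    "ARG": {"HB", "HG", "HD"},
    "ASN": {"HB", "HD2"},
    "ASP": {"HB"},
    "CYS": {"HB"},
    "GLN": {"HB", "HG", "HE2"},
    "GLU": {"HB", "HG"},
    "HIS": {"HB"},
    "ILE": {"HG1"},
    "LEU": {"HB"},
    "LYS": {"HB", "HG", "HD", "HE", "HZ"},
    "MET": {"HB", "HG"},
    "PHE": {"HB"},
    "PRO": {"HB", "HG", "HD"},
    "SER": {"HB"},
    "TRP": {"HB"},
    "TYR": {"HB"},
}

_GROUP_RE = re.compile(r"^(H[A-Z]*[0-9]?)([0-9])$")


def normalize_atom_name(name: str, resname: str = "") -> str:
    """Map a PDB v2-style proton name to the v3 dialect.

    Handles the leading-digit convention (``1HB`` -> ``HB1``), ``HN`` ->
    ``H``, and the 1/2 -> 2/3 renumbering of methylene protons (``HB1`` ->
    ``HB2`` for residues where v3 uses HB2/HB3).  Non-proton names pass
    through unchanged apart from whitespace/case cleanup.
    """
    name = name.strip().upper()
    if name and name[0].isdigit() and "H" in name:
        name = name[1:] + name[0]
    if name == "HN":
        return "H"
    m = _GROUP_RE.match(name)
    if m and resname:
        base, digit = m.group(1), m.group(2)
        if base in _SHIFTED_GROUPS.get(resname.strip().upper(), ()):
            if digit == "1":
                return base + "2"
            if digit == "2":
                return base + "3"
    return name


def v2_fallback_names(name: str, resname: str) -> list[str]:
    """Alternative v3 names to try when an exact selector name fails.

    A restraint written in the v2 dialect may say ``HB1`` for a residue
    whose v3 protons are HB2/HB3; normalization of the *structure* cannot
    fix the *restraint*, so resolution retries with the shifted name.
    """
    m = _GROUP_RE.match(name.upper())
    if not m:
        return []
    base, digit = m.group(1), m.group(2)
    if base in _SHIFTED_GROUPS.get(resname.upper(), ()):
        if digit == "1":
            return [base + "2"]
        if digit == "2":
            return [base + "3"]
    return []


# --- multi-model PDB ---------------------------------------------------------

def parse_multi_model_pdb(text: str, source_id: str = "") -> Ensemble:
    """Parse a (possibly multi-model) PDB string into an :class:`Ensemble`.

    One conformer per MODEL block, in file order; a file without MODEL
    records yields a single conformer.  Models whose atom sets differ from
    the first model are reconciled by intersection (with a warning).
    """
    if not text.strip():
        raise ParseError("empty PDB input")
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"PDB parse failure: {exc}") from None
    structure.setup_entities()
    if len(structure) == 0:
        raise ParseError("no models/atoms found in PDB input")

    per_model: list[dict[tuple, np.ndarray]] = []
    model_numbers: list[int] = []
    for model in structure:
        atoms: dict[tuple, np.ndarray] = {}
        for chain in model:
            for residue in chain:
                for atom in residue:
                    key = (
                        chain.name,
                        residue.seqid.num,
                        residue.name.strip().upper(),
                        normalize_atom_name(atom.name, residue.name),
                    )
                    if key not in atoms:  # keep first altloc
                        atoms[key] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if atoms:
            per_model.append(atoms)
            num = getattr(model, "num", None)
            if num is None:
                try:
                    num = int(getattr(model, "name", len(per_model)))
                except (TypeError, ValueError):
                    num = len(per_model)
            model_numbers.append(int(num))
    if not per_model:
        raise ParseError("no ATOM records found in PDB input")

    keys = [k for k in per_model[0] if all(k in m for m in per_model[1:])]
    if not keys:
        raise ParseError("zero atoms common to all models")
    if any(len(m) != len(keys) for m in per_model):
        logger.warning(
            "models differ in atom content; harmonized to the %d-atom intersection",
            len(keys),
        )
    atom_table = pd.DataFrame(keys, columns=["chain", "resid", "resname", "name"])
    coords = np.array([[m[k] for k in keys] for m in per_model], dtype=float)
    return Ensemble(atom_table, coords, model_numbers, source_id=source_id)


def load_ensemble(path: str | Path) -> Ensemble:
    return parse_multi_model_pdb(read_text(path), source_id=str(path))


# --- X-PLOR/CNS distance restraints -----------------------------------------

_OR_LINE = re.compile(r"\bor\b", re.IGNORECASE)
_ASSIGN = re.compile(r"\bassign\b", re.IGNORECASE)


def _strip_comments(text: str) -> str:
    lines = []
    for line in text.splitlines():
        if "!" in line:
            line = line[: line.index("!")]
        lines.append(line)
    return "\n".join(lines)


def _balanced_group(text: str, start: int) -> tuple[str, int]:
    """Return the contents of the parenthesized group starting at or after
    ``start`` and the index just past its closing paren."""
    i = text.index("(", start)
    depth = 0
    for j in range(i, len(text)):
        if text[j] == "(":
            depth += 1
        elif text[j] == ")":
            depth -= 1
            if depth == 0:
                return text[i + 1 : j], j + 1
    raise ValueError("unbalanced parentheses")


def _split_top_level_or(sel: str) -> list[str]:
    parts: list[str] = []
    depth = 0
    tokens = re.split(r"(\(|\))", sel)
    buf = ""
    for tok in tokens:
        if tok == "(":
            depth += 1
            buf += tok
        elif tok == ")":
            depth -= 1
            buf += tok
        else:
            if depth == 0:
                pieces = re.split(r"\bor\b", tok, flags=re.IGNORECASE)
                buf += pieces[0]
                for piece in pieces[1:]:
                    parts.append(buf)
                    buf = piece
            else:
                buf += tok
    parts.append(buf)
    return parts


_RESID_RE = re.compile(r"\bresid(?:ue)?\b\s+(-?\d+)", re.IGNORECASE)
_NAME_RE = re.compile(r"\bname\b\s+([A-Za-z0-9#*%+']+)", re.IGNORECASE)


def _parse_selector(sel: str) -> AtomSelector:
    alternatives = []
    for branch in _split_top_level_or(sel):
        rm = _RESID_RE.search(branch)
        nm = _NAME_RE.search(branch)
        if rm is None or nm is None:
            raise ValueError(f"selector branch lacks resid/name: {branch.strip()!r}")
        alternatives.append((int(rm.group(1)), nm.group(1).upper()))
    return AtomSelector(tuple(alternatives))


def parse_xplor_restraints(text: str, on_error: str = "raise") -> list[DistanceRestraint]:
    """Parse ``assign (sel)(sel) d dminus dplus`` statements.

    ``on_error='skip'`` drops malformed statements with a warning instead of
    raising.  Statements may span physical lines; ``!`` comments are ignored.
    Restraints whose statement text contains the word "or" are flagged
    ambiguous.
    """
    clean = _strip_comments(text)
    restraints: list[DistanceRestraint] = []
    matches = list(_ASSIGN.finditer(clean))
    for n, m in enumerate(matches):
        end = matches[n + 1].start() if n + 1 < len(matches) else len(clean)
        stmt = clean[m.start() : end]
        line_no = clean[: m.start()].count("\n") + 1
        try:
            left_txt, pos = _balanced_group(stmt, 0)
            right_txt, pos = _balanced_group(stmt, pos)
            numbers = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", stmt[pos:])
            if len(numbers) < 3:
                raise ValueError("fewer than three distance values")
            d, dminus, dplus = (float(x) for x in numbers[:3])
            restraint = DistanceRestraint(
                left=_parse_selector(left_txt),
                right=_parse_selector(right_txt),
                d=d,
                dminus=dminus,
                dplus=dplus,
                is_ambiguous=bool(_OR_LINE.search(stmt)),
                restraint_id=len(restraints) + 1,
            )
        except ValueError as exc:
            if on_error == "skip":
                logger.warning("skipping malformed assign at line %d: %s", line_no, exc)
                continue
            raise ParseError(f"malformed assign statement at line {line_no}: {exc}") from None
        restraints.append(restraint)
    return restraints


def drop_ambiguous_lines(text: str) -> tuple[str, int]:
    """Remove every physical line containing the word "or" (case-insensitive,
    word-boundary match) and count the surviving ``assign`` statements.

    Operates on physical lines *before* any statement joining, so a
    multi-line assign whose continuation carries the "or" loses only the
    offending line (the mutilated statement then fails to parse and is not
    counted).
    """
    kept_lines = [line for line in text.splitlines() if not _OR_LINE.search(line)]
    filtered = "\n".join(kept_lines)
    n_kept = len(parse_xplor_restraints(filtered, on_error="skip"))
    return filtered, n_kept


def write_xplor_restraints(restraints: list[DistanceRestraint]) -> str:
    return "\n".join(r.to_xplor() for r in restraints) + "\n"


# --- NMR-STAR ---------------------------------------------------------------

_STAR_KEYWORDS = {"loop_", "stop_", "data_", "save_", "global_"}


def _tokenize_star(text: str) -> list[str]:
    """Minimal STAR tokenizer: comments, quoted values, ``;`` text fields."""
    tokens: list[str] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            block = []
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            if i >= len(lines):
                raise ParseError("unterminated ';' text field")
            tokens.append("\n".join(block))
            i += 1
            continue
        j = 0
        while j < len(line):
            ch = line[j]
            if ch in " \t":
                j += 1
            elif ch == "#":
                break
            elif ch in "'\"":
                k = line.find(ch, j + 1)
                if k == -1:
                    raise ParseError(f"unterminated quote on line {i + 1}")
                tokens.append(line[j + 1 : k])
                j = k + 1
            else:
                k = j
                while k < len(line) and line[k] not in " \t":
                    k += 1
                tokens.append(line[j:k])
                j = k
        i += 1
    return tokens


def _extract_loops(tokens: list[str]) -> list[tuple[list[str], list[list[str]]]]:
    loops = []
    i = 0
    while i < len(tokens):
        if tokens[i].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags: list[str] = []
        while i < len(tokens) and tokens[i].startswith("_"):
            tags.append(tokens[i].lower())
            i += 1
        values: list[str] = []
        while i < len(tokens):
            tok = tokens[i]
            low = tok.lower()
            if low == "stop_":
                i += 1
                break
            if low in _STAR_KEYWORDS or low.startswith("data_") or low.startswith("save_") or tok.startswith("_"):
                break
            values.append(tok)
            i += 1
        if tags and values:
            if len(values) % len(tags):
                raise ParseError(
                    f"loop with {len(tags)} tags has {len(values)} values "
                    "(not a whole number of rows)"
                )
            rows = [values[k : k + len(tags)] for k in range(0, len(values), len(tags))]
            loops.append((tags, rows))
    return loops


def _col(tags: list[str], *candidates: str) -> int | None:
    for cand in candidates:
        for idx, tag in enumerate(tags):
            if tag == cand or tag.endswith("." + cand.lstrip("_")):
                return idx
    return None


def _to_float(token: str) -> float | None:
    if token in {".", "?", ""}:
        return None
    try:
        return float(token)
    except ValueError:
        return None


_J_LABELS = {
    "3JHNHA": "3J_HNHA",
    "3JHNA": "3J_HNHA",
    "3JHAC": "3J_HAC'",
    "3JHACO": "3J_HAC'",
    "3JHNCB": "3J_HNCB",
    "3JHNC": "3J_HNC'",
    "3JHNCO": "3J_HNC'",
}

_SHIFT_NUCLEI = {"CA", "CB", "HA", "H", "N", "C"}


def _merge_glycine_ha(records: list[ParameterRecord]) -> list[ParameterRecord]:
    """Average HA2/HA3 (or HA1/HA2) shifts of one residue into a single HA."""
    by_resid: dict[int, list[ParameterRecord]] = {}
    out: list[ParameterRecord] = []
    for rec in records:
        if rec.atoms and re.fullmatch(r"HA[1-3]", rec.atoms[0]):
            by_resid.setdefault(rec.resid, []).append(rec)
        else:
            out.append(rec)
    for resid, recs in sorted(by_resid.items()):
        mean = float(np.mean([r.value for r in recs]))
        out.append(ParameterRecord(resid, ("HA",), mean))
    return out


def parse_nmr_star(text: str) -> list[ParameterSet]:
    """Parse NMR-STAR 2.1/3.1 loops into :class:`ParameterSet` objects.

    Recognized categories: chemical shifts, S2 order parameters, RDCs and
    three-bond J couplings; unrecognized loops are skipped with a log note.
    Glycine HA2/HA3 experimental shifts are merged to one averaged HA value.
    """
    tokens = _tokenize_star(text)
    parameter_sets: list[ParameterSet] = []
    for tags, rows in _extract_loops(tokens):
        tagset = " ".join(tags)
        # chemical shifts
        val = _col(tags, "_chem_shift_value", "_atom_chem_shift.val")
        seq = _col(tags, "_residue_seq_code", "_atom_chem_shift.seq_id", "_atom_chem_shift.comp_index_id")
        atom = _col(tags, "_atom_name", "_atom_chem_shift.atom_id")
        if val is not None and seq is not None and atom is not None and "shift" in tagset:
            by_nucleus: dict[str, list[ParameterRecord]] = {}
            for row in rows:
                v = _to_float(row[val])
                if v is None:
                    continue
                name = normalize_atom_name(row[atom])
                nucleus = "HA" if re.fullmatch(r"HA[1-3]", name) else name
                if nucleus not in _SHIFT_NUCLEI:
                    continue
                by_nucleus.setdefault(nucleus, []).append(
                    ParameterRecord(int(row[seq]), (name,), v)
                )
            for nucleus, recs in sorted(by_nucleus.items()):
                if nucleus == "HA":
                    recs = _merge_glycine_ha(recs)
                parameter_sets.append(ParameterSet("chemical_shift", nucleus, recs, unit="ppm"))
            continue
        # S2 order parameters
        val = _col(tags, "_s2_value", "_order_param.order_param_val", "_order_param.s2_val")
        seq = _col(tags, "_residue_seq_code", "_order_param.seq_id", "_order_param.comp_index_id")
        atom = _col(tags, "_atom_name", "_order_param.atom_id")
        if val is not None and seq is not None:
            by_vec: dict[str, list[ParameterRecord]] = {}
            for row in rows:
                v = _to_float(row[val])
                if v is None:
                    continue
                name = normalize_atom_name(row[atom]) if atom is not None else "H"
                vector = "CA-HA" if name in {"HA", "CA"} else "N-H"
                by_vec.setdefault(vector, []).append(ParameterRecord(int(row[seq]), (name,), v))
            for vector, recs in sorted(by_vec.items()):
                parameter_sets.append(ParameterSet("s2", vector, recs, unit=""))
            continue
        # RDC
        val = _col(tags, "_residual_dipolar_coupling_value", "_rdc.val")
        seq1 = _col(tags, "_atom_one_residue_seq_code", "_rdc.seq_id_1")
        atom1 = _col(tags, "_atom_one_atom_name", "_rdc.atom_id_1")
        seq2 = _col(tags, "_atom_two_residue_seq_code", "_rdc.seq_id_2")
        atom2 = _col(tags, "_atom_two_atom_name", "_rdc.atom_id_2")
        if None not in (val, seq1, atom1, seq2, atom2):
            by_pair: dict[str, list[ParameterRecord]] = {}
            for row in rows:
                v = _to_float(row[val])
                if v is None:
                    continue
                a1 = normalize_atom_name(row[atom1])
                a2 = normalize_atom_name(row[atom2])
                pair = f"{a1}-{a2}"
                by_pair.setdefault(pair, []).append(
                    ParameterRecord(int(row[seq1]), (a1, a2), v)
                )
            for pair, recs in sorted(by_pair.items()):
                parameter_sets.append(ParameterSet("rdc", pair, recs, unit="Hz"))
            continue
        # J couplings
        val = _col(tags, "_coupling_constant_value", "_coupling_constant.val")
        code = _col(tags, "_coupling_constant_code", "_coupling_constant.code")
        seq = _col(tags, "_atom_one_residue_seq_code", "_coupling_constant.seq_id_1", "_residue_seq_code")
        if val is not None and code is not None and seq is not None:
            by_label: dict[str, list[ParameterRecord]] = {}
            for row in rows:
                v = _to_float(row[val])
                if v is None:
                    continue
                raw = row[code].upper().replace("_", "").replace("-", "")
                label = _J_LABELS.get(raw, row[code])
                by_label.setdefault(label, []).append(ParameterRecord(int(row[seq]), (), v))
            for label, recs in sorted(by_label.items()):
                parameter_sets.append(ParameterSet("jcoupling", label, recs, unit="Hz"))
            continue
        logger.info("skipping unrecognized STAR loop with tags: %s", tagset)
    return parameter_sets
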