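"""CSV/DOT readers and writers for every pipeline artifact.

Formats (all comma-separated UTF-8, no locale-dependent parsing):

* roster — ``code,label,description,source_note``
* voting sheet — ``factor_code,label,<expert_id>...`` with cells ``1/0``
  (also ``yes/no``, ``y/n``, case-insensitive)
* judgments (long form) — ``expert_id,row_code,col_code,symbol``
* SSIM (wide form) — first row/column are factor codes; upper triangle
  holds V/A/X/O, lower triangle and diagonal stay empty
* reachability matrix — first row/column are factor codes; cells ``0``,
  ``1`` or ``1*`` (the asterisk marks a transitive cell)
* digraph — Graphviz DOT with one rank per level

Unicode minus/en-dash in numeric cells is accepted on read and normalized
to ASCII ``-`` on write.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .engine import ABSENT, DIRECT, TRANSITIVE, ReachabilityMatrix, StructuralDigraph, to_roman
from .errors import MatrixParseError, ValidationError
from .roster import DeterminantRoster, ExpertJudgmentSet, RosterEntry, VoteSheet
from .ssim import SSIM, SYMBOLS, upper_triangle_pairs

log = logging.getLogger("ismkit")

_TRUE = {"1", "yes", "y", "true"}
_FALSE = {"0", "no", "n", "false"}


def _normalize_minus(text: str) -> str:
    return text.replace("−", "-").replace("–", "-")


def _read_rows(path: str | Path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh)]
    if not rows:
        raise MatrixParseError(f"{path}: empty file")
    return rows


# ---------------------------------------------------------------- roster

def read_roster(path: str | Path) -> DeterminantRoster:
    rows = _read_rows(path)
    header, body = rows[0], rows[1:]
    if [h.strip().lower() for h in header[:2]] != ["code", "label"]:
        raise MatrixParseError(f"{path}: expected header starting 'code,label'")
    entries = []
    for k, row in enumerate(body, start=2):
        try:
            code = int(row[0])
        except (ValueError, IndexError) as exc:
            raise MatrixParseError(f"{path}: row {k}: bad code {row[:1]}") from exc
        label = row[1] if len(row) > 1 else ""
        desc = row[2] if len(row) > 2 else ""
        src = row[3] if len(row) > 3 else ""
        entries.append(RosterEntry(code, label, desc, src))
    return DeterminantRoster(tuple(entries))


def write_roster(roster: DeterminantRoster, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "label", "description", "source_note"])
        for e in roster.entries:
            w.writerow([e.code, e.label, e.description, e.source_note])


# ----------------------------------------------------------- vote sheets

def read_votes(path: str | Path) -> list[VoteSheet]:
    """Read a voting-sheet CSV: ``factor_code,label,<expert_id>...``."""
    rows = _read_rows(path)
    header = rows[0]
    if header[0].strip().lower() != "factor_code":
        raise MatrixParseError(f"{path}: first header column must be 'factor_code'")
    expert_ids = tuple(h.strip() for h in header[2:])
    if not expert_ids:
        raise MatrixParseError(f"{path}: no expert columns found")
    sheets = []
    for k, row in enumerate(rows[1:], start=2):
        code = int(row[0])
        cells = [c.strip().lower() for c in row[2:]]
        if len(cells) != len(expert_ids):
            raise MatrixParseError(
                f"{path}: row {k}: {len(cells)} votes for {len(expert_ids)} experts"
            )
        votes = []
        for eid, c in zip(expert_ids, cells):
            if c in _TRUE:
                votes.append(True)
            elif c in _FALSE:
                votes.append(False)
            else:
                raise MatrixParseError(
                    f"{path}: row {k}, expert {eid}: unparseable vote {c!r}"
                )
        sheets.append(VoteSheet(factor_code=code, expert_ids=expert_ids, votes=tuple(votes)))
    return sheets


def write_votes(sheets: list[VoteSheet], roster: DeterminantRoster, path: str | Path) -> None:
    if not sheets:
        raise ValidationError("no vote sheets to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["factor_code", "label", *sheets[0].expert_ids])
        for s in sheets:
            w.writerow([s.factor_code, roster.label(s.factor_code), *(int(v) for v in s.votes)])


# ------------------------------------------------------------ judgments

def read_judgments(path: str | Path) -> list[ExpertJudgmentSet]:
    """Read long-form per-expert pair judgments; strict upper triangle."""
    rows = _read_rows(path)
    header = [h.strip().lower() for h in rows[0]]
    if header != ["expert_id", "row_code", "col_code", "symbol"]:
        raise MatrixParseError(
            f"{path}: expected header 'expert_id,row_code,col_code,symbol'"
        )
    per_expert: dict[str, dict[tuple[int, int], str]] = {}
    order: list[str] = []
    for k, row in enumerate(rows[1:], start=2):
        eid, i, j, sym = row[0].strip(), int(row[1]), int(row[2]), row[3].strip().upper()
        if i >= j:
            raise MatrixParseError(
                f"{path}: row {k}: pair ({i},{j}) not strict upper triangle"
            )
        if sym not in SYMBOLS:
            raise MatrixParseError(f"{path}: row {k}: unknown symbol {sym!r}")
        if eid not in per_expert:
            per_expert[eid] = {}
            order.append(eid)
        if (i, j) in per_expert[eid]:
            raise MatrixParseError(f"{path}: row {k}: duplicate pair ({i},{j}) for {eid}")
        per_expert[eid][(i, j)] = sym
    return [ExpertJudgmentSet(eid, per_expert[eid]) for eid in order]


def write_judgments(panel: list[ExpertJudgmentSet], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["expert_id", "row_code", "col_code", "symbol"])
        for ex in panel:
            for (i, j) in sorted(ex.judgments):
                w.writerow([ex.expert_id, i, j, ex.judgments[(i, j)]])


# ------------------------------------------------------------------ SSIM

def read_ssim(path: str | Path) -> SSIM:
    """Read a wide-form SSIM (codes on first row/column, letters in the
    upper triangle only)."""
    rows = _read_rows(path)
    header = rows[0]
    try:
        codes = tuple(int(c) for c in header[1:] if c.strip() != "")
    except ValueError as exc:
        raise MatrixParseError(f"{path}: non-integer code in header") from exc
    body = [r for r in rows[1:] if any(c.strip() for c in r)]
    if len(body) != len(codes):
        raise MatrixParseError(
            f"{path}: {len(body)} data rows for {len(codes)} header codes"
        )
    symbols: dict[tuple[int, int], str] = {}
    for r, row in enumerate(body):
        try:
            rcode = int(row[0])
        except ValueError as exc:
            raise MatrixParseError(f"{path}: row {r + 2}: bad row code {row[0]!r}") from exc
        if rcode != codes[r]:
            raise MatrixParseError(
                f"{path}: row {r + 2}: row code {rcode} != header code {codes[r]}"
            )
        for c, cell in enumerate(row[1:len(codes) + 1]):
            cell = cell.strip().upper()
            ccode = codes[c]
            if c <= r:
                if cell:
                    raise MatrixParseError(
                        f"{path}: cell ({rcode},{ccode}): upper triangle only, "
                        f"found {cell!r} on or below the diagonal"
                    )
                continue
            if cell not in SYMBOLS:
                raise MatrixParseError(
                    f"{path}: cell ({rcode},{ccode}): expected V/A/X/O, got {cell!r}"
                )
            symbols[(rcode, ccode)] = cell
    missing = sorted(set(upper_triangle_pairs(codes)) - set(symbols))
    if missing:
        raise MatrixParseError(f"{path}: missing upper-triangle pairs {missing}")
    return SSIM(codes=codes, symbols=symbols)


def write_ssim(ssim: SSIM, path: str | Path) -> None:
    n = ssim.n
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([""] + [str(c) for c in ssim.codes])
        for r, rcode in enumerate(ssim.codes):
            row = [str(rcode)]
            for c, ccode in enumerate(ssim.codes):
                row.append(ssim.symbols[(rcode, ccode)] if c > r else "")
            w.writerow(row)


# ---------------------------------------------------------------- matrix

_CELL_TO_TOKEN = {ABSENT: "0", DIRECT: "1", TRANSITIVE: "1*"}
_TOKEN_TO_CELL = {"0": ABSENT, "1": DIRECT, "1*": TRANSITIVE}


def read_matrix(path: str | Path, flavor: str = "as_given") -> ReachabilityMatrix:
    """Read a reachability matrix CSV (cells 0 / 1 / 1*).

    A zero diagonal cell is normalized to direct (self-reachability is a
    convention of the method) with a logged warning.
    """
    rows = _read_rows(path)
    header = rows[0]
    try:
        codes = tuple(int(c) for c in header[1:] if c.strip() != "")
    except ValueError as exc:
        raise MatrixParseError(f"{path}: non-integer code in header") from exc
    body = [r for r in rows[1:] if any(c.strip() for c in r)]
    if len(body) != len(codes):
        raise MatrixParseError(
            f"{path}: non-square: {len(body)} rows for {len(codes)} columns"
        )
    n = len(codes)
    cells = np.zeros((n, n), dtype=np.int8)
    for r, row in enumerate(body):
        if int(row[0]) != codes[r]:
            raise MatrixParseError(
                f"{path}: row {r + 2}: row code {row[0]!r} != header code {codes[r]}"
            )
        if len(row) < n + 1:
            raise MatrixParseError(f"{path}: row {r + 2}: expected {n} cells")
        for c in range(n):
            token = _normalize_minus(row[c + 1].strip())
            if token not in _TOKEN_TO_CELL:
                raise MatrixParseError(
                    f"{path}: cell ({codes[r]},{codes[c]}): expected 0/1/1*, got {token!r}"
                )
            cells[r, c] = _TOKEN_TO_CELL[token]
    fixed = [codes[i] for i in range(n) if cells[i, i] == ABSENT]
    if fixed:
        log.warning("%s: zero diagonal at %s normalized to direct", path, fixed)
        for i in range(n):
            if cells[i, i] == ABSENT:
                cells[i, i] = DIRECT
    return ReachabilityMatrix(codes=codes, cells=cells, flavor=flavor)


def write_matrix(m: ReachabilityMatrix, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([""] + [str(c) for c in m.codes])
        for r, rcode in enumerate(m.codes):
            w.writerow([str(rcode)] + [_CELL_TO_TOKEN[int(v)] for v in m.cells[r]])


# ------------------------------------------------------------------- DOT

def digraph_to_dot(d: StructuralDigraph) -> str:
    """Render the layered model as Graphviz DOT, one rank per level."""
    lines = ["digraph ism {", "  rankdir=BT;", "  node [shape=box];"]
    by_level: dict[int, list[int]] = {}
    for nid, lev in enumerate(d.node_levels):
        by_level.setdefault(lev, []).append(nid)
    for lev in sorted(by_level):
        lines.append(f"  subgraph level_{lev} {{")
        lines.append("    rank=same;")
        for nid in by_level[lev]:
            label = ",".join(str(c) for c in d.members[nid])
            lines.append(f'    n{nid} [label="{label}" xlabel="{to_roman(lev)}"];')
        lines.append("  }")
    for u, v in d.edges:
        lines.append(f"  n{u} -> n{v};")
    for i, j in d.mutual_pairs:
        lines.append(f'  // mutual influence: {i} <-> {j}')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_dot(d: StructuralDigraph, path: str | Path) -> None:
    Path(path).write_text(digraph_to_dot(d), encoding="utf-8")
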