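"""Markdown rendering of pipeline artifacts.

Tables are rendered in the conventional order of an ISM write-up: SSIM,
initial and final reachability matrices (with driving/dependence margins),
partitioning iterations, conical matrix, MICMAC summary, and — when an
audit was run — a closure-discrepancy ledger. Rendering is pure: the same
artifacts always produce the same text.
"""

from __future__ import annotations

import pandas as pd

from .engine import (
    ClosureAudit,
    ConicalMatrix,
    LevelPartition,
    PowerVector,
    ReachabilityMatrix,
    compute_powers,
    to_roman,
)
from .io import _CELL_TO_TOKEN
from .ssim import SSIM


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    out = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    out += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
    return "\n".join(out)


def ssim_markdown(ssim: SSIM) -> str:
    header = ["Code"] + [str(c) for c in ssim.codes]
    rows = []
    for r, rc in enumerate(ssim.codes):
        row = [str(rc)]
        for c, cc in enumerate(ssim.codes):
            row.append(ssim.symbols[(rc, cc)] if c > r else "")
        rows.append(row)
    return _md_table(header, rows)


def matrix_markdown(m: ReachabilityMatrix, margins: bool = True) -> str:
    powers: PowerVector | None = compute_powers(m) if margins else None
    header = ["Code"] + [str(c) for c in m.codes] + (["Driving"] if margins else [])
    rows = []
    for r, rc in enumerate(m.codes):
        row = [str(rc)] + [_CELL_TO_TOKEN[int(v)] for v in m.cells[r]]
        if powers:
            row.append(str(powers.driving[rc]))
        rows.append(row)
    if powers:
        rows.append(["Dependence"] + [str(powers.dependence[c]) for c in m.codes] + [""])
    return _md_table(header, rows)


def _fmt_set(s: frozenset[int]) -> str:
    return ",".join(str(c) for c in sorted(s))


def iterations_markdown(p: LevelPartition) -> str:
    blocks = []
    for it in range(1, p.depth + 1):
        recs = [r for r in p.trace if r.iteration == it]
        rows = [
            [
                str(r.code),
                _fmt_set(r.reachability),
                _fmt_set(r.antecedent),
                _fmt_set(r.intersection),
                to_roman(it) if r.leveled else "",
            ]
            for r in recs
        ]
        blocks.append(
            f"### Iteration {to_roman(it)}\n\n"
            + _md_table(
                ["Code", "Reachability set", "Antecedent set", "Intersection set", "Level"],
                rows,
            )
        )
    return "\n\n".join(blocks)


def conical_markdown(c: ConicalMatrix) -> str:
    header = ["Code"] + [str(x) for x in c.order]
    rows = [
        [str(rc)] + [_CELL_TO_TOKEN[int(v)] for v in c.cells[r]]
        for r, rc in enumerate(c.order)
    ]
    return _md_table(header, rows)


def summary_markdown(df: pd.DataFrame) -> str:
    header = list(df.columns)
    rows = [[str(v) for v in rec] for rec in df.itertuples(index=False)]
    return _md_table(header, rows)


def audit_markdown(a: ClosureAudit) -> str:
    lines = ["### Closure audit"]
    if a.consistent:
        lines.append("\nNo discrepancies: the as-given matrix matches both closures.")
    else:
        def cells(t):
            return ", ".join(f"({i},{j})" for i, j in t) or "none"

        lines += [
            "",
            f"- cells in as-given matrix unsupported by one-pass closure: "
            f"{cells(a.one_pass_unsupported)}",
            f"- cells added by one-pass closure but absent as given: "
            f"{cells(a.one_pass_missing)}",
            f"- cells in as-given matrix unsupported by full closure: "
            f"{cells(a.full_unsupported)}",
            f"- cells added by full closure but absent as given: "
            f"{cells(a.full_missing)}",
        ]
    lines.append("\nLevel partitions by closure mode:")
    for mode, levels in a.levels_by_mode.items():
        if isinstance(levels, str):
            lines.append(f"- {mode}: {levels}")
        else:
            desc = "; ".join(
                f"{to_roman(k)}={{{','.join(map(str, lev))}}}"
                for k, lev in enumerate(levels, start=1)
            )
            lines.append(f"- {mode}: {desc}")
    return "\n".join(lines)
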