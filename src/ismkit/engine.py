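"""Core ISM computations.

Implements the classical interpretive-structural-modeling chain:
SSIM → initial reachability matrix → transitive closure (with explicit
modes) → driving/dependence powers → level partitioning by iterated
top-element removal → conical (level-ordered) matrix → level-layered
structural digraph.

Cell provenance is kept throughout: a cell is *direct* (asserted by the
experts), *transitive* (added by closure, conventionally printed ``1*``),
or *absent*. The diagonal is always direct (every factor reaches itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import StallError, ValidationError
from .ssim import SSIM

ABSENT, DIRECT, TRANSITIVE = 0, 1, 2

_ROMAN = (
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def to_roman(k: int) -> str:
    """Roman numeral for a small positive level index."""
    if k < 1:
        raise ValueError(f"level index must be >= 1, got {k}")
    out = []
    for val, sym in _ROMAN:
        while k >= val:
            out.append(sym)
            k -= val
    return "".join(out)


@dataclass
class ReachabilityMatrix:
    """Square binary relation over the roster with per-cell provenance.

    ``cells[a, b]`` is one of :data:`ABSENT`, :data:`DIRECT`,
    :data:`TRANSITIVE`; positions follow ``codes`` order. ``flavor`` records
    how the matrix was obtained: ``initial`` (decoded straight from an
    SSIM), ``as_given`` (loaded from a published/edited file), ``one_pass``
    (length-2 compositions added once) or ``full_closure`` (reflexive-
    transitive closure).
    """

    codes: tuple[int, ...]
    cells: np.ndarray
    flavor: str = "initial"

    def __post_init__(self) -> None:
        self.codes = tuple(int(c) for c in self.codes)
        self.cells = np.asarray(self.cells, dtype=np.int8)
        n = len(self.codes)
        if self.cells.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.cells.shape} does not match {n} codes"
            )
        if not np.isin(self.cells, (ABSENT, DIRECT, TRANSITIVE)).all():
            raise ValidationError("matrix cells must be absent/direct/transitive")
        if not (np.diag(self.cells) == DIRECT).all():
            raise ValidationError("diagonal must be direct (self-reachability)")

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def binary(self) -> np.ndarray:
        """0/1 view: direct or transitive → 1."""
        return (self.cells != ABSENT).astype(np.int8)

    def index(self, code: int) -> int:
        return self.codes.index(code)

    def __getitem__(self, pair: tuple[int, int]) -> int:
        i, j = pair
        return int(self.cells[self.index(i), self.index(j)])

    def reaches(self, i: int, j: int) -> bool:
        return self[i, j] != ABSENT

    def copy(self, flavor: str | None = None) -> "ReachabilityMatrix":
        return ReachabilityMatrix(
            self.codes, self.cells.copy(), flavor or self.flavor
        )

    def to_digraph(self) -> nx.DiGraph:
        """Binary relation as a networkx digraph (self-loops omitted)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.codes)
        b = self.binary
        for a, i in enumerate(self.codes):
            for c, j in enumerate(self.codes):
                if a != c and b[a, c]:
                    g.add_edge(i, j)
        return g


def ssim_to_initial_rm(ssim: SSIM) -> ReachabilityMatrix:
    """Decode the SSIM symbols into the initial (direct) reachability matrix.

    For each upper-triangle pair (i, j): V → i reaches j; A → j reaches i;
    X → both; O → neither. The diagonal is set to direct.
    """
    n = ssim.n
    cells = np.zeros((n, n), dtype=np.int8)
    np.fill_diagonal(cells, DIRECT)
    pos = {c: k for k, c in enumerate(ssim.codes)}
    for (i, j), sym in ssim.symbols.items():
        a, b = pos[i], pos[j]
        if sym == "V":
            cells[a, b] = DIRECT
        elif sym == "A":
            cells[b, a] = DIRECT
        elif sym == "X":
            cells[a, b] = DIRECT
            cells[b, a] = DIRECT
        # O: leave both absent
    return ReachabilityMatrix(ssim.codes, cells, flavor="initial")


def transitive_closure(m: ReachabilityMatrix, mode: str = "full") -> ReachabilityMatrix:
    """Apply transitivity to the binary view under an explicit mode.

    ``full``
        Reflexive-transitive closure to a fixed point (Warshall semantics).
    ``one_pass``
        Add exactly the length-2 compositions: binary view of M ∨ M·M.
        This is the single sweep many desk ISM studies perform by hand.
    ``as_given``
        Return the matrix unchanged (trust the provided 1*/1 cells).

    Cells already direct are never downgraded; every newly reachable cell
    is marked transitive.
    """
    if mode == "as_given":
        return m.copy(flavor="as_given")
    b = m.binary.astype(bool)
    if mode == "full":
        closed = b.copy()
        n = m.n
        for k in range(n):  # Warshall: pivot on intermediate vertex k
            closed |= np.outer(closed[:, k], closed[k, :])
    elif mode == "one_pass":
        closed = b | ((b.astype(np.int16) @ b.astype(np.int16)) > 0)
    else:
        raise ValidationError(f"unknown closure mode {mode!r}")
    cells = np.where(closed, np.where(m.cells == DIRECT, DIRECT, TRANSITIVE), ABSENT)
    flavor = "full_closure" if mode == "full" else "one_pass"
    return ReachabilityMatrix(m.codes, cells.astype(np.int8), flavor=flavor)


@dataclass(frozen=True)
class PowerVector:
    """Driving (row-sum) and dependence (column-sum) powers, diagonal included."""

    codes: tuple[int, ...]
    driving: dict[int, int]
    dependence: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.driving.values())


def compute_powers(m: ReachabilityMatrix) -> PowerVector:
    """Row and column sums of the binary view (each includes the diagonal)."""
    b = m.binary
    return PowerVector(
        codes=m.codes,
        driving={c: int(b[k].sum()) for k, c in enumerate(m.codes)},
        dependence={c: int(b[:, k].sum()) for k, c in enumerate(m.codes)},
    )


@dataclass(frozen=True)
class IterationRecord:
    """Set triple of one factor in one partitioning iteration."""

    iteration: int
    code: int
    reachability: frozenset[int]
    antecedent: frozenset[int]
    intersection: frozenset[int]
    leveled: bool


@dataclass(frozen=True)
class LevelPartition:
    """Ordered level assignment; Level 1 ("I") is the top of the model."""

    levels: tuple[tuple[int, ...], ...]  # each level: ascending codes
    trace: tuple[IterationRecord, ...]

    @property
    def depth(self) -> int:
        return len(self.levels)

    def level_of(self, code: int) -> int:
        for k, lev in enumerate(self.levels, start=1):
            if code in lev:
                return k
        raise KeyError(code)

    def roman_of(self, code: int) -> str:
        return to_roman(self.level_of(code))

    def as_dict(self) -> dict[str, tuple[int, ...]]:
        return {to_roman(k): lev for k, lev in enumerate(self.levels, start=1)}


def partition_levels(m: ReachabilityMatrix) -> LevelPartition:
    """Partition factors into levels by iterated top-element removal.

    Each iteration computes, for every remaining factor, its reachability,
    antecedent and intersection sets restricted to the remaining factors; a
    factor whose reachability set equals the intersection is a current top
    element and is assigned the next level, then removed. On a matrix that
    is not transitively closed an iteration can level nothing, in which
    case a :class:`~ismkit.errors.StallError` is raised rather than looping.
    """
    b = m.binary.astype(bool)
    pos = {c: k for k, c in enumerate(m.codes)}
    remaining = list(m.codes)
    levels: list[tuple[int, ...]] = []
    trace: list[IterationRecord] = []
    it = 0
    while remaining:
        it += 1
        leveled_now: list[int] = []
        for c in remaining:
            i = pos[c]
            reach = frozenset(d for d in remaining if b[i, pos[d]])
            ante = frozenset(d for d in remaining if b[pos[d], i])
            inter = reach & ante
            leveled = reach == inter
            trace.append(IterationRecord(it, c, reach, ante, inter, leveled))
            if leveled:
                leveled_now.append(c)
        if not leveled_now:
            raise StallError(tuple(remaining))
        levels.append(tuple(sorted(leveled_now)))
        remaining = [c for c in remaining if c not in leveled_now]
    return LevelPartition(levels=tuple(levels), trace=tuple(trace))


@dataclass(frozen=True)
class ConicalMatrix:
    """Reachability matrix symmetrically permuted into level order."""

    order: tuple[int, ...]  # codes sorted by (level asc, code asc)
    cells: np.ndarray
    levels: tuple[tuple[int, ...], ...]

    @property
    def binary(self) -> np.ndarray:
        return (self.cells != ABSENT).astype(np.int8)


def build_conical_matrix(m: ReachabilityMatrix, p: LevelPartition) -> ConicalMatrix:
    """Permute rows/columns so Level I factors come first, codes ascending
    within a level; provenance marks are carried through."""
    covered = {c for lev in p.levels for c in lev}
    if covered != set(m.codes):
        raise ValidationError(
            f"partition covers {sorted(covered)} but matrix has {sorted(m.codes)}"
        )
    order = [c for lev in p.levels for c in sorted(lev)]
    idx = [m.codes.index(c) for c in order]
    cells = m.cells[np.ix_(idx, idx)]
    return ConicalMatrix(order=tuple(order), cells=cells, levels=p.levels)


@dataclass(frozen=True)
class StructuralDigraph:
    """Level-layered model graph.

    Nodes are strongly connected components of the binary relation (so the
    skeleton is acyclic); edges are the transitive reduction of the SCC
    condensation. Mutual influence inside an SCC is kept as bidirectional
    decoration pairs for rendering.
    """

    members: tuple[tuple[int, ...], ...]  # SCC node id -> sorted member codes
    edges: tuple[tuple[int, int], ...]  # reduced condensation edges (node ids)
    node_levels: tuple[int, ...]  # node id -> level index (1 = top)
    mutual_pairs: tuple[tuple[int, int], ...]  # intra-SCC factor pairs

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, mem in enumerate(self.members):
            g.add_node(nid, members=mem, level=self.node_levels[nid])
        g.add_edges_from(self.edges)
        return g


def build_digraph(m: ReachabilityMatrix, p: LevelPartition) -> StructuralDigraph:
    """Condense SCCs, transitively reduce the condensation, attach levels."""
    g = m.to_digraph()
    sccs = [tuple(sorted(s)) for s in nx.strongly_connected_components(g)]
    sccs.sort(key=lambda mem: mem[0])
    node_of = {c: nid for nid, mem in enumerate(sccs) for c in mem}
    cond = nx.DiGraph()
    cond.add_nodes_from(range(len(sccs)))
    for u, v in g.edges():
        a, b = node_of[u], node_of[v]
        if a != b:
            cond.add_edge(a, b)
    reduced = nx.transitive_reduction(cond)
    mutual = tuple(
        (i, j)
        for mem in sccs
        for ai, i in enumerate(mem)
        for j in mem[ai + 1:]
        if m.reaches(i, j) and m.reaches(j, i)
    )
    # an SCC of an as-given (non-closed) matrix can straddle partition
    # levels; the node is ranked at its topmost member's level
    node_levels = tuple(min(p.level_of(c) for c in mem) for mem in sccs)
    return StructuralDigraph(
        members=tuple(sccs),
        edges=tuple(sorted(reduced.edges())),
        node_levels=node_levels,
        mutual_pairs=mutual,
    )


@dataclass(frozen=True)
class ClosureAudit:
    """Cell-level comparison of a published matrix against recomputed closures.

    ``*_unsupported`` lists cells asserted in the published (as-given)
    matrix but absent from the recomputed closure of the base matrix;
    ``*_missing`` lists cells the closure adds that the published matrix
    lacks. Level partitions (or the stall residual) under each mode are
    reported side by side so a discrepancy is documented, never silently
    repaired.
    """

    one_pass_unsupported: tuple[tuple[int, int], ...]
    one_pass_missing: tuple[tuple[int, int], ...]
    full_unsupported: tuple[tuple[int, int], ...]
    full_missing: tuple[tuple[int, int], ...]
    levels_by_mode: dict[str, tuple[tuple[int, ...], ...] | str]

    @property
    def consistent(self) -> bool:
        return not (
            self.one_pass_unsupported
            or self.one_pass_missing
            or self.full_unsupported
            or self.full_missing
        )


def _cell_diff(
    a: ReachabilityMatrix, b: ReachabilityMatrix
) -> tuple[tuple[int, int], ...]:
    """Cells set in ``a`` but not in ``b`` (code pairs, row-major order)."""
    da, db = a.binary, b.binary
    return tuple(
        (a.codes[i], a.codes[j])
        for i in range(a.n)
        for j in range(a.n)
        if da[i, j] and not db[i, j]
    )


def audit_closure_consistency(
    as_given: ReachabilityMatrix, base: ReachabilityMatrix
) -> ClosureAudit:
    """Compare an as-given final matrix with one_pass/full closures of ``base``."""
    if as_given.codes != base.codes:
        raise ValidationError("as_given and base matrices index different rosters")
    one = transitive_closure(base, mode="one_pass")
    full = transitive_closure(base, mode="full")
    levels: dict[str, tuple[tuple[int, ...], ...] | str] = {}
    for name, mat in (("as_given", as_given), ("one_pass", one), ("full", full)):
        try:
            levels[name] = partition_levels(mat).levels
        except StallError as exc:
            levels[name] = f"stalled on residual {list(exc.residual)}"
    return ClosureAudit(
        one_pass_unsupported=_cell_diff(as_given, one),
        one_pass_missing=_cell_diff(one, as_given),
        full_unsupported=_cell_diff(as_given, full),
        full_missing=_cell_diff(full, as_given),
        levels_by_mode=levels,
    )
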