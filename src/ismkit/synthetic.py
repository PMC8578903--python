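"""Ground-truthed synthetic hierarchies and noisy expert panels.

The generator emulates the elicitation design of a desk-scale ISM study: a
latent leveled hierarchy of ``n`` factors, its direct influence relation
(every factor one level below the top drives at least one factor on the
next level up, plus optional extra cross-level edges and within-level
mutual pairs), its V/A/X/O encoding, and a panel of ``E`` experts who each
report the true symbol of a pair with probability ``p`` and otherwise one
of the three wrong symbols uniformly at random.

Ground-truth levels are defined as the longest-path-to-sink strata of the
SCC condensation of the direct relation — exactly the quantity ISM level
partitioning computes on a transitively closed matrix, so noise-free
recovery is a construction guarantee, not an empirical hope.

Defaults mirror the packaged case study's scale: 11 factors, 4 levels,
10 experts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .engine import partition_levels, ssim_to_initial_rm, transitive_closure
from .errors import ValidationError
from .roster import ExpertJudgmentSet, aggregate_judgments
from .ssim import SSIM, SYMBOLS, upper_triangle_pairs


@dataclass(frozen=True)
class HierarchySpec:
    """Parameters of one synthetic study."""

    n: int = 11
    level_count: int = 4
    extra_edge_prob: float = 0.25
    mutual_pair_prob: float = 0.2
    expert_count: int = 10
    agreement_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"need n >= 2, got {self.n}")
        if not (1 <= self.level_count <= self.n):
            raise ValidationError(
                f"level_count must be in 1..{self.n}, got {self.level_count}"
            )
        for name in ("extra_edge_prob", "mutual_pair_prob", "agreement_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.expert_count < 1:
            raise ValidationError("need at least one expert")


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated hierarchy with everything the pipeline should recover."""

    spec: HierarchySpec
    levels: tuple[tuple[int, ...], ...]  # level 1 = top (sinks)
    relation: frozenset[tuple[int, int]]  # direct edges i -> j, i != j
    ssim: SSIM
    panel: tuple[ExpertJudgmentSet, ...]

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(range(1, self.spec.n + 1))

    def level_of(self, code: int) -> int:
        for k, lev in enumerate(self.levels, start=1):
            if code in lev:
                return k
        raise KeyError(code)


def _assign_levels(rng: np.random.Generator, n: int, level_count: int) -> list[int]:
    """Per-code level index (1 = top), every level non-empty."""
    lev = list(range(1, level_count + 1))
    lev += list(rng.integers(1, level_count + 1, size=n - level_count))
    rng.shuffle(lev)
    return lev


def generate_hierarchy(spec: HierarchySpec) -> SyntheticTruth:
    """Draw a leveled influence structure, encode it, and simulate the panel."""
    rng = np.random.default_rng(spec.seed)
    codes = tuple(range(1, spec.n + 1))
    level_of = dict(zip(codes, _assign_levels(rng, spec.n, spec.level_count)))

    edges: set[tuple[int, int]] = set()
    # guarantee the strata: every factor below the top drives >= 1 factor
    # exactly one level up
    for c in codes:
        k = level_of[c]
        if k > 1:
            above = [d for d in codes if level_of[d] == k - 1]
            edges.add((c, int(rng.choice(above))))
    # optional extra downward-in-level edges (toward the top of the model)
    for u in codes:
        for v in codes:
            if level_of[v] < level_of[u] and (u, v) not in edges:
                if rng.random() < spec.extra_edge_prob:
                    edges.add((u, v))
    # optional mutual pairs between code-adjacent factors of the same level
    for lev in range(1, spec.level_count + 1):
        members = sorted(c for c in codes if level_of[c] == lev)
        for a, b in zip(members, members[1:]):
            if rng.random() < spec.mutual_pair_prob:
                edges.add((a, b))
                edges.add((b, a))

    levels = tuple(
        tuple(sorted(c for c in codes if level_of[c] == k))
        for k in range(1, spec.level_count + 1)
    )
    ssim = encode_relation(codes, edges)
    panel = simulate_expert_panel_from_ssim(
        ssim, spec.expert_count, spec.agreement_prob, rng
    )
    return SyntheticTruth(
        spec=spec,
        levels=levels,
        relation=frozenset(edges),
        ssim=ssim,
        panel=tuple(panel),
    )


def encode_relation(
    codes: tuple[int, ...], relation: set[tuple[int, int]] | frozenset[tuple[int, int]]
) -> SSIM:
    """Encode a direct relation as V/A/X/O over the upper triangle."""
    symbols = {}
    for i, j in upper_triangle_pairs(codes):
        fwd, back = (i, j) in relation, (j, i) in relation
        symbols[(i, j)] = "X" if (fwd and back) else "V" if fwd else "A" if back else "O"
    return SSIM(codes=codes, symbols=symbols)


def encode_ssim(truth: SyntheticTruth) -> SSIM:
    """The SSIM of a generated truth (identical to ``truth.ssim``)."""
    return encode_relation(truth.codes, truth.relation)


def simulate_expert_panel_from_ssim(
    ssim: SSIM, expert_count: int, agreement_prob: float, rng: np.random.Generator
) -> list[ExpertJudgmentSet]:
    """Each expert reports the true symbol w.p. ``p``, else a uniformly
    random wrong symbol."""
    panel = []
    pairs = sorted(ssim.symbols)
    for e in range(expert_count):
        judgments = {}
        for pair in pairs:
            true_sym = ssim.symbols[pair]
            if rng.random() < agreement_prob:
                judgments[pair] = true_sym
            else:
                wrong = [s for s in SYMBOLS if s != true_sym]
                judgments[pair] = wrong[int(rng.integers(len(wrong)))]
        panel.append(ExpertJudgmentSet(expert_id=f"expert_{e + 1}", judgments=judgments))
    return panel


def simulate_expert_panel(
    truth: SyntheticTruth, expert_count: int, agreement_prob: float, seed: int
) -> list[ExpertJudgmentSet]:
    """Fresh noisy panel for an existing truth, reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    return simulate_expert_panel_from_ssim(truth.ssim, expert_count, agreement_prob, rng)


def oracle_strata(codes: tuple[int, ...], relation: frozenset[tuple[int, int]]) -> tuple[tuple[int, ...], ...]:
    """Longest-path-to-sink strata of the SCC condensation (brute force).

    Independent reference for what level partitioning should recover on a
    closed matrix: stratum 1 holds the condensation sinks, stratum k holds
    nodes whose longest path to a sink has k−1 edges.
    """
    g = nx.DiGraph()
    g.add_nodes_from(codes)
    g.add_edges_from(relation)
    cond = nx.condensation(g)
    depth: dict[int, int] = {}
    for nid in reversed(list(nx.topological_sort(cond))):
        succ = list(cond.successors(nid))
        depth[nid] = 1 if not succ else 1 + max(depth[s] for s in succ)
    strata: dict[int, list[int]] = {}
    for nid, members in cond.nodes(data="members"):
        strata.setdefault(depth[nid], []).extend(members)
    return tuple(
        tuple(sorted(strata[k])) for k in range(1, max(strata) + 1)
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Monte-Carlo recovery rates of the full pipeline on synthetic truths."""

    reps: int
    level_recovery_fraction: float
    ssim_recovery_fraction: float
    per_rep: tuple[tuple[bool, bool], ...] = field(repr=False)  # (levels_ok, ssim_ok)


def recovery_experiment(spec: HierarchySpec, reps: int) -> RecoveryReport:
    """Generate ``reps`` studies and run the full pipeline on each.

    Per repetition: generate a truth, aggregate its (possibly noisy) expert
    panel into an SSIM, decode, take the full transitive closure, partition
    levels, and compare with the generated strata; also record whether
    aggregation recovered the true SSIM exactly.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    outcomes = []
    for r in range(reps):
        sub = HierarchySpec(
            n=spec.n,
            level_count=spec.level_count,
            extra_edge_prob=spec.extra_edge_prob,
            mutual_pair_prob=spec.mutual_pair_prob,
            expert_count=spec.expert_count,
            agreement_prob=spec.agreement_prob,
            seed=(spec.seed + 1) * 100_003 % (2**31) + r,
        )
        truth = generate_hierarchy(sub)
        agg_ssim, _ = aggregate_judgments(list(truth.panel), truth.codes)
        rm = transitive_closure(ssim_to_initial_rm(agg_ssim), mode="full")
        levels_ok = partition_levels(rm).levels == truth.levels
        ssim_ok = agg_ssim == truth.ssim
        outcomes.append((levels_ok, ssim_ok))
    return RecoveryReport(
        reps=reps,
        level_recovery_fraction=sum(o[0] for o in outcomes) / reps,
        ssim_recovery_fraction=sum(o[1] for o in outcomes) / reps,
        per_rep=tuple(outcomes),
    )
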