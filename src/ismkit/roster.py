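"""Factor roster ratification and expert-judgment aggregation.

An ISM study starts from a candidate list of factors (the roster). A panel
of experts first votes each factor in or out (ratification), then every
expert fills the upper triangle of pairwise V/A/X/O judgments; the panel's
judgments are aggregated pair-by-pair by majority into a single SSIM.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ElicitationError, TieError, ValidationError
from .ssim import SSIM, SYMBOL_PRIORITY, SYMBOLS, upper_triangle_pairs


@dataclass(frozen=True)
class RosterEntry:
    code: int
    label: str
    description: str = ""
    source_note: str = ""


@dataclass(frozen=True)
class DeterminantRoster:
    """Ordered, coded list of candidate factors.

    Codes must be unique and contiguous from 1 to n; every downstream
    matrix is indexed by these codes.
    """

    entries: tuple[RosterEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(e.code for e in self.entries)

    @property
    def n(self) -> int:
        return len(self.entries)

    def label(self, code: int) -> str:
        for e in self.entries:
            if e.code == code:
                return e.label
        raise KeyError(code)

    def subset(self, codes: set[int]) -> "DeterminantRoster":
        """New roster keeping only ``codes``, re-coded contiguously 1..k."""
        kept = [e for e in self.entries if e.code in codes]
        renum = [
            RosterEntry(i + 1, e.label, e.description, e.source_note)
            for i, e in enumerate(kept)
        ]
        return DeterminantRoster(tuple(renum))


@dataclass(frozen=True)
class RosterValidationReport:
    valid: bool
    n: int
    problems: tuple[str, ...]


def validate_roster(roster: DeterminantRoster) -> RosterValidationReport:
    """Report duplicate codes, gaps in 1..n, and empty labels."""
    problems: list[str] = []
    codes = roster.codes
    n = len(codes)
    if n < 2:
        problems.append(f"roster has {n} entries; at least 2 required")
    dupes = sorted(c for c, k in Counter(codes).items() if k > 1)
    if dupes:
        problems.append(f"duplicate codes: {dupes}")
    expected = set(range(1, n + 1))
    if set(codes) != expected:
        gaps = sorted(expected - set(codes))
        strays = sorted(set(codes) - expected)
        problems.append(f"codes not contiguous 1..{n}: missing {gaps}, unexpected {strays}")
    empty = [e.code for e in roster.entries if not e.label.strip()]
    if empty:
        problems.append(f"empty labels at codes: {empty}")
    return RosterValidationReport(valid=not problems, n=n, problems=tuple(problems))


@dataclass(frozen=True)
class VoteSheet:
    """Per-factor inclusion votes of the ratification panel."""

    factor_code: int
    expert_ids: tuple[str, ...]
    votes: tuple[bool, ...]  # aligned with expert_ids

    def __post_init__(self) -> None:
        object.__setattr__(self, "expert_ids", tuple(self.expert_ids))
        object.__setattr__(self, "votes", tuple(bool(v) for v in self.votes))
        if len(self.expert_ids) != len(self.votes):
            raise ValidationError(
                f"factor {self.factor_code}: {len(self.votes)} votes for "
                f"{len(self.expert_ids)} experts"
            )
        if len(set(self.expert_ids)) != len(self.expert_ids):
            raise ValidationError(f"factor {self.factor_code}: duplicate expert ids")

    @property
    def yes_count(self) -> int:
        return sum(self.votes)

    @property
    def no_count(self) -> int:
        return len(self.votes) - self.yes_count


@dataclass(frozen=True)
class RatificationResult:
    included_codes: frozenset[int]
    tallies: dict[int, tuple[int, int]]  # code -> (yes, no)
    tie_flags: frozenset[int]
    rule_used: str


def ratify_determinants(
    sheets: list[VoteSheet], tie_policy: str = "include"
) -> RatificationResult:
    """Include every factor whose yes votes exceed its no votes.

    A tied factor is included, excluded, or raises, per ``tie_policy``
    (``include`` | ``exclude`` | ``error``); ties are always flagged.
    """
    if tie_policy not in ("include", "exclude", "error"):
        raise ValidationError(f"unknown tie_policy {tie_policy!r}")
    if not sheets:
        raise ElicitationError("no vote sheets supplied")
    panel = sheets[0].expert_ids
    if not panel:
        raise ElicitationError("empty expert panel")
    for s in sheets:
        if s.expert_ids != panel:
            raise ValidationError(
                f"factor {s.factor_code}: expert panel differs from the other sheets"
            )
    codes = [s.factor_code for s in sheets]
    if len(set(codes)) != len(codes):
        raise ValidationError("duplicate factor codes across vote sheets")

    included: set[int] = set()
    tallies: dict[int, tuple[int, int]] = {}
    ties: set[int] = set()
    for s in sheets:
        tallies[s.factor_code] = (s.yes_count, s.no_count)
        if s.yes_count > s.no_count:
            included.add(s.factor_code)
        elif s.yes_count == s.no_count:
            ties.add(s.factor_code)
            if tie_policy == "error":
                raise TieError(
                    f"ratification tie ({s.yes_count}-{s.no_count}) on factor "
                    f"{s.factor_code}"
                )
            if tie_policy == "include":
                included.add(s.factor_code)
    return RatificationResult(
        included_codes=frozenset(included),
        tallies=tallies,
        tie_flags=frozenset(ties),
        rule_used=f"majority-yes, ties {tie_policy}d" if tie_policy != "error" else "majority-yes, ties error",
    )


@dataclass(frozen=True)
class ExpertJudgmentSet:
    """One expert's complete upper triangle of V/A/X/O pair judgments."""

    expert_id: str
    judgments: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "judgments", dict(self.judgments))
        for (i, j), sym in self.judgments.items():
            if i >= j:
                raise ValidationError(
                    f"expert {self.expert_id}: pair ({i},{j}) is not strict "
                    "upper triangle (row < col required)"
                )
            if sym not in SYMBOLS:
                raise ValidationError(
                    f"expert {self.expert_id}: pair ({i},{j}) has unknown symbol {sym!r}"
                )


@dataclass(frozen=True)
class AggregationTally:
    """Per-pair symbol counts across the panel and the winning symbol."""

    pair: tuple[int, int]
    counts: dict[str, int]
    winner: str
    majority_kind: str  # absolute | plurality | tie
    tied_symbols: tuple[str, ...] = field(default=())


def aggregate_judgments(
    panel: list[ExpertJudgmentSet],
    codes: tuple[int, ...],
    tie_policy: str = "priority_order",
    priority: tuple[str, ...] = SYMBOL_PRIORITY,
) -> tuple[SSIM, list[AggregationTally]]:
    """Aggregate per-expert pair judgments into one SSIM by plurality.

    For each pair the most frequent symbol wins. ``majority_kind`` is
    ``absolute`` when the winner's count exceeds half the panel,
    ``plurality`` otherwise, and ``tie`` when the top count is shared; tied
    pairs are resolved per ``tie_policy``:

    - ``priority_order`` — highest-priority tied symbol wins (default
      X > V > A > O: an asserted relation beats "no relation");
    - ``flag`` — same resolution, but only flagged, no error;
    - ``error`` — raise :class:`TieError` naming the pair.
    """
    if tie_policy not in ("error", "priority_order", "flag"):
        raise ValidationError(f"unknown tie_policy {tie_policy!r}")
    if not panel:
        raise ElicitationError("empty expert panel")
    if sorted(priority) != sorted(SYMBOLS):
        raise ValidationError(f"priority must permute {SYMBOLS}, got {priority}")
    expected = set(upper_triangle_pairs(codes))
    for ex in panel:
        missing = sorted(expected - set(ex.judgments))
        extra = sorted(set(ex.judgments) - expected)
        if missing or extra:
            raise ValidationError(
                f"expert {ex.expert_id}: incomplete triangle, missing {missing}, "
                f"unexpected {extra}"
            )

    E = len(panel)
    symbols: dict[tuple[int, int], str] = {}
    tallies: list[AggregationTally] = []
    for pair in upper_triangle_pairs(codes):
        counts = Counter(ex.judgments[pair] for ex in panel)
        top = max(counts.values())
        tied = tuple(s for s in priority if counts.get(s, 0) == top)
        if len(tied) > 1:
            if tie_policy == "error":
                raise TieError(
                    f"aggregation tie on pair {pair}: symbols {list(tied)} each "
                    f"have {top} of {E} votes"
                )
            winner = tied[0]  # highest priority among the tied symbols
            kind = "tie"
        else:
            winner = tied[0]
            kind = "absolute" if top * 2 > E else "plurality"
        symbols[pair] = winner
        tallies.append(
            AggregationTally(
                pair=pair,
                counts={s: counts.get(s, 0) for s in SYMBOLS},
                winner=winner,
                majority_kind=kind,
                tied_symbols=tied if len(tied) > 1 else (),
            )
        )
    return SSIM(codes=tuple(codes), symbols=symbols), tallies
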