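"""MICMAC driving–dependence classification.

MICMAC (cross-impact matrix multiplication applied to classification) plots
each factor at (dependence power, driving power) and, under the
scale-centric convention, splits the plane at half the factor count into
four quadrants:

    independent — high driving, low dependence (critical drivers)
    dependent   — low driving, high dependence (driven outcomes)
    linkage     — both high (unstable, relay factors)
    autonomous  — both low (weakly coupled)

"High" means strictly greater than the boundary (default n/2). The net
influence of a factor is driving − dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .engine import LevelPartition, PowerVector
from .errors import ValidationError
from .roster import DeterminantRoster

QUADRANTS = ("independent", "dependent", "linkage", "autonomous")


@dataclass(frozen=True)
class MicmacConfig:
    n: int
    boundary: float | None = None  # default n/2

    def __post_init__(self) -> None:
        b = self.effective_boundary
        if not (0 < b < self.n):
            raise ValidationError(f"boundary {b} outside (0, {self.n})")

    @property
    def effective_boundary(self) -> float:
        return self.n / 2 if self.boundary is None else self.boundary


@dataclass(frozen=True)
class MicmacPoint:
    code: int
    driving: int
    dependence: int


@dataclass(frozen=True)
class MicmacResult:
    points: tuple[MicmacPoint, ...]
    quadrants: dict[int, str]  # code -> quadrant label
    config: MicmacConfig

    def net_influences(self) -> dict[int, int]:
        return {p.code: net_influence(p) for p in self.points}


def net_influence(point: MicmacPoint) -> int:
    """Driving power minus dependence power (the factor's net push on the system)."""
    return point.driving - point.dependence


def classify_point(point: MicmacPoint, config: MicmacConfig) -> str:
    """Quadrant of one (driving, dependence) coordinate; high means
    strictly greater than the boundary."""
    b = config.effective_boundary
    hi_drive, hi_dep = point.driving > b, point.dependence > b
    if hi_drive and hi_dep:
        return "linkage"
    if hi_drive:
        return "independent"
    if hi_dep:
        return "dependent"
    return "autonomous"


def classify_factors(powers: PowerVector, config: MicmacConfig) -> MicmacResult:
    """Label every factor of an n-factor system with its MICMAC quadrant."""
    if config.n != len(powers.codes):
        raise ValidationError(
            f"config.n={config.n} but powers cover {len(powers.codes)} factors"
        )
    points = tuple(
        MicmacPoint(c, powers.driving[c], powers.dependence[c]) for c in powers.codes
    )
    quadrants = {p.code: classify_point(p, config) for p in points}
    return MicmacResult(points=points, quadrants=quadrants, config=config)


def key_factors(partition: LevelPartition, micmac: MicmacResult) -> frozenset[int]:
    """Factors at the deepest (bottom) level that are classified independent."""
    bottom = partition.levels[-1]
    return frozenset(c for c in bottom if micmac.quadrants[c] == "independent")


def summarize(
    roster: DeterminantRoster,
    partition: LevelPartition,
    micmac: MicmacResult,
) -> pd.DataFrame:
    """One row per factor: powers, net influence, quadrant, level, key flag.

    Column order follows the conventional juxtaposed-results layout:
    code, label, driving, dependence, effectiveness, cluster, level, comment.
    """
    mic_codes = {p.code for p in micmac.points}
    part_codes = {c for lev in partition.levels for c in lev}
    if mic_codes != set(roster.codes) or part_codes != set(roster.codes):
        raise ValidationError("roster, partition and MICMAC results index different factors")
    keys = key_factors(partition, micmac)
    by_code = {p.code: p for p in micmac.points}
    rows = []
    for code in roster.codes:
        p = by_code[code]
        rows.append(
            {
                "code": code,
                "label": roster.label(code),
                "driving": p.driving,
                "dependence": p.dependence,
                "effectiveness": net_influence(p),
                "cluster": micmac.quadrants[code].capitalize(),
                "level": partition.roman_of(code),
                "comment": "Key factor" if code in keys else "",
            }
        )
    return pd.DataFrame(rows)
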