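"""Structural self-interaction matrix (SSIM).

The SSIM is the standard elicitation artifact of interpretive structural
modeling: for every unordered factor pair (i, j) with i < j a single symbol
records the contextual relation ("leads to"):

    V  — row i leads to column j
    A  — column j leads to row i
    X  — i and j lead to each other
    O  — no relation between i and j

Only the strict upper triangle is stored; the lower triangle is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import ValidationError

SYMBOLS = ("V", "A", "X", "O")

#: Default tie-break priority for aggregation: any asserted relation beats
#: "no relation", and the mutual relation beats the one-directional ones.
SYMBOL_PRIORITY = ("X", "V", "A", "O")


def upper_triangle_pairs(codes: tuple[int, ...]) -> Iterator[tuple[int, int]]:
    """Yield all (i, j) code pairs with i before j in roster order."""
    for a in range(len(codes)):
        for b in range(a + 1, len(codes)):
            yield codes[a], codes[b]


@dataclass(frozen=True)
class SSIM:
    """A complete upper-triangular symbolic relation matrix.

    Parameters
    ----------
    codes
        Factor codes in roster order.
    symbols
        Mapping from (row_code, col_code), row before col, to a symbol in
        ``{V, A, X, O}``. Must cover the full strict upper triangle.
    """

    codes: tuple[int, ...]
    symbols: Mapping[tuple[int, int], str] = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))
        object.__setattr__(self, "symbols", dict(self.symbols))
        expected = set(upper_triangle_pairs(self.codes))
        got = set(self.symbols)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValidationError(
                f"SSIM triangle incomplete or malformed: missing pairs {missing}, "
                f"unexpected pairs {extra}"
            )
        for pair, sym in self.symbols.items():
            if sym not in SYMBOLS:
                raise ValidationError(f"SSIM pair {pair}: unknown symbol {sym!r}")

    @property
    def n(self) -> int:
        return len(self.codes)

    def __getitem__(self, pair: tuple[int, int]) -> str:
        return self.symbols[pair]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SSIM):
            return NotImplemented
        return self.codes == other.codes and dict(self.symbols) == dict(other.symbols)
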