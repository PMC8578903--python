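"""Exception hierarchy shared across the toolkit."""


class IsmError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(IsmError):
    """An input object violates a structural invariant."""


class ElicitationError(IsmError):
    """The expert panel input is unusable (e.g. empty panel)."""


class TieError(IsmError):
    """A vote or judgment tie occurred under a tie policy of ``error``."""


class MatrixParseError(IsmError):
    """A matrix/SSIM file could not be parsed; carries row/column context."""


class StallError(IsmError):
    """Level partitioning made no progress on a non-transitively-closed matrix."""

    def __init__(self, residual: tuple[int, ...]):
        self.residual = tuple(residual)
        super().__init__(
            "level partitioning stalled: no factor in the residual set "
            f"{list(self.residual)} satisfies reachability == intersection; "
            "the matrix is not transitively closed — apply transitive_closure "
            "with mode='full' (or 'one_pass') first"
        )
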