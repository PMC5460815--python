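"""Exception hierarchy shared across the package."""


class DwdfamError(Exception):
    """Base class for all package-specific errors."""


class PatternSyntaxError(DwdfamError):
    """Malformed degenerate-pattern string; carries the offending token position."""

    def __init__(self, message: str, token_index: int | None = None):
        super().__init__(message)
        self.token_index = token_index


class SequenceError(DwdfamError):
    """A sequence contains an unexpected character or violates a frame/length contract."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class ConsistencyError(DwdfamError):
    """Cross-table reference broken (unknown protein/gene id, duplicate id, ...)."""


class PlanInfeasibleError(DwdfamError):
    """A synthetic-data plan cannot be realized (capacity or count constraints)."""


class InvalidPlanError(DwdfamError):
    """A synthetic-data plan violates its own invariants (e.g. duplicate tissue names)."""


class UndefinedDistanceError(DwdfamError):
    """A pairwise distance has zero comparable sites; names the offending pair."""

    def __init__(self, id_a: str, id_b: str):
        super().__init__(
            f"no comparable (gap-free) sites between {id_a!r} and {id_b!r}; "
            "p-distance is undefined"
        )
        self.pair = (id_a, id_b)
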