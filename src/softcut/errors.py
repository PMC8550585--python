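"""Exception hierarchy for softcut."""


class SoftcutError(Exception):
    """Base class for all softcut errors."""


class InvalidGeometryError(SoftcutError):
    """Model generation produced a degenerate or empty geometry."""


class InsufficientPointsError(SoftcutError):
    """A spatial test requires more points than were supplied."""


class RankDeficiencyError(SoftcutError):
    """The MLS moment matrix is singular or too ill-conditioned to invert.

    Carries the offending element (or vertex) index when known.
    """

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class RowOverflowError(SoftcutError):
    """A table row would exceed the fixed maximum row width.

    Fixed-width rows are a hard capacity contract: an element may not be
    connected to more nodes than the maximum allocated at creation time.
    """

    def __init__(self, message: str, row_index: int | None = None):
        super().__init__(message)
        self.row_index = row_index


class TableConsistencyError(SoftcutError):
    """Row-aligned tables disagree on shape or row lengths."""


class DivergenceError(SoftcutError):
    """An iterative solve produced non-finite values."""


class ConfigError(SoftcutError):
    """A run configuration failed validation.

    Carries the offending field name.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field
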