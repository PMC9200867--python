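"""Exception hierarchy for the vcgdi pipeline."""


class VcgdiError(Exception):
    """Base class for all vcgdi errors."""


class ParameterError(VcgdiError, ValueError):
    """An operation was called with invalid parameters or degenerate input."""


class ParseError(VcgdiError, ValueError):
    """A file could not be parsed into a valid record."""


class LeadMissingError(ParseError):
    """A required standard lead is absent from the input record."""

    def __init__(self, lead: str, path: str | None = None):
        self.lead = lead
        where = f" in {path}" if path else ""
        super().__init__(f"required lead {lead!r} not found{where}")


class QCError(VcgdiError):
    """A recording failed a quality-control gate (too few beats, low
    beat-to-beat correlation); carries the reason for the exclusion report."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)
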