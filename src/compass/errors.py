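"""Exception hierarchy for COMPASS data handling and analysis."""


class CompassError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CompassError):
    """The file cannot be parsed at all (empty, malformed header, bad timestamps)."""


class IntegrityError(CompassError):
    """The file parses but violates a data invariant (non-monotone time, out-of-range values)."""


class RhythmError(CompassError):
    """A rhythm statistic is undefined for this input (constant trace, too few cycles)."""


class ScheduleError(CompassError):
    """A light schedule cannot be inferred from the light channel."""
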