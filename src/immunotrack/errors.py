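"""Exception hierarchy shared by all immunotrack modules."""


class ImmunotrackError(Exception):
    """Base class for all package errors."""


class FormatError(ImmunotrackError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ImmunotrackError):
    """Input values violate a documented invariant."""


class UnavailableMetricError(ImmunotrackError):
    """A metric cannot be computed from the available data
    (e.g. no productive clones, unknown nucleated-cell count)."""


class DegenerateInputError(ImmunotrackError):
    """Input is at a boundary where the requested method is undefined
    (e.g. logit-Wald interval with 0 or n successes)."""
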