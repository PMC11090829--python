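"""Exception hierarchy for the pipeline.

All errors derive from :class:`OrgfidError` so callers (and the CLI) can
catch pipeline failures without swallowing unrelated bugs.
"""


class OrgfidError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OrgfidError, ValueError):
    """Invalid configuration: bad role map, missing channel, bad constant."""


class ImageFormatError(OrgfidError, ValueError):
    """Image file exists but its layout does not match expectations."""


class DegenerateThresholdError(OrgfidError, ValueError):
    """Automatic thresholding is undefined (e.g. constant-intensity channel)."""


class InsufficientReferenceError(OrgfidError, ValueError):
    """Too few reference records to fit quartile bin boundaries."""


class EmptyConditionError(OrgfidError, ValueError):
    """A condition has no sections, so no distribution can be formed."""


class NoTissueError(OrgfidError, ValueError):
    """A section has no measurable tissue; its log-ratio is undefined."""


class InvalidDistributionError(OrgfidError, ValueError):
    """A probability vector has negative mass or does not sum to one."""


class UndefinedStatisticError(OrgfidError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class GenerationError(OrgfidError, ValueError):
    """A synthetic-data spec requests an unreachable configuration."""
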