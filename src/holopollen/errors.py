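"""Exception hierarchy and sentinel values shared across the package."""

from __future__ import annotations

import math


class HoloPollenError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HoloPollenError, ValueError):
    """A parameter is outside its documented domain."""


class ConfigurationError(HoloPollenError, ValueError):
    """A configuration object is internally inconsistent."""


class DataError(HoloPollenError, ValueError):
    """Input data violates a precondition (missing labels, bad shapes...)."""


class ParseError(HoloPollenError, ValueError):
    """A file could not be parsed; the message names the offending line/field."""


class ManifestIntegrityError(HoloPollenError, ValueError):
    """A dataset manifest references files that do not exist."""


#: Label assigned when the classifier abstains at a confidence threshold.
UNCLASSIFIED = "UNCLASSIFIED"

#: Sentinel for metrics that are undefined on the given input (e.g. the
#: scaling factor when the automatic total is zero).  NaN is used so the
#: value propagates through arrays; callers must treat it explicitly via
#: :func:`is_defined`, never compare with ``==``.
UNDEFINED_METRIC = float("nan")


def is_defined(value: float) -> bool:
    """True if *value* is a defined metric (not the undefined sentinel)."""
    return not math.isnan(value)
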