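"""Exception hierarchy for the thermoapos pipeline.

Every stage raises a subclass of :class:`ThermoAposError` so the CLI can
abort with the stage name and a clean message instead of a traceback.
"""


class ThermoAposError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ThermoAposError):
    """Malformed raw-grid file (truncated payload, bad header, zero dims)."""


class TemperatureRangeError(ThermoAposError):
    """A temperature is not representable in the raw-grid dialect."""


class DegenerateInputError(ThermoAposError):
    """Input is valid in shape but carries no usable signal (e.g. all zeros)."""


class ParameterError(ThermoAposError):
    """Invalid user-supplied parameter (even smoothing size, bad format name)."""


class UnimodalFieldError(ThermoAposError):
    """The temperature histogram has no two separable modes: the image has no
    background that can be split off."""


class AnchorValidationError(ThermoAposError):
    """Anchor set is missing points, has duplicates, out-of-bounds positions,
    or violates the head-to-crotch vertical ordering."""


class SegmentationError(ThermoAposError):
    """ROI geometry could not be computed; the message names the ROI."""


class EmptyROIError(ThermoAposError):
    """A polygon enclosed no grid-cell centers."""


class DegenerateROIError(ThermoAposError):
    """An ROI has no nonzero temperatures, so no nonzero cluster exists."""


class FeatureError(ThermoAposError):
    """A pooled face or chest region is empty after zero-exclusion."""


class LookupError_(ThermoAposError):
    """Unknown object id queried against an APOS graph."""
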