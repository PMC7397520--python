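"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`HipspectError`
so callers (and the CLI) can distinguish configuration mistakes, bad input
data, and genuine computation failures by exception class.
"""


class HipspectError(Exception):
    """Base class for all hipspect errors."""


class GeometryError(HipspectError):
    """A shape (sphere, ROI) does not fit the volume it is applied to."""


class ParameterError(HipspectError):
    """An invalid model parameter (negative rate, bad truncation bounds...)."""


class CohortError(HipspectError):
    """An invalid cohort specification (e.g. empty cohort)."""


class ManifestError(HipspectError):
    """A malformed cohort manifest row or missing column."""


class MeasurementError(HipspectError):
    """An ROI measurement could not be taken (no eligible voxels)."""


class ScoreError(HipspectError):
    """A perfusion ratio is undefined (non-positive reference uptake)."""


class InputError(HipspectError):
    """Malformed label sequences or unknown categorical values."""


class RocError(HipspectError):
    """ROC analysis undefined (single-class outcomes, degenerate variance)."""
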