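"""Exception hierarchy for chairrise.

All package errors derive from :class:`ChairRiseError` so callers can catch
one base class; the leaf classes distinguish bad files, bad values, bad
parameters and failed stream alignment.
"""


class ChairRiseError(Exception):
    """Base class for all chairrise errors."""


class FormatError(ChairRiseError):
    """A file could not be parsed (missing column, empty file, bad row)."""


class ValidationError(ChairRiseError, ValueError):
    """Data violates a domain invariant (non-monotone time, overlap, ...)."""


class ParameterError(ChairRiseError, ValueError):
    """A configuration parameter is out of its admissible range."""


class InputError(ChairRiseError, ValueError):
    """An operation received input it cannot work on (too short, mismatched)."""


class AlignmentError(ChairRiseError):
    """Two sensor streams share no common time interval."""


class EstimationError(ChairRiseError):
    """A quantity (body weight, resting weight) could not be estimated."""


class TrainingError(ChairRiseError):
    """A classifier stage could not be trained (e.g. single-class data)."""
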