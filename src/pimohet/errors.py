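"""Exception hierarchy.

Every failure mode named in the stage contracts maps to one of these, so
callers (and the workflow driver) can distinguish bad configuration from
degenerate data from misaligned inputs.
"""


class PimohetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PimohetError):
    """Invalid configuration value; message names the offending field."""


class GeometryError(PimohetError):
    """Synthetic geometry cannot be realised (e.g. biopsy punch does not fit)."""


class EmptyTissueError(PimohetError):
    """No tissue pixels found in a section image."""


class EmptyRegionError(PimohetError):
    """Requested quantification region contains no pixels."""


class CalibrationError(PimohetError):
    """Threshold calibration impossible (e.g. no ordinal signal in scores)."""


class ProtocolError(PimohetError):
    """Sections from different staining protocols mixed in one calibration."""


class SampleSizeError(PimohetError):
    """Too few matched observations for the requested statistic."""


class DegenerateDataError(PimohetError):
    """Zero variance / zero range where a spread is required."""


class AlignmentError(PimohetError):
    """Two inputs that must cover the same patients or samples do not."""


class LabellingError(PimohetError):
    """Required labels (kit, biopsy order) missing or ambiguous."""


class CoverageError(PimohetError):
    """Too many signature genes missing from the expression matrix."""


class DataError(PimohetError):
    """Malformed input table (duplicates, impossible values)."""


class InputError(PimohetError):
    """Empty or otherwise unusable input to a statistical routine."""
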