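"""Exception types raised by the pipeline."""


class GreentrackError(Exception):
    """Base class for all package errors."""


class FormatError(GreentrackError):
    """Input file does not match the expected tabular/GeoJSON dialect."""


class EmptyInputError(GreentrackError):
    """No usable records could be parsed from an input."""


class CRSError(GreentrackError):
    """Coordinate-system mismatch or coordinates outside the projection domain."""


class StateError(GreentrackError):
    """Operation called on data in the wrong state (unprojected, unannotated...)."""


class GenerationError(GreentrackError):
    """Synthetic-map packing could not be satisfied within bounded retries."""
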