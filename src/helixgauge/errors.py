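"""Exception hierarchy for the helixgauge pipeline."""


class HelixGaugeError(Exception):
    """Base class for all helixgauge errors."""


class ContentError(HelixGaugeError):
    """Input exists but does not contain what the pipeline needs."""


class MissingAtomError(ContentError):
    """A nucleotide lacks one of the four backbone atoms."""


class DegenerateGeometryError(HelixGaugeError):
    """Coordinates too degenerate to define the requested geometry."""


class SeriesAlignmentError(HelixGaugeError):
    """Two per-site series do not share a consistent indexing."""
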