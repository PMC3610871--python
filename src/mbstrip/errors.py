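"""Exception hierarchy for mbstrip.

All package-specific failures derive from :class:`MbstripError` so callers
(and the CLI) can distinguish configuration, data, and design problems.
"""


class MbstripError(Exception):
    """Base class for all mbstrip errors."""


class FastaParseError(MbstripError):
    """A FASTA stream could not be parsed; message names the offending record."""


class PanelConfigError(MbstripError):
    """The panel configuration is missing, malformed, or inconsistent with the FASTA."""


class PanelValidationError(MbstripError):
    """A panel violates an invariant (duplicate ids, bad residues, bad group label)."""


class CoordinateError(MbstripError):
    """A region could not be resolved to alignment columns."""


class DesignError(MbstripError):
    """A peptide or sandwich design rule could not be satisfied."""


class SpecError(MbstripError):
    """A synthetic-panel specification is internally inconsistent."""
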