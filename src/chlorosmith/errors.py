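"""Exception hierarchy shared across the toolkit."""


class ChlorosmithError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameter(ChlorosmithError, ValueError):
    """A caller-supplied parameter is out of its valid range."""


class ParseError(ChlorosmithError, ValueError):
    """A record in an input file could not be parsed.

    Carries ``record_index`` (0-based record or line number) when known.
    """

    def __init__(self, message, record_index=None):
        super().__init__(message)
        self.record_index = record_index


class NoLinkedPeaks(ChlorosmithError):
    """No (N, 2N) peak pair could be found in the k-mer spectrum."""


class EmptyBaitSet(ChlorosmithError):
    """The selected multiplicity band contains no k-mers."""


class EmptyInput(ChlorosmithError):
    """An operation that needs reads or sequences received none."""


class NoIRFound(ChlorosmithError):
    """No inverted repeat of at least the requested length exists."""


class InvalidRegionMap(ChlorosmithError, ValueError):
    """A quadripartite region map is inconsistent with its sequence."""


class EmptyChain(ChlorosmithError):
    """No unique anchors could be placed between two sequences."""


class NotCollinear(ChlorosmithError):
    """Anchor chain covers too little of the reference for direct calling.

    Carries ``coverage``, the anchored fraction of the reference.
    """

    def __init__(self, message, coverage=None):
        super().__init__(message)
        self.coverage = coverage


class RefMismatch(ChlorosmithError, ValueError):
    """A variant's stated reference allele disagrees with the reference."""


class InvalidVariant(ChlorosmithError, ValueError):
    """A variant record violates basic allele constraints."""


class ReferenceMismatch(ChlorosmithError, ValueError):
    """Variant lists against different references cannot be merged."""


class InvalidAnnotation(ChlorosmithError, ValueError):
    """Gene annotation violates containment or span constraints."""


class MissingInput(ChlorosmithError, FileNotFoundError):
    """A pipeline stage's required input is absent."""
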