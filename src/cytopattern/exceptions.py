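"""Exception hierarchy for cytopattern."""


class CytopatternError(Exception):
    """Base class for all cytopattern errors."""


class FormatError(CytopatternError):
    """A file or header does not parse under the declared dialect."""


class ValidationError(CytopatternError):
    """Parsed content violates an invariant (duplicates, non-binary cells, ...)."""
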