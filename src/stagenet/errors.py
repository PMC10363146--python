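"""Exception hierarchy shared across the pipeline."""


class StagenetError(Exception):
    """Base class for all pipeline errors."""


class FormatError(StagenetError):
    """A file does not conform to the expected Firehose-style dialect."""


class ValidationError(StagenetError):
    """Parsed data violates a domain invariant (duplicate barcodes, beta
    values outside [0, 1], control-range sample codes, ...)."""


class ConfigError(StagenetError):
    """A run or simulation configuration violates its invariants."""


class DegenerateInputError(StagenetError):
    """A statistical routine received input on which its estimate is
    undefined (e.g. a constant vector for a rank correlation)."""
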