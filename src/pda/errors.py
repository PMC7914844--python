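"""Exception hierarchy for the pda package."""


class PdaError(Exception):
    """Base class for all pda errors."""


class ContractError(PdaError, ValueError):
    """An operation was called with arguments violating its contract."""


class StepSizeError(PdaError, RuntimeError):
    """The Metropolis chain is effectively stuck (acceptance below 1%)."""


class ArchiveError(PdaError, OSError):
    """A sample or maxima archive is missing, malformed, or truncated."""
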