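"""Exception hierarchy shared across the pipeline."""


class HgtscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HgtscanError):
    """Raised when a configuration value is missing, malformed or out of range."""


class DependencyError(HgtscanError):
    """Raised when a pipeline stage is run without its upstream outputs."""


class ChainBranchingError(HgtscanError):
    """Raised when junction walking meets a breakend with more than one partner.

    The message lists the ambiguous breakends so the caller can inspect the
    offending junctions.
    """
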