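"""Typed errors raised across the pipeline."""


class EcotransectError(Exception):
    """Base class for all package errors."""

    code = "error"


class ConfigurationError(EcotransectError, ValueError):
    """Invalid scenario, run configuration, or input table."""

    code = "config"


class ClusterCountError(EcotransectError, ValueError):
    """Requested number of fuzzy clusters violates the k <= n/2 - 1 limit."""

    code = "cluster_count"


class StageError(EcotransectError, RuntimeError):
    """A pipeline stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
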