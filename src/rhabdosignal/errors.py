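"""Structured exceptions raised across the pipeline."""


class RhabdosignalError(Exception):
    """Base class for all package errors."""


class SchemaError(RhabdosignalError):
    """An input table is missing a mandatory column or is malformed."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"missing mandatory column {column!r}{where}")


class EmptyGroupError(RhabdosignalError):
    """A contingency-table group (exposure, reference, or sex stratum) is empty."""


class UndefinedEstimateError(RhabdosignalError):
    """A zero cell makes the odds ratio undefined and correction is disabled."""


class ArmError(RhabdosignalError):
    """Association-rule metric undefined (no transactions / zero marginal support)."""


class ConfigError(RhabdosignalError):
    """A generator or pipeline configuration is infeasible or invalid."""
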