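"""Exception hierarchy for birthlink."""


class BirthlinkError(Exception):
    """Base class for all birthlink errors."""


class ConfigError(BirthlinkError, ValueError):
    """Invalid simulation or linkage configuration."""


class ValidationError(BirthlinkError, ValueError):
    """Input data violates a documented precondition."""


class RecordParseError(BirthlinkError, ValueError):
    """A record file row could not be parsed.

    Carries the 1-based data row number and the offending field so the
    caller can locate the problem in the CSV.
    """

    def __init__(self, line: int, field: str, message: str):
        self.line = line
        self.field = field
        super().__init__(f"row {line}, field '{field}': {message}")


class UndefinedMetricError(BirthlinkError, ArithmeticError):
    """A metric's denominator is zero, so the metric is undefined."""


class PipelineError(BirthlinkError, RuntimeError):
    """An orchestration stage is missing its upstream artifact."""
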