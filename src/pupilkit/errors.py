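"""Exception hierarchy.

ConfigError — invalid settings (CLI exit code 1).
DataError   — invalid or degenerate data (CLI exit code 2).
"""


class PupilkitError(Exception):
    """Base class for all package errors."""


class ConfigError(PupilkitError, ValueError):
    """Invalid configuration value."""


class DataError(PupilkitError, ValueError):
    """Invalid, inconsistent, or degenerate input data."""


class CollinearityError(DataError):
    """Design matrix is (near-)singular."""

    def __init__(self, condition_number: float):
        self.condition_number = condition_number
        super().__init__(
            f"design matrix is near-singular (condition number {condition_number:.3g})"
        )
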