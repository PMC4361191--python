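"""Exception hierarchy shared across the pipeline.

Each class maps to a distinct process exit code in the CLI so that a failed
stage can be identified from the shell (config 2, data 3, training 4,
inference 5).
"""


class StreamDiagError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(StreamDiagError):
    """Invalid configuration value or file."""

    exit_code = 2


class DataError(StreamDiagError):
    """Malformed or degenerate input data (standardization, splits, ANOVA)."""

    exit_code = 3


class TrainingError(StreamDiagError):
    """Network or ensemble training failed to converge."""

    exit_code = 4


class NumericalError(TrainingError):
    """Non-finite values encountered during optimisation."""


class InferenceError(StreamDiagError):
    """Prediction-time failure (missing inputs, shape mismatch)."""

    exit_code = 5
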