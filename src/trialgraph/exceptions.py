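"""Exception hierarchy for the pipeline stages."""


class TrialGraphError(Exception):
    """Base class for all package errors."""


class SchemaError(TrialGraphError):
    """Registry file does not match the expected column schema."""


class AliasValidationError(TrialGraphError):
    """Alias map has a cycle or a non-fixed-point canonical target."""


class SplitError(TrialGraphError):
    """Edge split cannot be produced under its constraints."""


class SamplingError(TrialGraphError):
    """Negative-edge sampling pool is exhausted."""


class TrainingError(TrialGraphError):
    """Training diverged (non-finite loss)."""


class GenerationError(TrialGraphError):
    """Synthetic-registry configuration is infeasible."""
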