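"""Exception hierarchy for the fem package."""


class FemError(Exception):
    """Base class for all fem-specific errors."""


class ParameterError(FemError, ValueError):
    """A function argument is outside its documented domain."""


class InputError(FemError, ValueError):
    """Malformed or empty user input (genome, reads)."""


class IndexFormatError(FemError):
    """An index file has the wrong magic string or format version."""


class IndexCorruptionError(FemError):
    """An index file is truncated or internally inconsistent."""


class SelectionError(FemError):
    """Seed selection is infeasible (too few admissible seed starts)."""


class ConfigurationError(FemError):
    """Mapping parameters are mutually inconsistent (e.g. l_step > l_max)."""


class EvaluationError(FemError):
    """Evaluator inputs disagree (e.g. mismatched read identifiers)."""
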