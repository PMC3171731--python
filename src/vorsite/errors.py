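"""Exception hierarchy."""


class VorsiteError(Exception):
    """Base class for package errors."""


class EmptyStructureError(VorsiteError):
    """A parsed file contained no standard residues."""


class ConfigurationError(VorsiteError):
    """Invalid configuration (unknown chain, bad mode, bad parameter)."""


class GeometryError(VorsiteError):
    """Degenerate geometry defeated the tessellation."""


class GenerationError(VorsiteError):
    """A synthetic fixture could not satisfy its specification."""


class ConservationError(VorsiteError):
    """Alignment could not be mapped onto the chain."""


class ConsistencyError(VorsiteError):
    """Inputs that must agree (registries, residue sets, scores) do not."""


class TrainingError(VorsiteError):
    """Training preconditions violated (e.g. single-class labels)."""


class EvaluationError(VorsiteError):
    """Evaluation preconditions violated (e.g. single-class labels)."""


class InputError(VorsiteError):
    """A required prediction input is missing."""
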