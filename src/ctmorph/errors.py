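"""Exception hierarchy for the ctmorph pipeline.

Every stage raises a subclass of :class:`CtMorphError` so callers (and the
pipeline orchestrator, which converts per-measurement failures into absence
flags) can catch package errors without masking programming errors.
"""


class CtMorphError(Exception):
    """Base class for all ctmorph errors."""


class ParameterError(CtMorphError, ValueError):
    """A generator or operation parameter is outside its valid domain."""


class CanvasError(ParameterError):
    """A phantom shape does not fit on the requested canvas."""


class InputError(CtMorphError, ValueError):
    """Invalid input data (empty directory, mismatched lengths, ...)."""


class MetadataError(CtMorphError, ValueError):
    """Required imaging metadata is missing or invalid (names the tag)."""


class FormatError(CtMorphError, ValueError):
    """A file is not in the expected on-disk format."""


class ConfigurationError(CtMorphError, ValueError):
    """Unknown extractor / backend id or invalid configuration."""


class TrainingError(CtMorphError, ValueError):
    """Classifier training preconditions violated (e.g. single class)."""


class CurationError(CtMorphError, ValueError):
    """Dataset curation failed (e.g. a label with no images at all)."""


class IntervalError(CtMorphError, ValueError):
    """An annotated slice interval is invalid (start > end)."""


class StateError(CtMorphError, RuntimeError):
    """Operation called on an object in the wrong state (unfitted model)."""


class ContractError(CtMorphError, RuntimeError):
    """A pluggable backend violated its output contract."""


class DegradationError(CtMorphError, ValueError):
    """Mask degradation would empty the mask."""


class DegenerateMaskError(CtMorphError, ValueError):
    """Mask has too little foreground for the requested geometry."""


class AmbiguousAxisError(CtMorphError, ValueError):
    """Mask is too isotropic for a principal axis to be meaningful."""


class DegenerateHullError(CtMorphError, ValueError):
    """Foreground is collinear; no 2D convex hull exists."""


class NoGrooveError(CtMorphError, ValueError):
    """No anterior concavity deep enough to be a trochlear groove."""


class SingleCondyleError(CtMorphError, ValueError):
    """Posterior hull points all lie on one side; no condylar axis."""


class NoOpeningError(CtMorphError, ValueError):
    """No convexity defect deep enough to be the acetabular opening."""


class PairingError(CtMorphError, ValueError):
    """Pipeline and reference reports cannot be paired by patient id."""
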