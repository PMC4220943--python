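"""Exception hierarchy for the reorientation pipeline.

All domain errors derive from :class:`CephorientError` so callers (and the
CLI) can distinguish validation problems from degenerate-geometry problems.
"""


class CephorientError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CephorientError):
    """Malformed or insufficient input data."""


class MissingLandmarkError(ValidationError):
    """A required landmark is absent from a digitization trial."""


class InsufficientDataError(ValidationError):
    """Too few patients, trials or rows for the requested statistic."""


class DegenerateGeometryError(CephorientError):
    """Geometry too ill-conditioned to define the requested construct."""


class DegenerateFrameError(DegenerateGeometryError):
    """The four reference landmarks cannot define a reference frame
    (Na coincides with S, or Ba lies on the Na-S line)."""


class DegenerateAngleError(DegenerateGeometryError):
    """A reference point coincides with the averaged landmark, so the
    angle subtended at that landmark is undefined."""


class CollinearityError(CephorientError):
    """The regression design matrix is rank-deficient within a step."""


class UnknownPredictorError(CephorientError):
    """A marginal effect was requested for a predictor not in the model."""
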