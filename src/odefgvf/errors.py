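"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`OdefgvfError` so callers (and the
end-to-end runner) can attribute a failure to a stage without string
matching.
"""


class OdefgvfError(Exception):
    """Base class for all package errors."""


class ImageIOError(OdefgvfError):
    """File unreadable or not decodable as an image."""


class FormatError(OdefgvfError):
    """Input decodes but violates the pipeline's format contract."""


class GeometryError(OdefgvfError):
    """Retina geometry could not be estimated (e.g. all-dark image)."""


class ValidationError(OdefgvfError):
    """Manifest or record fails validation (bad label, missing column)."""


class SpecError(OdefgvfError):
    """Phantom specification is internally inconsistent."""


class AssessmentError(OdefgvfError):
    """Vessel-network completeness cannot be assessed (empty skeleton)."""


class FitError(OdefgvfError):
    """Curve fit is underdetermined or degenerate."""


class ConvergenceError(OdefgvfError):
    """Line-convergence point undefined (all lines parallel) or contour empty."""


class RoiError(OdefgvfError):
    """ROI location outside the image."""


class FillError(OdefgvfError):
    """Harmonic region filling has no boundary data."""


class NumericalError(OdefgvfError):
    """Linear algebra failed beyond ridge rescue."""


class DegenerateRegionError(OdefgvfError):
    """One side of the level set holds (almost) no pixels."""


class DivergenceError(OdefgvfError):
    """Level-set update produced non-finite values; try a smaller time step."""


class SegmentationError(OdefgvfError):
    """FGVF run failed (divergence or contour collapse); carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FeatureError(OdefgvfError):
    """A feature is mathematically undefined on this input; names the feature."""

    def __init__(self, message, feature=None):
        super().__init__(message)
        self.feature = feature


class TrainingError(OdefgvfError):
    """Classifier cannot be trained (single class, too few samples)."""


class SplitError(OdefgvfError):
    """Cross-validation folds cannot be formed."""


class InputError(OdefgvfError):
    """Non-finite or malformed numeric input."""


class EvaluationError(OdefgvfError):
    """Scores undefined on these inputs (empty ground truth, length mismatch)."""


class PipelineError(OdefgvfError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline failed at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
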