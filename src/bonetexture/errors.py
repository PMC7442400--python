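"""Exception hierarchy for the bonetexture package.

All package-specific failures derive from :class:`BoneTextureError` so
callers (and the CLI) can distinguish user/data errors from genuine bugs.
"""


class BoneTextureError(Exception):
    """Base class for all errors raised by bonetexture."""


class DimensionalityError(BoneTextureError):
    """An image is not a 3-D volume."""


class GeometryError(BoneTextureError):
    """A mask does not match the geometry of its companion volume."""


class DegenerateVoiError(BoneTextureError):
    """The volume of interest is empty or too small for texture analysis."""


class EmptyMatrixError(BoneTextureError):
    """No valid voxel pair exists for a given co-occurrence displacement."""


class SchemaError(BoneTextureError):
    """A table is malformed: missing columns, duplicate ids, empty input."""


class CohortParseError(BoneTextureError):
    """A covariate value could not be parsed or violates its domain."""


class JoinError(BoneTextureError):
    """Feature and cohort tables do not join 1:1 on subject id."""


class DegeneratePredictorError(BoneTextureError):
    """A regression predictor has zero variance."""


class CollinearityError(BoneTextureError):
    """The regression design matrix is rank deficient."""


class UndefinedConcordanceError(BoneTextureError):
    """Concordance is undefined (constant input sequences)."""


class PhantomSpecError(BoneTextureError):
    """A synthetic phantom specification is invalid."""
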