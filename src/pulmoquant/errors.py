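"""Exception hierarchy shared by all pipeline stages."""


class PulmoquantError(Exception):
    """Base class for all errors raised by this package."""


class VolumeFormatError(PulmoquantError):
    """Image on disk is not a 3D scalar volume usable as a CT dataset."""


class VolumeValidationError(PulmoquantError):
    """Loaded voxel data violates an invariant (e.g. NaN/Inf voxels)."""


class MaskAlignmentError(PulmoquantError):
    """Mask shape does not match its CT volume."""


class LabelSchemeError(PulmoquantError):
    """Mask contains labels outside the {0: background, 1: right, 2: left} scheme."""


class EmptyRegionError(PulmoquantError):
    """A lung region selection produced zero voxels (MLA is undefined on it)."""


class PairingError(PulmoquantError):
    """Inspiration/expiration volumes do not belong to the same subject scan."""


class PhantomSpecError(PulmoquantError):
    """Synthetic phantom specification is infeasible or invalid."""


class DesignError(PulmoquantError):
    """Cohort design is invalid (unknown group, empty group, bad days)."""


class NormalizationError(PulmoquantError):
    """Control-group normalization is undefined (pooled control mean is zero)."""


class UndefinedChangeError(PulmoquantError):
    """Percent change vs. the disease arm is undefined (its mean is zero)."""


class InsufficientDataError(PulmoquantError):
    """Too few observations for the requested statistical test."""


class ScoreValidationError(PulmoquantError):
    """Histological field score outside the 0-8 ordinal scale."""


class ConfigError(PulmoquantError):
    """Run configuration failed validation."""
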