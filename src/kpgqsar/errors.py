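"""Exception hierarchy."""


class KpgError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KpgError):
    """An interchange document is missing a field or has a malformed value."""


class OrderingError(KpgError):
    """An occupied MO lies above an empty MO in the energy-sorted spectrum."""


class DegenerateMOError(KpgError):
    """Every population of an MO fell at or below the zeroing threshold,
    so the MO cannot be renormalized to unit population."""


class NearZeroEigenvalueError(KpgError):
    """A contributing MO eigenvalue sits within tolerance of zero;
    superdelocalizability terms F/E diverge, which signals that the
    electronic-structure method produced eigenvalues straddling the
    Fermi level and is unsuitable for this index."""


class UndefinedFrontierError(KpgError):
    """An atom has no occupied (or no empty) MO with nonzero population,
    so its local frontier indices are undefined."""


class SingularityError(KpgError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message, dependent_columns=()):
        super().__init__(message)
        self.dependent_columns = list(dependent_columns)


class AssemblyError(KpgError):
    """Descriptor-matrix assembly failed (missing activity, duplicate id,
    inconsistent skeleton map)."""


class GenerationError(KpgError):
    """A synthetic dataset could not realise its declared ground truth."""


class ConfigError(KpgError):
    """A run configuration is invalid or references missing paths."""
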