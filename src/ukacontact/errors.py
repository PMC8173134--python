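"""Exception hierarchy for the ukacontact pipeline."""


class UkaContactError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(UkaContactError, ValueError):
    """A geometric or numeric parameter violates its precondition."""


class InvalidInputError(UkaContactError, ValueError):
    """An input object (mesh, series, sample) is empty or malformed."""


class OutOfFootprintError(UkaContactError, ValueError):
    """A requested contact location falls outside the insert footprint."""


class ProjectionGeometryError(UkaContactError, ValueError):
    """Mesh/source/detector arrangement does not admit a central projection."""


class DegenerateGeometryError(UkaContactError, ValueError):
    """Rank-deficient correspondences or otherwise degenerate geometry."""


class GimbalDegenerateError(UkaContactError, ValueError):
    """Joint-coordinate-system axes are (nearly) parallel."""


class NoContactError(UkaContactError, ValueError):
    """Surfaces are farther apart than the plausible joint gap."""


class DegenerateSampleError(UkaContactError, ValueError):
    """A statistical sample has no variance or is otherwise unusable."""


class UnsupportedFormatError(UkaContactError, ValueError):
    """File extension not recognised by the IO layer."""


class ParseError(UkaContactError, ValueError):
    """A file could not be parsed; message names the offending location."""


class ConfigError(UkaContactError, ValueError):
    """Pipeline configuration failed schema validation."""
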