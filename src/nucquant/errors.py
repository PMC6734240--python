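"""Exception hierarchy."""


class NucquantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NucquantError):
    """A setting is inconsistent with the data or with other settings."""


class PlacementError(NucquantError):
    """Nuclei could not be placed without overlap within the attempt budget."""


class DegenerateInputError(NucquantError):
    """Input carries no usable information (e.g. a constant image)."""


class GeometryError(NucquantError):
    """A rectangle/frame falls outside the image bounds."""


class MissingVoxelSizeError(NucquantError):
    """A stack was read without voxel-size metadata and none was supplied."""


class StackFormatError(NucquantError):
    """TIFF pages are ragged or the array layout is not understood."""
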