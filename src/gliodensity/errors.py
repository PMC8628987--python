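"""Exception types raised across the pipeline."""


class ConfigurationError(ValueError):
    """A requested geometry or configuration cannot be realized."""


class StabilityError(RuntimeError):
    """Explicit time stepping would violate its stability (CFL) bound."""


class NumericalError(RuntimeError):
    """A solver produced values outside its contracted tolerance."""


class FormatError(ValueError):
    """A file does not match the pipeline's I/O conventions."""


class EmptyPairsError(ValueError):
    """Pair collection found no voxel with both a density sample and a finite distance."""
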