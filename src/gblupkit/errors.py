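"""Exception hierarchy shared across the package."""


class GblupkitError(Exception):
    """Base class for all package-specific errors."""


class PedigreeError(GblupkitError):
    """Invalid pedigree: duplicate ids, unknown parents, or cycles."""


class GenotypeIOError(GblupkitError):
    """Malformed or empty genotype input."""


class PhenotypeIOError(GblupkitError):
    """Malformed phenotype input (duplicates, bad values)."""


class FilterError(GblupkitError):
    """A marker filter removed everything, or was misconfigured."""


class ModelError(GblupkitError):
    """Mixed-model construction or solving failed."""


class SimulationError(GblupkitError):
    """Infeasible simulation configuration."""
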