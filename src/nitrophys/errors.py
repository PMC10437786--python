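"""Exception hierarchy shared across the package.

Every error raised by nitrophys derives from :class:`NitrophysError`, so
callers (and the CLI) can catch one base class and still distinguish
input problems from fit failures or design violations.
"""


class NitrophysError(Exception):
    """Base class for all nitrophys errors."""


class InvalidInputError(NitrophysError, ValueError):
    """A measured input (absorbance, mass, curve point) violates its domain."""


class InvalidParameterError(NitrophysError, ValueError):
    """A model parameter is outside its admissible range."""


class FitFailureError(NitrophysError, RuntimeError):
    """A nonlinear fit did not converge or the data are unidentifiable."""


class InsufficientDataError(NitrophysError, ValueError):
    """Too few usable points for the requested regression."""


class UndefinedTraitError(NitrophysError, ValueError):
    """A derived quantity (SLA, RWR, LSP, LCP) is undefined for this input."""


class InfeasibleFluorescenceError(NitrophysError, ValueError):
    """Electron transport rate too low for the variable-J conductance formula."""


class NonphysicalConductanceError(NitrophysError, ValueError):
    """Variable-J chloroplastic CO2 exceeds intercellular CO2 (gm <= 0)."""


class DesignError(NitrophysError, ValueError):
    """The experimental layout is unbalanced or otherwise invalid."""


class CyclicGraphError(NitrophysError, ValueError):
    """A path-model specification contains a directed cycle."""


class CollinearityError(NitrophysError, ValueError):
    """The sample covariance matrix is singular (collinear variables)."""


class ConfigError(NitrophysError, ValueError):
    """A simulation or pipeline configuration value is invalid."""


class SchemaError(NitrophysError, ValueError):
    """An input table is missing required columns or has unmapped names."""
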