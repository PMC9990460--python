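"""Exception hierarchy shared across the package.

The CLI maps these onto fixed exit codes: configuration problems exit 2,
data integrity problems exit 3.
"""


class GliascreenError(Exception):
    """Base class for all package errors."""


class SchemaError(GliascreenError):
    """An input table is missing required columns or has malformed values."""


class IntegrityError(GliascreenError):
    """Well-level data violate a structural invariant (duplicates, orphan genes...)."""


class CapacityError(GliascreenError):
    """A screen design asks for more library wells than the plates can hold."""


class ConfigError(GliascreenError):
    """A run configuration is missing keys or holds out-of-range values."""


class FitError(GliascreenError):
    """A calibration fit is underdetermined or produced an unusable model."""


class CurveError(GliascreenError):
    """A fitted standard curve is not physically plausible (e.g. negative slope)."""
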