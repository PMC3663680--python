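"""Exception hierarchy.

All package errors derive from :class:`MetagrowthError` so callers can catch
one base class; the CLI maps subclasses to distinct exit codes.
"""


class MetagrowthError(Exception):
    """Base class for all package errors."""


class DataError(MetagrowthError):
    """Invalid or insufficient input data (bad volumes, duplicate times, ...)."""


class FitError(MetagrowthError):
    """A model fit could not be performed or did not converge."""


class NoDoublingTimeError(MetagrowthError):
    """A non-growing tumour (SGR <= 0) has no finite volume doubling time.

    Distinct from :class:`DataError`: the input is legal (negative growth
    rates are kept throughout the package), it simply has no DT.
    """


class UnreachableVolumeError(MetagrowthError):
    """The requested volume lies outside the range a growth curve can reach,
    e.g. at or above the Gompertz plateau volume."""
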