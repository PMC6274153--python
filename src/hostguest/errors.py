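"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input is outside the physically meaningful domain.

    The message always names the offending parameter.
    """


class UndefinedFractionError(DomainError):
    """Bound fraction requested for a state with zero total guest."""


class UnidentifiableModelError(ValueError):
    """The data cannot constrain the model parameters (e.g. flat observables)."""


class NoMaximumError(ValueError):
    """A Job curve has no interior maximum (e.g. identically zero)."""


class UnknownElementError(KeyError):
    """A molecular formula contains an element missing from the mass table."""


class SlowExchangeError(ValueError):
    """A slow-exchange NMR series was passed to the fast-exchange fitter."""


class PipelineConfigError(ValueError):
    """A pipeline configuration file is missing required content."""
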