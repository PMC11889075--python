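"""Exception types shared across the package."""


class IRandError(Exception):
    """Base class for package-specific failures."""


class PositivityError(IRandError):
    """Raised when a sample contains only one treatment class.

    Propensity-score methods require 0 < P(T=1|X) < 1; a one-class sample
    makes the contrast unidentifiable.
    """


class DesignError(IRandError):
    """Raised when an estimator is applied to an incompatible study design
    (e.g. a difference-in-differences variant that needs an all-treated
    follow-up applied to a panel that is not built that way)."""


class GroupError(IRandError):
    """Raised when a required treatment-history group is empty."""


class SeedContractError(IRandError):
    """Raised when two estimator runs that must share subsample assignments
    (the mediation decomposition) were run with different assignments."""
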