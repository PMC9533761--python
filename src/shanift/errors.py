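"""Exception hierarchy for shanift."""


class ShaniftError(Exception):
    """Base class for all shanift errors."""


class ProfileError(ShaniftError, ValueError):
    """Malformed or unusable scattering profile (parsing, ordering, sigmas)."""


class IllPosedError(ShaniftError, RuntimeError):
    """The normal equations are singular or hopelessly ill conditioned."""


class UnphysicalFitError(ShaniftError, RuntimeError):
    """A derived size parameter is undefined for the fitted coefficients
    (e.g. negative radius-of-gyration radicand, non-positive Porod invariant)."""


class EstimationError(ShaniftError, RuntimeError):
    """Automatic D or alpha estimation cannot proceed (e.g. no Guinier
    region and no interior peak for the Guinier-peak fallback)."""
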