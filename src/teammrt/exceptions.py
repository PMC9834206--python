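"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


class StructuralError(ValueError):
    """Inputs violate a structural contract (e.g. assignments not covering all team-weeks)."""


class RakingError(ValueError):
    """Raking cannot converge (e.g. empty sample category with nonzero target mass)."""


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient; the message names collinear terms."""
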