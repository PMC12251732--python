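"""Exception hierarchy shared by all coopfall modules."""


class CoopfallError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CoopfallError, ValueError):
    """A measurement or record violates a domain invariant."""


class ConfigurationError(CoopfallError):
    """A rule base, profile, or config file is malformed or inconsistent."""


class NoRuleFiredError(CoopfallError):
    """No fuzzy rule produced a non-zero activation; caller decides fallback."""


class StateError(CoopfallError, RuntimeError):
    """Operation requires a trained/loaded model that is not available."""


class IncompatibleArtifactError(CoopfallError):
    """A serialized model artifact has a missing or unsupported version."""
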