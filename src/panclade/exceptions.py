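"""Exception hierarchy."""


class PancladeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PancladeError):
    """Invalid configuration (bad rates, malformed tree, bad parameters)."""


class InputError(PancladeError):
    """Invalid user-supplied data (duplicate ids, inconsistent universes...)."""


class GenerationError(PancladeError):
    """The simulator could not realise a requested event."""
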