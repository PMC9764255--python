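"""Exception hierarchy for proximap."""


class ProximapError(Exception):
    """Base class for all proximap errors."""


class InputError(ProximapError, ValueError):
    """A data file is malformed or violates an invariant."""


class ConfigurationError(ProximapError, ValueError):
    """A run configuration or threshold set is inconsistent with the data."""
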