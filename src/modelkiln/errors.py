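"""Exception hierarchy shared by all pipeline stages."""


class KilnError(Exception):
    """Base class for all framework errors."""


class ConfigurationError(KilnError):
    """A parameter file or method name is invalid; raised before any work starts."""


class FatalError(KilnError):
    """An unrecoverable error in a pipeline stage.

    Carries the stage name so CLI/log messages can point at the failing
    step (``idata``, ``learn``, ``apply``, ``odata``, ``manage`` ...).
    """

    def __init__(self, message: str, stage: str = ""):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" if stage else message)


class RepositoryError(KilnError):
    """Model-governance error: collisions, missing versions, immutability."""
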