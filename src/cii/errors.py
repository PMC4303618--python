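"""Exception hierarchy."""


class CIIError(Exception):
    """Base class for all package errors."""


class DuplicateKeyError(CIIError):
    """A record with this key already exists; nothing is overwritten in place."""


class MissingKeyError(CIIError):
    """A foreign key or lookup key does not resolve."""


class UnknownFieldError(CIIError):
    """A query predicate names a field that no table declares."""


class InvalidTransitionError(CIIError):
    """A piece status edge outside the allowed state machine."""


class FunctionalTierError(CIIError):
    """An override attempted by a study type below the top functional tier."""


class FrozenStoreError(CIIError):
    """Mutation attempted on an immutable release snapshot."""


class UnknownScenarioError(CIIError):
    """Unrecognised fixture scenario name."""


class StageError(CIIError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")
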