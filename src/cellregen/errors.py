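"""Exception hierarchy shared by all cellregen modules."""


class CellRegenError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CellRegenError, ValueError):
    """A constructor or operation received an out-of-contract argument."""


class EmptyStructureError(CellRegenError, ValueError):
    """A shape generator produced no lattice nodes."""


class InvalidAmputationError(CellRegenError, ValueError):
    """An amputation mask would remove every cell or is not a subset."""


class StateError(CellRegenError, RuntimeError):
    """An operation was called on a structure in the wrong life-cycle state."""


class ContractError(CellRegenError, ValueError):
    """Two inputs that must agree (e.g. field node sets) do not."""


class InfeasibleTargetError(CellRegenError, ValueError):
    """A prescribed organizer signal is below the self-generated field."""


class SpecError(CellRegenError, ValueError):
    """A run-spec document violates the documented schema."""

    def __init__(self, message: str, key_path: str = ""):
        self.key_path = key_path
        super().__init__(f"{key_path}: {message}" if key_path else message)
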