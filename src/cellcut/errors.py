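"""Exception hierarchy shared by all cellcut modules."""


class CellcutError(Exception):
    """Base class for all cellcut-specific errors."""


class ContractError(CellcutError, ValueError):
    """An argument violated an operation's precondition."""


class FormatError(CellcutError):
    """A file exists but its content cannot be interpreted."""


class DegenerateHistogramError(CellcutError):
    """The intensity histogram has no split (e.g. a constant image)."""


class EmptySeedError(CellcutError):
    """A seed class is empty where both classes are required."""


class PlacementError(CellcutError):
    """Synthetic cell placement failed within the retry budget."""


class DegenerateTestError(CellcutError):
    """A statistical test cannot be computed from the given samples."""
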