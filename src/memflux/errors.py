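"""Exception hierarchy for memflux."""


class MemfluxError(Exception):
    """Base class for all memflux errors."""


class PDBParseError(MemfluxError):
    """A PDB record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StructureError(MemfluxError):
    """Structurally inconsistent input (e.g. atom counts differ between frames)."""


class SelectionError(MemfluxError):
    """An atom selection could not be resolved."""


class UnsupportedFeatureError(MemfluxError):
    """Input requires a feature the toolkit deliberately does not support
    (e.g. triclinic periodic boxes)."""
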