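"""Exception hierarchy.

Every error raised by droplens derives from :class:`DroplensError` so callers
can catch the package's failures without masking programming errors.
"""


class DroplensError(Exception):
    """Base class for all droplens errors."""


class ParseError(DroplensError, ValueError):
    """A text input does not follow its declared format (reports the line)."""


class StructuralError(DroplensError, ValueError):
    """Internally inconsistent data: counts, ordering or index coverage."""


class SelectionError(DroplensError, KeyError):
    """A selection query references an unknown label."""

    def __init__(self, label: str, known) -> None:
        self.label = label
        self.known = sorted(known)
        super().__init__(
            f"unknown label {label!r}; known labels: {', '.join(self.known)}"
        )

    def __str__(self) -> str:  # KeyError would repr() the tuple
        return self.args[0]


class GeometryError(DroplensError, ValueError):
    """Impossible geometry (triclinic box, ring larger than the membrane...)."""


class PackingError(DroplensError, ValueError):
    """A synthetic membrane cannot hold the requested number of molecules."""


class PlantError(DroplensError, ValueError):
    """A planted statistic is incompatible with the system geometry."""


class RegistrationError(DroplensError, ValueError):
    """Density-profile registration failed (no unique reference peak)."""


class FitError(DroplensError, RuntimeError):
    """A least-squares fit failed or the data admit no such model."""
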