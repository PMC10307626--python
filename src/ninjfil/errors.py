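"""Package-wide exception types."""


class NinjfilError(ValueError):
    """Base class for all ninjfil errors."""


class InvalidModelError(NinjfilError):
    """A structural model violates a precondition (missing atoms, bad counts)."""


class DegenerateGeometryError(NinjfilError):
    """Geometry admits no unique answer (180-degree screw, coaxial residues...)."""


class ClashError(NinjfilError):
    """An assembly operation produced a steric clash."""

    def __init__(self, message: str, distance: float, pair: tuple):
        super().__init__(message)
        self.distance = distance
        self.pair = pair
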