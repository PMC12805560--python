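"""Exception hierarchy for the model-generation pipeline.

User-facing errors (bad input, bad parameters) derive from
:class:`MolforgeError` so the CLI can distinguish them from internal
failures and exit with the appropriate status code.
"""


class MolforgeError(Exception):
    """Base class for all user-facing errors raised by molforge."""


class EmptyInput(MolforgeError):
    """Raised when an input string is empty or blank after trimming."""


class EmptyToken(MolforgeError):
    """Raised when a batch contains a blank entry (e.g. ``"CCO,,CO"``)."""


class EmptyFile(MolforgeError):
    """Raised when a batch CSV file contains no usable rows."""


class InvalidSmiles(MolforgeError):
    """Raised when a SMILES string cannot be parsed.

    The offending input is echoed in the message and available as
    ``.smiles``.
    """

    def __init__(self, smiles: str, reason: str = "invalid SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class ValenceError(MolforgeError):
    """Raised when an atom exceeds its standard valence during hydrogenation."""


class EmbeddingFailure(MolforgeError):
    """Raised when 3D coordinate generation fails after all retry seeds."""


class BadParam(MolforgeError):
    """Raised for out-of-range fixture or batch parameters."""


class BadGeometryParam(MolforgeError):
    """Raised for degenerate mesh-primitive parameters (zero radius,
    coincident cylinder endpoints, insufficient tessellation)."""


class StyleError(MolforgeError):
    """Raised for an unknown representation kind or invalid style value."""


class EmptyScene(MolforgeError):
    """Raised when a layout or exporter receives no models."""


class UnknownFormat(MolforgeError):
    """Raised when an export format is not one of the supported set."""
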