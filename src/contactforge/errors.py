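"""Exception hierarchy shared across contactforge."""


class ContactForgeError(Exception):
    """Base class for all contactforge errors."""


class FormatError(ContactForgeError):
    """A file could not be parsed; message carries the offending line number."""


class EmptyStructureError(ContactForgeError):
    """A parsed structure contained no usable residues."""


class MissingAtomError(ContactForgeError):
    """A residue lacks an atom required by the requested operation."""


class ConfigurationError(ContactForgeError):
    """Incompatible or incomplete configuration (e.g. CD map without a library)."""


class InconsistencyError(ContactForgeError):
    """Internally inconsistent data (e.g. contacts for an amino acid of frequency 0)."""


class InsufficientDataError(ContactForgeError):
    """Not enough observations for the requested statistic."""


class DegenerateInputError(ContactForgeError):
    """Input is degenerate for the requested operation (e.g. S_max <= 0)."""
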