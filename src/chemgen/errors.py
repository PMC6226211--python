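"""Exception types shared across the package."""


class ChemgenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChemgenError, ValueError):
    """A file on disk violates the expected labeled-TSV / GMT dialect."""


class AlignmentError(ChemgenError, ValueError):
    """Two matrices cannot be aligned on a shared axis (e.g. no common strains)."""


class AnnotationError(ChemgenError, ValueError):
    """Invalid term-membership structure (e.g. a cycle in the is_a edge list)."""


class ConfigError(ChemgenError, ValueError):
    """A pipeline configuration is missing or inconsistent."""
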