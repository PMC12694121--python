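"""Exception hierarchy shared across the pipeline stages."""


class BsamapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BsamapError, ValueError):
    """Invalid configuration value or inconsistent option combination."""


class FormatError(BsamapError, ValueError):
    """Malformed input file (VCF/GFF/TSV); message carries context such as
    the offending line number where available."""


class AnnotationError(BsamapError, ValueError):
    """Gene model / reference sequence inconsistency during effect calls."""
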