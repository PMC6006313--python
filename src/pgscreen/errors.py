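"""Exception hierarchy shared across the pipeline."""


class PgscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(PgscreenError):
    """Invalid or inconsistent run configuration."""


class FormatError(PgscreenError):
    """Malformed input file (BED/TSV) content."""


class QCFailure(PgscreenError):
    """Sample-level quality-control failure (e.g. no amplified DNA)."""
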