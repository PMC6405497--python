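"""Exception hierarchy shared across the pipeline."""


class SsrGbsError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(SsrGbsError):
    """Invalid marker panel, sample sheet, override table or run configuration."""


class FormatError(SsrGbsError):
    """Malformed input file (FASTQ/FASTA/TSV)."""


class PipelineError(SsrGbsError):
    """Internal inconsistency between pipeline stages."""
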