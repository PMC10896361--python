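"""Exception hierarchy shared across the package."""


class DnaclrError(Exception):
    """Base class for all package errors."""


class FormatError(DnaclrError):
    """Malformed input file (FASTA/TSV); message names the offending line/row."""


class AlphabetError(DnaclrError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class DegenerateInputError(DnaclrError):
    """Input too short/empty to compute the requested quantity."""


class ConfigError(DnaclrError):
    """Invalid or inconsistent configuration."""


class InputError(DnaclrError):
    """Runtime input violates an operation's precondition."""


class BatchSizeError(InputError):
    """Contrastive batch too small (no negatives exist)."""
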