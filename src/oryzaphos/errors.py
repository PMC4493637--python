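"""Exception hierarchy shared across the package."""


class OryzaPhosError(Exception):
    """Base class for all package-specific failures."""


class DataError(OryzaPhosError):
    """Malformed or inconsistent input data (FASTA, site tables, fragments)."""


class ConfigError(OryzaPhosError):
    """Invalid configuration or parameter combination."""
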