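"""Exception hierarchy shared across the package."""


class PlastosigError(Exception):
    """Base class for all package-specific errors."""


class DataError(PlastosigError):
    """Malformed or inconsistent input data (sequences, alignments, trees)."""


class ConfigError(PlastosigError):
    """Invalid run configuration or command-line arguments."""


class StructureError(DataError):
    """No quadripartite structure could be identified in a sequence."""
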