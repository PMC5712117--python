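"""Error hierarchy shared by all modules.

``FormatError`` marks malformed input files (syntax-level problems);
``DataError`` marks inputs that parse but violate a semantic contract,
e.g. a gene id referenced by a hit table that is absent from the gene
models. The CLI maps these to distinct exit codes.
"""


class VinencError(Exception):
    """Base class for all toolkit errors."""


class FormatError(VinencError):
    """A file does not conform to its declared text format."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class DataError(VinencError):
    """Inputs are well-formed but semantically inconsistent."""
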