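"""Exception hierarchy with stable CLI exit codes."""


class ChromadiffError(Exception):
    """Base class; `exit_code` is what the CLI returns for this failure."""

    exit_code = 1


class FormatError(ChromadiffError):
    """Unsupported file format, bit depth, or channel layout."""

    exit_code = 3


class DimensionMismatchError(ChromadiffError):
    """Image pair does not share identical H x W dimensions."""

    exit_code = 4


class ParameterError(ChromadiffError):
    """Invalid metric parameters or perturbation settings."""

    exit_code = 5


class OutputError(ChromadiffError):
    """Could not write an output file."""

    exit_code = 6
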