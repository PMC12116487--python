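"""Exception hierarchy shared by the library and the command-line tool."""


class DonnError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class InputError(DonnError):
    """Malformed, inconsistent, or out-of-contract user input."""

    exit_code = 2


class FormatError(InputError):
    """A file could not be parsed in the requested format."""


class DivergenceError(DonnError):
    """Training or integration produced non-finite or runaway state."""

    exit_code = 3


class IntegrityError(DonnError):
    """A model archive failed its checksum or version check."""

    exit_code = 2
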