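"""Exception hierarchy. All package errors derive from :class:`KinmotifError`."""


class KinmotifError(Exception):
    """Base class for all errors raised by kinmotif."""

    category = "error"


class ParameterError(KinmotifError, ValueError):
    """An argument value is outside its documented domain."""

    category = "parameter"


class InputError(KinmotifError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""

    category = "input"


class DegenerateDataError(KinmotifError, ValueError):
    """Data is degenerate for the requested operation (all-zero column, zero variance)."""

    category = "degenerate"


class StageError(InputError):
    """A motif matrix was supplied at the wrong processing stage."""

    category = "stage"


class AlphabetError(InputError):
    """A sequence contains a character outside the expected alphabet."""

    category = "alphabet"


class AnchorError(KinmotifError, ValueError):
    """Problems locating a kinase-domain anchor motif (HRD/APE/DFG)."""

    category = "anchor"


class AnchorNotFoundError(AnchorError):
    category = "anchor-not-found"


class AnchorAmbiguityError(AnchorError):
    category = "anchor-ambiguous"


class ParseError(KinmotifError, ValueError):
    """A file does not conform to its dialect; carries line context when known."""

    category = "parse"

    def __init__(self, message: str, line: int | None = None, path: str | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}:"
        if line is not None:
            loc += f"line {line}: "
        super().__init__(loc + message)
        self.line = line
        self.path = path
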