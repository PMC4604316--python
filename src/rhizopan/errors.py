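"""Exception hierarchy used across the package."""


class RhizopanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RhizopanError, ValueError):
    """Malformed input file.

    Parameters
    ----------
    message:
        Human-readable description of the problem.
    path:
        Offending file, if known.
    line:
        1-based line number, if known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class ConsistencyError(RhizopanError, ValueError):
    """Inputs that are individually valid but mutually inconsistent
    (e.g. a matrix strain with no compartment label)."""


class DegenerateTableError(RhizopanError, ValueError):
    """A contingency table with a zero row or column margin, on which the
    chi-square statistic is undefined."""
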