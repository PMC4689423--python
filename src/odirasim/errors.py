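"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI:

* :class:`ParameterError` -> 2 (bad parameter values or ranges)
* :class:`LicensingError`, :class:`PreconditionError` and their subclasses -> 3
* :class:`ParseError` -> 4 (malformed input files)
"""


class OdiraError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(OdiraError, ValueError):
    """A parameter is out of its documented range."""

    exit_code = 2


class LicensingError(OdiraError):
    """An operation that requires an active replication origin was refused.

    Dog-bone extrusion is licensed by an active origin between the two
    inverted repeats (the origin-dependence tenet of the amplification
    mechanism); inactive origins -- the ars228-deletion analogue -- never
    license one.
    """

    exit_code = 3


class PreconditionError(OdiraError):
    """A structural precondition of an operation does not hold."""

    exit_code = 3


class HomologyError(PreconditionError):
    """Integration target absent: no (unique) homology in the chromosome."""


class AssemblyError(PreconditionError):
    """Fork oligos cannot assemble (e.g. non-complementary tails)."""


class DesignError(PreconditionError):
    """An oligo/adapter design request is unsatisfiable."""


class FixtureError(PreconditionError):
    """Synthetic fixture features cannot be placed as requested."""


class ParseError(OdiraError):
    """Malformed input file."""

    exit_code = 4

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
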