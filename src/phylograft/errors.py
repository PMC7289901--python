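"""Exception hierarchy.

All phylograft errors derive from :class:`PhylograftError` so callers can
catch the package's failures with a single except clause while still
distinguishing configuration problems from data problems.
"""


class PhylograftError(Exception):
    """Base class for all phylograft errors."""


class ParameterError(PhylograftError, ValueError):
    """Invalid simulation or analysis parameter."""


class TreeParseError(PhylograftError, ValueError):
    """Malformed Newick/NEXUS input."""


class TraceFormatError(PhylograftError, ValueError):
    """Malformed or inconsistent posterior tree trace."""


class ContractError(PhylograftError, ValueError):
    """An operation's precondition on its input tree was violated."""


class ConfigError(PhylograftError, ValueError):
    """Invalid or inconsistent study configuration."""


class MonophylyError(PhylograftError, ValueError):
    """Outgroup taxa intrude into the ingroup of a subclade sample."""

    def __init__(self, message, intruders=()):
        super().__init__(message)
        self.intruders = frozenset(intruders)


class AgeConflictError(PhylograftError, ValueError):
    """A prepared subclade is older than the stem it must attach below."""
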