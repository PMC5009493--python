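"""Exception hierarchy shared across the pipeline."""


class PairmintError(Exception):
    """Base class for all pairmint errors."""


class FormatError(PairmintError, ValueError):
    """A tabular input file violates its expected format."""


class SBMLParseError(PairmintError, ValueError):
    """An SBML document could not be parsed or lacks required annotations."""


class NoBiomassError(PairmintError, ValueError):
    """No biomass reaction could be located in a metabolic model."""


class MissingSequenceError(PairmintError, KeyError):
    """OTUs referenced by the association table have no sequence record."""


class UnmatchedOTUError(PairmintError, KeyError):
    """An OTU in the association table has no genome match."""


class CommunityBuildError(PairmintError, ValueError):
    """Two single-species models cannot be merged into a community."""


class DependencyError(PairmintError, FileNotFoundError):
    """A pipeline stage is missing an upstream intermediate file."""
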