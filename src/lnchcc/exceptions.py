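"""Named error types raised by lnchcc readers and estimators."""


class LncHccError(Exception):
    """Base class for all lnchcc errors."""


class DuplicateIdError(LncHccError):
    """Duplicate probe or sample identifiers in an input table."""


class NonNumericValueError(LncHccError):
    """A cell of an expression or Ct table could not be parsed as a number."""


class MissingSampleError(LncHccError):
    """A design record references a sample absent from the expression matrix."""


class NonPositiveIntensityError(LncHccError):
    """Intensities must be strictly positive (log2 is taken downstream)."""


class MultiMappingProbeError(LncHccError):
    """A probe maps to more than one transcript; the 1:1 assumption is violated."""


class MalformedRecordError(LncHccError):
    """A BED12/GFF3/annotation line failed validation; carries the line number."""


class InsufficientPairsError(LncHccError):
    """Fewer tumor/normal pairs than a statistical test requires."""


class UnknownChromosomeError(LncHccError):
    """A transcript lies on a chromosome absent from the gene models."""


class MissingCtError(LncHccError):
    """A Ct value needed for a 2^-ddCt computation is absent."""


class ConfigError(LncHccError):
    """An invalid simulation or pipeline configuration."""
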