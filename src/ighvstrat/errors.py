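"""Exception hierarchy.

Every data problem raises an explicit, typed error rather than silently
producing a default value; statistical degeneracies (empty sample, single
class label, constant vector) are errors, not zeros.
"""


class IghvStratError(Exception):
    """Base class for all package errors."""


class VGeneParseError(IghvStratError, ValueError):
    """A V-gene call string could not be parsed into a gene symbol."""


class SchemaError(IghvStratError, ValueError):
    """A clonotype or clinical table is missing required columns."""


class MissingDataError(IghvStratError, ValueError):
    """A required clinical field is absent where silence would be unsafe."""


class UndefinedStatisticError(IghvStratError, ValueError):
    """The requested statistic is undefined for this input
    (empty repertoire, single-class labels, constant vector)."""


class PipelineDependencyError(IghvStratError, RuntimeError):
    """A pipeline stage was requested before the stage it depends on."""
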