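"""Exception hierarchy shared across the pipeline stages."""


class GuidelinkError(Exception):
    """Base class for all package errors."""


class InvalidTermError(GuidelinkError):
    """A term surface form is empty or normalizes to nothing."""


class FormatError(GuidelinkError):
    """An input file is unreadable, lacks mandatory columns, or is mostly malformed."""


class HierarchyError(GuidelinkError):
    """A parent-child cycle was found in a terminology source."""


class DuplicateEntryError(GuidelinkError):
    """Two rows share a (concept_id, source) pair within one vocabulary."""


class AtcFormatError(GuidelinkError):
    """A string does not have a valid ATC code shape."""


class ExtractionError(GuidelinkError):
    """A guideline document lacks the recommendations section."""


class ConsistencyError(GuidelinkError):
    """Cross-stage inputs disagree (e.g. a mention for an unselected document)."""


class ConfigurationError(GuidelinkError):
    """A run or generator configuration is invalid or infeasible."""
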