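"""Exception hierarchy for braincons.

All library errors derive from :class:`BrainconsError` so callers (and the
CLI) can distinguish validation problems from genuine bugs.
"""


class BrainconsError(Exception):
    """Base class for all braincons errors."""


class ValidationError(BrainconsError, ValueError):
    """A graph, edge, node or table violates a structural invariant."""


class SchemaError(ValidationError):
    """A file lacks a required attribute key or has the wrong dialect."""


class HierarchyError(ValidationError):
    """A parcellation-hierarchy table is malformed (duplicates, gaps,
    non-decreasing level sizes, or an ill-defined level-to-level map)."""


class MappingError(BrainconsError, KeyError):
    """A node label is missing from the parcellation hierarchy, or a
    requested level does not exist."""


class InputError(BrainconsError, ValueError):
    """Operation preconditions on user-supplied data are not met
    (too few runs, mismatched node sets, empty vectors, ...)."""


class ConfigError(BrainconsError, ValueError):
    """A policy or simulation configuration is internally inconsistent."""
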