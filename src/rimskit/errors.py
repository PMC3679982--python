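"""Exception hierarchy.

Every operation failure raises a subclass of :class:`RimsError`; the CLI maps
these to a nonzero exit code and a one-line message naming the failed
precondition.
"""


class RimsError(Exception):
    """Base class for all domain errors."""


class NotFoundError(RimsError):
    """An id or name does not resolve to an object."""


class DuplicateNameError(RimsError):
    """A uniqueness constraint (sibling name, template name, ...) failed."""


class PermissionDeniedError(RimsError):
    """The acting user lacks the role, ownership or grant required."""


class ValidationError(RimsError):
    """A value or definition violates its schema."""


class TemplateLockedError(RimsError):
    """Mutation attempted on a template already used by a project."""


class TreeError(RimsError):
    """An operation would break the project tree (cycle, bad parent)."""


class ArchiveError(RimsError):
    """Unsupported or inconsistent archive input."""


class RepositoryError(RimsError):
    """Repository initialisation / consistency problem."""


class TableError(RimsError):
    """Malformed annotation table (ragged rows, duplicate headers, ...)."""
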