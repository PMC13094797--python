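"""Exception hierarchy.

Every failure mode a caller may want to branch on gets its own class;
exit codes in the CLI map one-to-one onto these.
"""

from __future__ import annotations


class StudyflowError(Exception):
    """Base class for all package errors."""


class ConfigError(StudyflowError):
    """Any problem with the project configuration."""


class ConfigSyntaxError(ConfigError):
    """The YAML itself cannot be parsed. Carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ConfigConsistencyError(ConfigError):
    """Cross-references in the configuration do not resolve.

    ``problems`` lists every dangling reference, not just the first.
    """

    def __init__(self, problems: list[str]):
        super().__init__(
            "configuration inconsistent: " + "; ".join(problems)
        )
        self.problems = list(problems)


class UsageError(StudyflowError):
    """An operation was called outside its contract (caller bug, not data)."""


class TransportError(StudyflowError):
    """A file or directory could not be read/written/moved."""


class MigrationError(StudyflowError):
    """The study store holds a schema incompatible with the dictionary."""


class DataIntegrityError(StudyflowError):
    """The store contents violate a structural invariant (e.g. id-change cycle)."""


class PrivacyError(StudyflowError):
    """A privacy transform received input it cannot minimize; fail closed."""
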