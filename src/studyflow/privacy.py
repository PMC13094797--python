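"""Privacy-minimization transforms for potentially identifying fields.

The study stores the minimum identifying precision its analyses need:
dates of birth at month level, residence at 3-digit ZIP prefix (which
encodes a multi-county area), and outright omission for directly
identifying values. Transforms are idempotent and fail closed — no rule
ever emits a value more precise than its input, and input a rule cannot
minimize is dropped or refused rather than passed through.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from .config import ProjectConfig
from .errors import PrivacyError

Transform = Literal[
    "truncate-date-to-month", "truncate-zip-to-3", "drop", "pass"
]

_MONTH_RE = re.compile(r"^[0-9]{4}-[0-9]{2}$")
_FULLDATE_RE = re.compile(r"^[0-9]{4}-[0-9]{2}-[0-9]{2}")
_ZIP_RE = re.compile(r"^[0-9]{5}([0-9]{4}|-[0-9]{4})?$")
_ZIP3_RE = re.compile(r"^[0-9]{3}$")


@dataclass(frozen=True)
class PrivacyRule:
    """A transform bound to one dictionary field."""

    table: str
    field: str
    transform: Transform
    applied_at: Literal["import", "report", "both"] = "import"

    def applies_at(self, stage: str) -> bool:
        return self.applied_at in (stage, "both")


def apply_privacy(value: str, rule: PrivacyRule | str) -> str:
    """Apply one privacy transform to one value.

    Empty input is missing data and passes through empty under every rule.
    Raises :class:`PrivacyError` for a date a truncate rule cannot parse;
    non-US postal codes under ZIP truncation are dropped to empty rather
    than passed through.
    """
    transform = rule.transform if isinstance(rule, PrivacyRule) else rule
    if value == "":
        return ""
    if transform == "pass":
        return value
    if transform == "drop":
        return ""
    if transform == "truncate-date-to-month":
        if _MONTH_RE.match(value):
            return value  # already month-level: idempotent
        if _FULLDATE_RE.match(value):
            return value[:7]
        raise PrivacyError(
            f"cannot truncate non-ISO date {value!r} to month level"
        )
    if transform == "truncate-zip-to-3":
        if _ZIP3_RE.match(value):
            return value  # already truncated
        if _ZIP_RE.match(value):
            return value[:3]
        return ""  # non-US / malformed postal code: drop, never pass through
    raise PrivacyError(f"unknown privacy transform {transform!r}")


def rules_from_config(
    config: ProjectConfig, stage: str | None = None
) -> dict[tuple[str, str], PrivacyRule]:
    """Collect the privacy rules declared in the dictionary, keyed by
    (table, field); optionally filtered to those active at ``stage``."""
    rules: dict[tuple[str, str], PrivacyRule] = {}
    for tname, schema in config.dictionaries.items():
        for f in schema.fields:
            if f.privacy is None or f.privacy.transform == "pass":
                continue
            rule = PrivacyRule(
                table=tname,
                field=f.name,
                transform=f.privacy.transform,
                applied_at=f.privacy.applied_at,
            )
            if stage is None or rule.applies_at(stage):
                rules[(tname, f.name)] = rule
    return rules
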