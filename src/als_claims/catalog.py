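"""ICD-9-CM symptom catalog and wildcard code matching.

The catalog is the rule set that drives every downstream stage: each
*symptom definition* names a diagnosis of interest, the likelihood that
a claim carrying one of its codes reflects a first ALS symptom (``high``
or ``moderate``), and the onset category it indicates (``bulbar`` or
``limb``).  *Analysis groups* collect codes for descriptive tabulation —
symptom/diagnosis groups for prevalence tables and procedure groups for
diagnostic-test utilization — without participating in onset detection.

Codes are compared as dotted strings.  A trailing ``X`` in a pattern is a
family wildcard: ``438.1X`` covers the fourth/fifth-digit expansions
438.10–438.19, and ``359.X`` covers every code in the 359 family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml

LIKELIHOODS = ("high", "moderate")
ONSET_CATEGORIES = ("bulbar", "limb")
SYMPTOM_GROUPS = ("bulbar", "limb", "nerve", "respiratory", "other")
GROUP_KINDS = ("symptom_or_diagnosis", "diagnostic_test")

_DEFAULT_CATALOG_RESOURCE = "default_catalog.yml"


class CatalogError(ValueError):
    """Malformed code pattern or inconsistent catalog definition."""


def normalize_code(code: str) -> str:
    """Return the dotted, uppercase form of an ICD-9-CM diagnosis code.

    Claims extracts frequently omit the decimal point; it is re-inserted
    after the third character (after the fourth for E-codes).  V-codes
    and codes that already contain a dot are passed through apart from
    case folding and whitespace trimming.
    """
    text = str(code).strip().upper()
    if not text:
        raise CatalogError("empty ICD-9-CM code")
    if "." in text or text.startswith("V"):
        return text
    root = 4 if text.startswith("E") else 3
    if len(text) > root:
        return text[:root] + "." + text[root:]
    return text


def _validate_pattern_text(text: str) -> str:
    cleaned = str(text).strip().upper()
    if not cleaned:
        raise CatalogError("empty code pattern")
    n_wild = cleaned.count("X")
    if n_wild > 1:
        raise CatalogError(f"pattern {text!r} has multiple wildcards")
    if n_wild == 1 and not cleaned.endswith("X"):
        raise CatalogError(f"pattern {text!r} has a non-terminal wildcard")
    return cleaned


@dataclass(frozen=True)
class CodePattern:
    """An ICD-9-CM code pattern, optionally ending in an ``X`` wildcard."""

    text: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "text", _validate_pattern_text(self.text))

    @property
    def is_wildcard(self) -> bool:
        return self.text.endswith("X")

    @property
    def prefix(self) -> str:
        """Literal text before the wildcard (the whole text if exact)."""
        return self.text[:-1] if self.is_wildcard else self.text

    def matches(self, code: str) -> bool:
        """True when a normalized code falls under this pattern.

        Exact patterns require string identity.  Wildcard patterns match
        any code whose text begins with the literal prefix; a family
        pattern like ``359.X`` additionally covers the bare root ``359``.
        """
        if not self.is_wildcard:
            return code == self.text
        if code.startswith(self.prefix):
            return True
        return self.prefix.endswith(".") and code == self.prefix[:-1]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text


def parse_code_pattern(text: str) -> CodePattern:
    """Parse and normalize one pattern string, rejecting malformed input."""
    return CodePattern(text)


def matches(pattern: CodePattern, code: str) -> bool:
    """Functional form of :meth:`CodePattern.matches` on a normalized code."""
    return pattern.matches(code)


@dataclass(frozen=True)
class SymptomDefinition:
    """One diagnosis of interest in the onset rule table.

    Parameters
    ----------
    label : str
        Human-readable name of the diagnosis of interest.
    likelihood : {"high", "moderate"}
        Tier of the onset rule: a single high-likelihood code, or two
        distinct moderate-likelihood diagnoses in one quarter, marks the
        first-symptom quarter.
    category : {"bulbar", "limb"}
        Onset category the symptom indicates.
    subgroup : str
        Free-text clinical subgroup (e.g. "Speech", "Gait").
    patterns : tuple of CodePattern
        ICD-9-CM codes or code families for the diagnosis.
    """

    label: str
    likelihood: str
    category: str
    subgroup: str
    patterns: tuple[CodePattern, ...]

    def __post_init__(self) -> None:
        if self.likelihood not in LIKELIHOODS:
            raise CatalogError(f"likelihood must be one of {LIKELIHOODS}, got {self.likelihood!r}")
        if self.category not in ONSET_CATEGORIES:
            raise CatalogError(f"category must be one of {ONSET_CATEGORIES}, got {self.category!r}")
        patterns = tuple(p if isinstance(p, CodePattern) else CodePattern(p) for p in self.patterns)
        if not patterns:
            raise CatalogError(f"symptom definition {self.label!r} has no patterns")
        object.__setattr__(self, "patterns", patterns)

    def matches(self, code: str) -> bool:
        return any(p.matches(code) for p in self.patterns)


@dataclass(frozen=True)
class CodeGroupDefinition:
    """A descriptive code grouping for prevalence or utilization tables.

    ``symptom_or_diagnosis`` groups hold ICD-9-CM patterns matched against
    diagnosis claims and belong to one of the five symptom groups.
    ``diagnostic_test`` groups hold opaque procedure-group identifiers
    matched exactly against procedure claims (real procedure coding
    systems are licensed, and group membership is all the analysis needs).
    """

    label: str
    group_kind: str
    patterns: tuple
    symptom_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group_kind not in GROUP_KINDS:
            raise CatalogError(f"group_kind must be one of {GROUP_KINDS}, got {self.group_kind!r}")
        if self.group_kind == "symptom_or_diagnosis":
            if self.symptom_group not in SYMPTOM_GROUPS:
                raise CatalogError(
                    f"group {self.label!r}: symptom_group must be one of {SYMPTOM_GROUPS}"
                )
            patterns = tuple(
                p if isinstance(p, CodePattern) else CodePattern(p) for p in self.patterns
            )
        else:
            if self.symptom_group is not None:
                raise CatalogError(f"group {self.label!r}: diagnostic tests carry no symptom_group")
            patterns = tuple(str(p) for p in self.patterns)
        if not patterns:
            raise CatalogError(f"group {self.label!r} has no patterns")
        object.__setattr__(self, "patterns", patterns)

    def matches(self, code: str, code_kind: str = "diagnosis") -> bool:
        """True when a claim code of the given kind falls in this group."""
        if self.group_kind == "diagnostic_test":
            return code_kind == "procedure_group" and code in self.patterns
        return code_kind == "diagnosis" and any(p.matches(code) for p in self.patterns)


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen = set()
    for label in labels:
        if label in seen:
            raise CatalogError(f"duplicate {what} label {label!r}")
        seen.add(label)


@dataclass(frozen=True)
class CodeCatalog:
    """Container for the symptom rule table and the analysis groupings."""

    symptom_definitions: tuple[SymptomDefinition, ...]
    analysis_groups: tuple[CodeGroupDefinition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symptom_definitions", tuple(self.symptom_definitions))
        object.__setattr__(self, "analysis_groups", tuple(self.analysis_groups))
        _check_unique((d.label for d in self.symptom_definitions), "symptom definition")
        _check_unique((g.label for g in self.analysis_groups), "analysis group")

    # -- lookup ---------------------------------------------------------
    def classify_code(self, code: str) -> list[SymptomDefinition]:
        """All symptom definitions matching a diagnosis code, in catalog order."""
        normalized = normalize_code(code)
        return [d for d in self.symptom_definitions if d.matches(normalized)]

    def symptom_groups(self) -> list[CodeGroupDefinition]:
        return [g for g in self.analysis_groups if g.group_kind == "symptom_or_diagnosis"]

    def test_groups(self) -> list[CodeGroupDefinition]:
        return [g for g in self.analysis_groups if g.group_kind == "diagnostic_test"]

    def get_group(self, label: str) -> CodeGroupDefinition:
        for g in self.analysis_groups:
            if g.label == label:
                return g
        raise KeyError(f"no analysis group labelled {label!r}")

    def get_definition(self, label: str) -> SymptomDefinition:
        for d in self.symptom_definitions:
            if d.label == label:
                return d
        raise KeyError(f"no symptom definition labelled {label!r}")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "symptom_definitions": [
                {
                    "label": d.label,
                    "likelihood": d.likelihood,
                    "category": d.category,
                    "subgroup": d.subgroup,
                    "patterns": [p.text for p in d.patterns],
                }
                for d in self.symptom_definitions
            ],
            "analysis_groups": [
                {
                    "label": g.label,
                    "group_kind": g.group_kind,
                    **(
                        {"symptom_group": g.symptom_group}
                        if g.group_kind == "symptom_or_diagnosis"
                        else {}
                    ),
                    "patterns": [str(p) for p in g.patterns],
                }
                for g in self.analysis_groups
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CodeCatalog":
        try:
            defs = tuple(
                SymptomDefinition(
                    label=entry["label"],
                    likelihood=entry["likelihood"],
                    category=entry["category"],
                    subgroup=entry.get("subgroup", ""),
                    patterns=tuple(parse_code_pattern(p) for p in entry["patterns"]),
                )
                for entry in payload.get("symptom_definitions", [])
            )
            groups = tuple(
                CodeGroupDefinition(
                    label=entry["label"],
                    group_kind=entry["group_kind"],
                    symptom_group=entry.get("symptom_group"),
                    patterns=tuple(entry["patterns"]),
                )
                for entry in payload.get("analysis_groups", [])
            )
        except KeyError as exc:  # missing required key
            raise CatalogError(f"catalog entry missing field {exc}") from exc
        return cls(symptom_definitions=defs, analysis_groups=groups)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False, allow_unicode=True)

    @classmethod
    def load(cls, path) -> "CodeCatalog":
        with open(path, "r", encoding="utf-8") as handle:
            payload = yaml.safe_load(handle)
        if not isinstance(payload, dict):
            raise CatalogError(f"catalog file {path} does not hold a mapping")
        return cls.from_dict(payload)


def classify_code(catalog: CodeCatalog, code: str) -> list[SymptomDefinition]:
    """Functional form of :meth:`CodeCatalog.classify_code`."""
    return catalog.classify_code(code)


@lru_cache(maxsize=1)
def default_catalog() -> CodeCatalog:
    """The shipped rule set: the full symptom tier table plus the
    prevalence symptom groups and diagnostic-test groups used in the
    published tabulations."""
    source = resources.files("als_claims.data").joinpath(_DEFAULT_CATALOG_RESOURCE)
    payload = yaml.safe_load(source.read_text(encoding="utf-8"))
    return CodeCatalog.from_dict(payload)
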