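"""Code lists defining the four SBCE criteria.

A second breast cancer event (SBCE) is flagged when a patient meets any one of
four criteria, each defined by sets of administrative codes:

1. death from breast cancer (cause-of-death code),
2. a breast procedure together with a matching associated diagnosis on the
   same event record,
3. a systemic-therapy record,
4. a radiotherapy record.

The concrete code lists are deployment configuration, not constants: which
procedure, diagnosis, drug and radiotherapy codes indicate a second event
depends on the jurisdiction's coding systems and on clinical curation. This
module loads such lists from a YAML file (one section per criterion, one
sub-block per data source, codes as a list), validates them, and evaluates
code membership. A synthetic, non-clinical default list ships with the
package for testing and simulation.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "MatchMode",
    "Criterion",
    "LATERALITY_CAPABLE",
    "CodeSet",
    "CriterionDefinition",
    "CodeListRegistry",
    "CodeListError",
    "match_code",
    "load_codelists",
    "default_codelists_path",
    "default_codelists",
]


class MatchMode(str, enum.Enum):
    EXACT = "exact"
    PREFIX = "prefix"


class Criterion(str, enum.Enum):
    """The four SBCE criteria."""

    DEATH_BREAST_CANCER = "death_breast_cancer"
    PROCEDURE_DIAGNOSIS = "procedure_diagnosis"
    SYSTEMIC_TREATMENT = "systemic_treatment"
    RADIOTHERAPY = "radiotherapy"


#: Criteria whose qualifying events carry usable laterality, so that a
#: contralateral second primary can be inferred from them.
LATERALITY_CAPABLE = frozenset(
    {Criterion.PROCEDURE_DIAGNOSIS, Criterion.RADIOTHERAPY}
)


class CodeListError(ValueError):
    """Raised when a code-list file violates the schema or its invariants."""


def _normalize(code: str) -> str:
    return code.strip().upper()


@dataclass(frozen=True)
class CodeSet:
    """A set of codes from one coding system with its matching semantics.

    In ``prefix`` mode a member matches any code it is a prefix of (ICD-style
    hierarchy truncation); ambiguous sets where one member is a prefix of
    another are rejected at construction, since the shorter member would
    shadow the longer one.
    """

    code_system: str
    codes: frozenset[str]
    match_mode: MatchMode = MatchMode.EXACT

    def __post_init__(self) -> None:
        if not self.codes:
            raise CodeListError(
                f"code set for system {self.code_system!r} is empty"
            )
        if self.match_mode is MatchMode.PREFIX:
            members = sorted(self.codes)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    if b.startswith(a):
                        raise CodeListError(
                            f"ambiguous prefix pair in {self.code_system!r}: "
                            f"{a!r} is a prefix of {b!r}"
                        )

    @classmethod
    def from_codes(
        cls,
        code_system: str,
        codes: Iterable[str],
        match_mode: MatchMode | str = MatchMode.EXACT,
        context: str = "",
    ) -> "CodeSet":
        """Build a code set, normalising case/whitespace and deduplicating."""
        raw = [_normalize(c) for c in codes if str(c).strip()]
        unique = frozenset(raw)
        if len(raw) != len(unique):
            dupes = sorted({c for c in unique if raw.count(c) > 1})
            logger.warning(
                "duplicate codes deduplicated%s: %s",
                f" in {context}" if context else "",
                ", ".join(dupes),
            )
        return cls(code_system, unique, MatchMode(match_mode))


def match_code(
    code: str, code_set: CodeSet, code_system: Optional[str] = None
) -> bool:
    """True if ``code`` is a member of ``code_set``.

    If ``code_system`` is given and differs from the set's system the result
    is False: codes from unrelated systems never match, they are simply
    ignored.
    """
    if not code:
        raise ValueError("code must be non-empty")
    if code_system is not None and code_system != code_set.code_system:
        return False
    code = _normalize(code)
    if code_set.match_mode is MatchMode.EXACT:
        return code in code_set.codes
    return any(code.startswith(member) for member in code_set.codes)


@dataclass(frozen=True)
class CriterionDefinition:
    """One SBCE criterion: which sources it reads and which codes qualify.

    ``code_sets`` maps each source the criterion reads to the code set
    matched against the event's own code.  For the procedure+diagnosis
    criterion, ``diagnosis_code_sets`` additionally maps each source to the
    code set matched against the event's associated diagnosis code; an event
    qualifies only when both match.
    """

    criterion_id: Criterion
    source_filters: frozenset[str]
    code_sets: Mapping[str, CodeSet]
    diagnosis_code_sets: Mapping[str, CodeSet] = field(default_factory=dict)
    laterality_capable: bool = False

    def __post_init__(self) -> None:
        expected_lat = self.criterion_id in LATERALITY_CAPABLE
        if self.laterality_capable != expected_lat:
            raise CodeListError(
                f"laterality_capable must be {expected_lat} for "
                f"{self.criterion_id.value}"
            )
        if set(self.code_sets) != set(self.source_filters):
            raise CodeListError(
                f"{self.criterion_id.value}: code_sets keys must equal "
                f"source_filters"
            )
        needs_dx = self.criterion_id is Criterion.PROCEDURE_DIAGNOSIS
        if needs_dx and set(self.diagnosis_code_sets) != set(self.source_filters):
            raise CodeListError(
                "procedure_diagnosis requires a diagnosis code set for each "
                "source"
            )
        if not needs_dx and self.diagnosis_code_sets:
            raise CodeListError(
                f"{self.criterion_id.value} does not take diagnosis code sets"
            )

    def matches_event(
        self,
        source: str,
        code: str,
        code_system: Optional[str] = None,
        diagnosis_code: Optional[str] = None,
        diagnosis_code_system: Optional[str] = None,
    ) -> bool:
        """True if an event from ``source`` with these codes qualifies."""
        if source not in self.source_filters or not code:
            return False
        if not match_code(code, self.code_sets[source], code_system):
            return False
        if self.criterion_id is Criterion.PROCEDURE_DIAGNOSIS:
            if not diagnosis_code:
                return False
            return match_code(
                diagnosis_code,
                self.diagnosis_code_sets[source],
                diagnosis_code_system,
            )
        return True


@dataclass(frozen=True)
class CodeListRegistry:
    """All four criterion definitions plus free-text provenance."""

    criteria: Mapping[Criterion, CriterionDefinition]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c.value for c in Criterion if c not in self.criteria]
        if missing:
            raise CodeListError(
                "missing criterion definition(s): " + ", ".join(missing)
            )

    def __getitem__(self, criterion: Criterion) -> CriterionDefinition:
        return self.criteria[criterion]

    def __iter__(self):
        return iter(Criterion)


def _parse_source_block(
    criterion: Criterion, source: str, block: Mapping
) -> tuple[CodeSet, Optional[CodeSet]]:
    context = f"{criterion.value}/{source}"
    try:
        primary = CodeSet.from_codes(
            str(block["code_system"]),
            block["codes"],
            block.get("match_mode", "exact"),
            context=context,
        )
    except KeyError as exc:
        raise CodeListError(f"{context}: missing key {exc}") from exc
    dx_block = block.get("diagnosis")
    diagnosis = None
    if dx_block is not None:
        diagnosis = CodeSet.from_codes(
            str(dx_block["code_system"]),
            dx_block["codes"],
            dx_block.get("match_mode", "exact"),
            context=f"{context}/diagnosis",
        )
    return primary, diagnosis


def load_codelists(path: str | Path) -> CodeListRegistry:
    """Load and validate a YAML code-list file.

    The file has a ``criteria`` mapping with one section per criterion id
    and one sub-block per source; see ``sbce/data/default_codelists.yml``
    for the layout and ``sbce/data/codelist_schema.json`` for the schema.

    Raises :class:`CodeListError` naming the absent criterion if any of the
    four is missing, and on ambiguous prefix pairs, naming both codes.
    """
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "criteria" not in doc:
        raise CodeListError(f"{path}: expected a mapping with a 'criteria' key")
    sections = doc["criteria"]
    criteria: dict[Criterion, CriterionDefinition] = {}
    for criterion in Criterion:
        if criterion.value not in sections:
            raise CodeListError(
                f"{path}: missing criterion section {criterion.value!r}"
            )
        section = sections[criterion.value]
        if not isinstance(section, dict) or not section:
            raise CodeListError(
                f"{path}: criterion {criterion.value!r} has no source blocks"
            )
        code_sets: dict[str, CodeSet] = {}
        dx_sets: dict[str, CodeSet] = {}
        for source, block in section.items():
            primary, diagnosis = _parse_source_block(criterion, source, block)
            code_sets[source] = primary
            if diagnosis is not None:
                dx_sets[source] = diagnosis
        criteria[criterion] = CriterionDefinition(
            criterion_id=criterion,
            source_filters=frozenset(code_sets),
            code_sets=code_sets,
            diagnosis_code_sets=dx_sets,
            laterality_capable=criterion in LATERALITY_CAPABLE,
        )
    unknown = set(sections) - {c.value for c in Criterion}
    if unknown:
        raise CodeListError(
            f"{path}: unknown criterion section(s): {', '.join(sorted(unknown))}"
        )
    return CodeListRegistry(
        criteria=criteria, provenance=str(doc.get("provenance", str(path)))
    )


def default_codelists_path() -> Path:
    """Path to the packaged synthetic (non-clinical) default code lists."""
    return Path(
        resources.files("sbce").joinpath("data/default_codelists.yml")  # type: ignore[arg-type]
    )


def default_codelists() -> CodeListRegistry:
    """Load the packaged synthetic default code lists."""
    return load_codelists(default_codelists_path())
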