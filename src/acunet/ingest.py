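"""Reading and normalising free-text acupoint prescription records.

A prescription record is the set of acupoints one practitioner selected for
one clinical case. Raw exports carry the acupoints as a single delimited
free-text field, with the usual mess of case differences, spacing, pinyin or
romanised names and non-standard meridian abbreviations; this module maps
every token onto WHO standard nomenclature (two-letter meridian code plus
point number, e.g. ``ST36``, or an extra-point code such as ``EX-LE4``)
before any counting happens.

The bundled alias table is a reconstruction assembled from published
summary tables (pinyin with and without diacritics, Korean romanisations);
users can extend or replace it with :meth:`AliasTable.from_tsv`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, UnknownAcupointError, ValidationError

__all__ = [
    "MERIDIAN_MAX_POINT",
    "AliasTable",
    "RawRecord",
    "PrescriptionRecord",
    "NormalizationReport",
    "is_valid_code",
    "normalize_token",
    "read_prescriptions",
    "build_records",
    "build_count_matrix",
]

# WHO standard nomenclature: 14 meridians with their highest point number,
# and the five extra-point regions.
MERIDIAN_MAX_POINT: dict[str, int] = {
    "LU": 11, "LI": 20, "ST": 45, "SP": 21, "HT": 9, "SI": 19, "BL": 67,
    "KI": 27, "PC": 9, "TE": 23, "GB": 44, "LR": 14, "GV": 28, "CV": 24,
}
EXTRA_REGION_MAX_POINT: dict[str, int] = {
    "HN": 15, "CA": 1, "B": 9, "UE": 11, "LE": 12,
}

# Non-WHO meridian abbreviations still common in clinical free text.
_PREFIX_SYNONYMS = {
    "SJ": "TE", "TB": "TE", "TW": "TE", "DU": "GV", "REN": "CV", "RN": "CV",
    "LIV": "LR", "KD": "KI", "UB": "BL", "P": "PC", "H": "HT",
}

_CODE_RE = re.compile(r"^([A-Z]{1,3})\s*-?\s*0*([1-9]\d*)$")
_EXTRA_RE = re.compile(r"^EX\s*-?\s*(HN|CA|B|UE|LE)\s*-?\s*0*([1-9]\d*)$")


def is_valid_code(code: str) -> bool:
    """True if ``code`` is a canonical WHO acupoint code (``ST36``, ``EX-LE4``)."""
    m = re.fullmatch(r"(LU|LI|ST|SP|HT|SI|BL|KI|PC|TE|GB|LR|GV|CV)([1-9]\d*)", code)
    if m:
        return int(m.group(2)) <= MERIDIAN_MAX_POINT[m.group(1)]
    m = re.fullmatch(r"EX-(HN|CA|B|UE|LE)([1-9]\d*)", code)
    if m:
        return int(m.group(2)) <= EXTRA_REGION_MAX_POINT[m.group(1)]
    return False


def _structural_code(token: str) -> str | None:
    """Parse a token that is already (a variant of) a WHO code, else None."""
    t = token.strip().upper()
    m = _EXTRA_RE.match(t)
    if m:
        code = f"EX-{m.group(1)}{int(m.group(2))}"
        return code if is_valid_code(code) else None
    m = _CODE_RE.match(t)
    if m:
        prefix = _PREFIX_SYNONYMS.get(m.group(1), m.group(1))
        code = f"{prefix}{int(m.group(2))}"
        return code if is_valid_code(code) else None
    return None


def _alias_key(variant: str) -> str:
    """Lookup key: casefold and drop all whitespace and hyphens."""
    return re.sub(r"[\s\-]+", "", variant.casefold())


class AliasTable:
    """Mapping from free-text name variants to canonical acupoint codes.

    Keys are matched case-insensitively, ignoring whitespace and hyphens.
    Every canonical code maps to itself.
    """

    def __init__(self, entries: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for variant, code in (entries or {}).items():
            self.add(variant, code)

    def add(self, variant: str, code: str) -> None:
        if not is_valid_code(code):
            raise ValidationError(
                f"alias target {code!r} (for variant {variant!r}) is not a "
                "valid WHO acupoint code"
            )
        self._map[_alias_key(variant)] = code
        # canonical codes always map to themselves
        self._map.setdefault(_alias_key(code), code)

    def get(self, token: str) -> str | None:
        return self._map.get(_alias_key(token))

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, token: str) -> bool:
        return _alias_key(token) in self._map

    @classmethod
    def from_tsv(cls, path) -> "AliasTable":
        """Load a two-column TSV (variant, canonical_code), UTF-8, with header."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"variant", "canonical_code"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"alias table {path} must have columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        table = cls()
        for variant, code in zip(df["variant"], df["canonical_code"]):
            table.add(str(variant), str(code))
        return table

    @classmethod
    def default(cls) -> "AliasTable":
        """The bundled alias table (reconstructed pinyin/romanised names)."""
        with resources.as_file(
            resources.files("acunet.data").joinpath("aliases.tsv")
        ) as p:
            return cls.from_tsv(p)


def normalize_token(token: str, aliases: AliasTable) -> str:
    """Map one free-text token to its canonical acupoint code.

    Matching is case-insensitive and ignores surrounding whitespace, internal
    spacing and hyphens. Tokens already written as (a variant of) a WHO code
    are canonicalised structurally, including common non-WHO meridian
    abbreviations (``LIV3`` -> ``LR3``, ``Ren12`` -> ``CV12``); anything else
    must be present in the alias table.

    Raises
    ------
    ValidationError
        If the token is empty after trimming.
    UnknownAcupointError
        If the token matches neither the alias table nor the code grammar.
    """
    if not token or not token.strip():
        raise ValidationError("empty acupoint token")
    code = aliases.get(token)
    if code is not None:
        return code
    code = _structural_code(token)
    if code is not None:
        return code
    raise UnknownAcupointError(token.strip())


@dataclass(frozen=True)
class RawRecord:
    """One parsed input row, before any normalisation."""

    practitioner_id: str
    case_id: str
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class PrescriptionRecord:
    """One practitioner's deduplicated acupoint set for one case."""

    practitioner_id: str
    case_id: str
    acupoints: frozenset[str]

    def __post_init__(self):
        if not self.acupoints:
            raise ValidationError(
                f"record ({self.practitioner_id}, {self.case_id}) has an "
                "empty acupoint set"
            )


@dataclass
class NormalizationReport:
    """What batch normalisation dropped or collapsed, for audit."""

    unknown_tokens: list[dict] = field(default_factory=list)
    dedup_events: list[dict] = field(default_factory=list)
    dropped_records: list[dict] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "unknown_tokens": self.unknown_tokens,
                "dedup_events": self.dedup_events,
                "dropped_records": self.dropped_records,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def read_prescriptions(path, token_delimiter: str = ";",
                       sep: str | None = None) -> list[RawRecord]:
    """Read raw prescription rows from a delimited text file.

    The file must have header columns ``practitioner_id``, ``case_id`` and
    ``acupoints``; the acupoints field holds ``token_delimiter``-separated
    free-text names. No normalisation is performed and token order is kept.
    ``sep`` is the column separator (default: inferred, so both CSV and TSV
    parse).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    required = ["practitioner_id", "case_id", "acupoints"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records: list[RawRecord] = []
    for i, row in df.iterrows():
        pid, cid = row["practitioner_id"], row["case_id"]
        if pd.isna(pid) or pd.isna(cid):
            raise FormatError(f"{path}: row {i}: missing practitioner or case id")
        raw = row["acupoints"]
        tokens = ()
        if not pd.isna(raw):
            tokens = tuple(t.strip() for t in str(raw).split(token_delimiter)
                           if t.strip())
        if not tokens:
            raise ValidationError(
                f"record ({pid}, {cid}): empty acupoint field"
            )
        records.append(RawRecord(str(pid), str(cid), tokens))
    return records


def build_records(raw_records: Iterable[RawRecord], aliases: AliasTable,
                  on_unknown: str = "error",
                  ) -> tuple[list[PrescriptionRecord], NormalizationReport]:
    """Normalise raw rows into validated :class:`PrescriptionRecord` sets.

    Tokens are normalised then deduplicated into a set (a prescription is a
    set: the same point written twice is one selection). ``on_unknown`` is
    ``"error"`` (strict: first unknown token aborts) or ``"drop"`` (batch:
    unknown tokens are dropped and reported; records left empty are dropped
    and reported).

    Raises
    ------
    ValidationError
        On a duplicate (practitioner_id, case_id) pair.
    """
    if on_unknown not in ("error", "drop"):
        raise ValidationError(f"on_unknown must be 'error' or 'drop', got {on_unknown!r}")
    report = NormalizationReport()
    seen: set[tuple[str, str]] = set()
    records: list[PrescriptionRecord] = []
    for raw in raw_records:
        key = (raw.practitioner_id, raw.case_id)
        if key in seen:
            raise ValidationError(
                f"duplicate record for (practitioner {raw.practitioner_id!r}, "
                f"case {raw.case_id!r})"
            )
        seen.add(key)
        codes: list[str] = []
        for token in raw.tokens:
            try:
                codes.append(normalize_token(token, aliases))
            except UnknownAcupointError as err:
                if on_unknown == "error":
                    raise
                report.unknown_tokens.append(
                    {"practitioner_id": raw.practitioner_id,
                     "case_id": raw.case_id, "token": err.token}
                )
        unique = frozenset(codes)
        if len(unique) < len(codes):
            report.dedup_events.append(
                {"practitioner_id": raw.practitioner_id,
                 "case_id": raw.case_id,
                 "n_tokens": len(codes), "n_unique": len(unique)}
            )
        if not unique:
            report.dropped_records.append(
                {"practitioner_id": raw.practitioner_id,
                 "case_id": raw.case_id,
                 "reason": "no acupoints survived normalization"}
            )
            continue
        records.append(PrescriptionRecord(raw.practitioner_id, raw.case_id, unique))
    return records, report


def build_count_matrix(records: Sequence[PrescriptionRecord],
                       case_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Count, per case, how many records contain each acupoint.

    Returns a cases × acupoints integer DataFrame. Each record contributes at
    most 1 per acupoint (records hold sets), so every entry is bounded by the
    per-case record count. Rows follow ``case_order`` if given, else first
    appearance; columns are lexicographic.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot build a count matrix from zero records")
    if case_order is None:
        case_order = list(dict.fromkeys(r.case_id for r in records))
    else:
        case_order = list(case_order)
        extra = {r.case_id for r in records} - set(case_order)
        if extra:
            raise ValidationError(f"records contain cases not in case_order: {sorted(extra)}")
    acupoints = sorted({a for r in records for a in r.acupoints})
    counts = pd.DataFrame(0, index=pd.Index(case_order, name="case_id"),
                          columns=acupoints, dtype=int)
    for rec in records:
        for a in rec.acupoints:
            counts.at[rec.case_id, a] += 1
    return counts
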