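"""Swiss-Prot/TrEMBL flat-file parsing and annotation-text cleaning.

Flat files are record-per-entry text: the two leftmost columns carry a line
code (ID, AC, DT, CC, ...) and each record ends with a ``//`` line.  Only
the annotation-bearing lines matter here: ID (entry name), AC (accessions),
DT (creation date) and CC (free-text comments).  Cleaning strips the
structural scaffolding from the comments — topic headings such as
``-!- FUNCTION:``, any copyright block, punctuation and brackets — and
lower-cases the residue, leaving just the words whose reuse statistics the
rest of the package models.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "AnnotationEntry",
    "CleanedText",
    "CleaningConfig",
    "CopyrightMatch",
    "ParseIssue",
    "ParseResult",
    "TruncatedRecordError",
    "MalformedRecordError",
    "ValidationReport",
    "parse_flatfile",
    "strip_structure",
    "clean_text",
    "detect_copyright",
    "validate_counts",
    "write_entry_inventory",
    "DEFAULT_TOPIC_HEADINGS",
    "DEFAULT_COPYRIGHT_SIGNATURES",
]


@dataclass
class AnnotationEntry:
    """One database record: identity, creation date and raw comment lines."""

    entry_name: str
    accessions: list[str]
    creation_date: Optional[date]
    cc_lines: list[str]
    source_version: str = ""

    def __post_init__(self) -> None:
        if not self.entry_name:
            raise ValueError("entry_name must be non-empty")
        if not self.accessions:
            raise ValueError("accessions must be non-empty")

    @property
    def primary_accession(self) -> str:
        return self.accessions[0]


@dataclass
class CleanedText:
    """Cleaned lower-case annotation text of one entry, plus an audit trail."""

    tokens_source: str
    removed_headings: list[tuple[str, int]] = field(default_factory=list)
    removed_copyright: Optional[str] = None
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CopyrightMatch:
    """Contiguous span of cc_lines matched by a copyright signature."""

    start: int  # inclusive index into cc_lines
    end: int  # exclusive
    signature_id: str


class MalformedRecordError(ValueError):
    """Record missing its ID or AC line; carries the record's line span."""

    def __init__(self, message: str, line_span: tuple[int, int]):
        super().__init__(f"{message} (lines {line_span[0]}-{line_span[1]})")
        self.line_span = line_span


class TruncatedRecordError(ValueError):
    """File ended mid-record (content after the last '//' terminator)."""


@dataclass
class ParseIssue:
    message: str
    line_span: tuple[int, int]


class ParseResult(list):
    """List of entries plus recoverable per-record parse issues."""

    def __init__(self, entries: Iterable[AnnotationEntry] = (), issues: Optional[list[ParseIssue]] = None):
        super().__init__(entries)
        self.issues: list[ParseIssue] = issues or []


_MONTHS = {m: i + 1 for i, m in enumerate(
    ["JAN", "FEB", "MAR", "APR", "MAY", "JUN", "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"])}
_DT_DATE = re.compile(r"(\d{1,2})-([A-Z]{3})-(\d{2,4})", re.IGNORECASE)


def parse_dt_date(text: str) -> Optional[date]:
    """Extract a DD-MMM-YYYY or DD-MMM-YY date; 2-digit years pivot at 1950."""
    m = _DT_DATE.search(text)
    if not m:
        return None
    day, mon, year = int(m.group(1)), m.group(2).upper(), int(m.group(3))
    if mon not in _MONTHS:
        return None
    if year < 100:
        year += 1900 if year >= 50 else 2000
    try:
        return date(year, _MONTHS[mon], day)
    except ValueError:
        return None


def parse_flatfile(source, version_label: str = "", *, strict: bool = False) -> ParseResult:
    """Parse a flat file into :class:`AnnotationEntry` objects.

    ``source`` may be text, a path, or an open text/byte stream.  Undecodable
    bytes are replaced with U+FFFD and noted as issues.  Records missing an
    ID or AC line are recoverable: they are skipped and recorded in
    ``result.issues`` (or raised when ``strict=True``).  Content after the
    final ``//`` terminator raises :class:`TruncatedRecordError`.
    """
    text = _read_source(source)
    lines = text.splitlines()

    entries: list[AnnotationEntry] = []
    issues: list[ParseIssue] = []
    if "�" in text:
        issues.append(ParseIssue("undecodable bytes replaced with U+FFFD", (0, len(lines))))

    rec_start = 0
    name: Optional[str] = None
    accs: list[str] = []
    created: Optional[date] = None
    cc: list[str] = []
    in_record = False

    def reset() -> None:
        nonlocal name, accs, created, cc, in_record
        name, accs, created, cc, in_record = None, [], None, [], False

    for lineno, raw in enumerate(lines, start=1):
        if raw.strip() == "//":
            span = (rec_start, lineno)
            if name is None or not accs:
                missing = "ID" if name is None else "AC"
                err = MalformedRecordError(f"record missing {missing} line before '//'", span)
                if strict:
                    raise err
                issues.append(ParseIssue(str(err), span))
            else:
                entries.append(AnnotationEntry(name, accs, created, cc, version_label))
            reset()
            rec_start = lineno
            continue

        code = raw[:2]
        payload = raw[5:] if len(raw) > 5 else ""
        if raw.strip():
            in_record = True
        if code == "ID":
            toks = payload.split()
            if toks:
                name = toks[0]
        elif code == "AC":
            accs.extend(a.strip() for a in payload.replace(";", " ").split() if a.strip())
        elif code == "DT":
            if created is None:
                created = parse_dt_date(payload)
        elif code == "CC":
            cc.append(payload.rstrip())
        # every other line code is ignored

    if in_record and (name is not None or accs or cc):
        raise TruncatedRecordError(
            f"file ends mid-record: content after line {rec_start} has no '//' terminator"
        )
    return ParseResult(entries, issues)


def _read_source(source) -> str:
    if isinstance(source, bytes):
        return source.decode("ascii", errors="replace")
    if isinstance(source, Path):
        return source.read_bytes().decode("ascii", errors="replace")
    if isinstance(source, str):
        if "\n" not in source and Path(source).is_file():
            return Path(source).read_bytes().decode("ascii", errors="replace")
        return source
    data = source.read()
    if isinstance(data, bytes):
        return data.decode("ascii", errors="replace")
    return data


# UniProtKB user-manual comment topics (editable via CleaningConfig / YAML).
DEFAULT_TOPIC_HEADINGS = [
    "ALLERGEN", "ALTERNATIVE PRODUCTS", "BIOPHYSICOCHEMICAL PROPERTIES",
    "BIOTECHNOLOGY", "CATALYTIC ACTIVITY", "CAUTION", "COFACTOR",
    "DATABASE", "DEVELOPMENTAL STAGE", "DISEASE", "DISRUPTION PHENOTYPE",
    "DOMAIN", "ENZYME REGULATION", "ACTIVITY REGULATION", "FUNCTION",
    "INDUCTION", "INTERACTION", "MASS SPECTROMETRY", "MISCELLANEOUS",
    "PATHWAY", "PHARMACEUTICAL", "POLYMORPHISM", "PTM", "RNA EDITING",
    "SEQUENCE CAUTION", "SIMILARITY", "SUBCELLULAR LOCATION", "SUBUNIT",
    "TISSUE SPECIFICITY", "TOXIC DOSE", "WEB RESOURCE",
]

# Known public wordings: the statement introduced at Swiss-Prot release 37,
# and the reworded UniProt-era statements (changed at UniProtKB 4 and 7),
# plus a generic fallback for any other contiguous copyright block.
DEFAULT_COPYRIGHT_SIGNATURES = {
    "swissprot37": [
        r"this\s+swiss-?prot\s+entry\s+is\s+copyright",
    ],
    "uniprotkb4": [
        r"copyrighted\s+by\s+the\s+uniprot\s+consortium",
    ],
    "uniprotkb7": [
        r"distributed\s+under\s+the\s+creative\s+commons",
    ],
    "generic-copyright": [
        r"copyright",
    ],
}


@dataclass
class CleaningConfig:
    """What to strip from comment text before word counting."""

    topic_headings: list[str] = field(default_factory=lambda: list(DEFAULT_TOPIC_HEADINGS))
    # hyphen excluded so hyphenated words survive as single tokens
    punctuation: str = string.punctuation.replace("-", "")
    copyright_signatures: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COPYRIGHT_SIGNATURES.items()})

    @classmethod
    def from_yaml(cls, path) -> "CleaningConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "topic_headings" in data:
            kwargs["topic_headings"] = [str(h).upper() for h in data["topic_headings"]]
        if "punctuation" in data:
            kwargs["punctuation"] = str(data["punctuation"])
        if "copyright_signatures" in data:
            kwargs["copyright_signatures"] = {
                str(k): [str(p) for p in v] for k, v in data["copyright_signatures"].items()}
        return cls(**kwargs)


def detect_copyright(cc_lines: Sequence[str], signatures: Optional[dict[str, list[str]]] = None
                     ) -> Optional[CopyrightMatch]:
    """Find the maximal contiguous cc_lines span matching a copyright signature.

    Matching is case-insensitive and whitespace-tolerant.  A matched line is
    extended backwards over adjacent delimiter rows (runs of dashes) and
    forwards over continuation text up to and including the closing
    delimiter, mirroring how the statements appear in the historical
    releases.  Longest span wins; ties go to the earliest span.
    """
    if signatures is None:
        signatures = DEFAULT_COPYRIGHT_SIGNATURES
    norm = [re.sub(r"\s+", " ", ln).strip().lower() for ln in cc_lines]
    compiled = [(sig_id, re.compile(pat, re.IGNORECASE))
                for sig_id, pats in signatures.items() for pat in pats]

    def is_delim(i: int) -> bool:
        return bool(norm[i]) and set(norm[i]) <= {"-"}

    best: Optional[CopyrightMatch] = None
    for i, line in enumerate(norm):
        hit = next((sig_id for sig_id, rx in compiled if rx.search(line)), None)
        if hit is None:
            continue
        start = i
        while start > 0 and is_delim(start - 1):
            start -= 1
        end = i + 1
        while end < len(norm):
            if norm[end].startswith("-!-"):
                break
            if is_delim(end):
                end += 1
                break
            if not norm[end]:
                break
            end += 1
        cand = CopyrightMatch(start, end, hit)
        if best is None or (cand.end - cand.start) > (best.end - best.start):
            best = cand
    if best is None:
        return None
    # report the most specific signature matching anywhere in the span
    # (generic fallback only if nothing else matches)
    span_lines = norm[best.start:best.end]
    matched = [sig for sig, rx in compiled if any(rx.search(l) for l in span_lines)]
    specific = [s for s in matched if s != "generic-copyright"]
    sig_id = specific[-1] if specific else best.signature_id
    return CopyrightMatch(best.start, best.end, sig_id)


_HEADING_RE = re.compile(r"-!-\s*([A-Z][A-Z0-9 /&'()-]*?)\s*:")


def clean_text(text: str, config: Optional[CleaningConfig] = None) -> str:
    """Punctuation/bracket removal, lower-casing and whitespace collapse.

    Idempotent: cleaning already-clean text is the identity.
    """
    if config is None:
        config = CleaningConfig()
    table = str.maketrans({ch: " " for ch in config.punctuation})
    return re.sub(r"\s+", " ", text.translate(table).lower()).strip()


def strip_structure(entry: AnnotationEntry, config: Optional[CleaningConfig] = None) -> CleanedText:
    """Clean one entry's comment block (extraction steps 2-3).

    Removes any detected copyright block, then topic headings (logged with
    counts; unrecognised heading-like structure is still removed but
    recorded as a warning), then punctuation, brackets and the case/space
    structure.  The result is the entry's bag of annotation words as a
    single lower-case string.
    """
    if config is None:
        config = CleaningConfig()

    lines = list(entry.cc_lines)
    match = detect_copyright(lines, config.copyright_signatures)
    removed_copyright = None
    if match is not None:
        lines = lines[: match.start] + lines[match.end:]
        removed_copyright = match.signature_id

    text = "\n".join(lines)
    heading_counts: dict[str, int] = {}
    warnings: list[str] = []
    known = {h.upper() for h in config.topic_headings}

    def _eat(m: re.Match) -> str:
        heading = re.sub(r"\s+", " ", m.group(1)).strip().upper()
        heading_counts[heading] = heading_counts.get(heading, 0) + 1
        if heading not in known:
            warnings.append(f"unlisted heading-like structure removed: {heading!r}")
        return " "

    text = _HEADING_RE.sub(_eat, text)
    return CleanedText(
        tokens_source=clean_text(text, config),
        removed_headings=sorted(heading_counts.items()),
        removed_copyright=removed_copyright,
        warnings=warnings,
    )


@dataclass
class ValidationReport:
    """Parsed-vs-expected entry count check (never raises; a reporting tool)."""

    parsed: int
    expected: int

    @property
    def delta(self) -> int:
        return self.parsed - self.expected

    @property
    def passed(self) -> bool:
        return self.parsed == self.expected

    def to_json(self) -> str:
        return json.dumps({"parsed": self.parsed, "expected": self.expected,
                           "delta": self.delta, "passed": self.passed})


def validate_counts(entries: Sequence[AnnotationEntry], expected: int) -> ValidationReport:
    if expected < 0:
        raise ValueError("expected entry count must be >= 0")
    return ValidationReport(parsed=len(entries), expected=expected)


def write_entry_inventory(entries: Iterable[AnnotationEntry], path) -> None:
    """TSV inventory: accession, entry_name, creation_date, n_cc_lines."""
    with open(path, "w") as fh:
        fh.write("accession\tentry_name\tcreation_date\tn_cc_lines\n")
        for e in entries:
            d = e.creation_date.isoformat() if e.creation_date else "unknown"
            fh.write(f"{e.primary_accession}\t{e.entry_name}\t{d}\t{len(e.cc_lines)}\n")
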