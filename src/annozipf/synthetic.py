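"""Synthetic Swiss-Prot-style flat files with known ground truth.

Every downstream operation — parsing, cleaning, counting, power-law fitting,
cohort tracking — is testable without any database download: the generator
builds a vocabulary whose word-type frequencies follow a discrete power law
with known exponent above ``x_min`` (plus a separate sub-``x_min``
multinomial head, so tests can distort the head without touching the tail
truth), spreads the tokens over entries' FUNCTION comment blocks, injects
topic headings and optional copyright blocks, and returns both the flat-file
text and a ledger recording every truth a test needs.

Entry prose is deliberately minimal: the statistics, not the text, are what
downstream code consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np

from .flatfile import CleaningConfig, clean_text
from .powerlaw import PowerLawParams, sample

__all__ = ["SyntheticSpec", "generate_corpus", "generate_timeline", "COPYRIGHT_BLOCKS"]


# Emulations of the three historical wordings (Swiss-Prot 37; UniProtKB 4; 7).
COPYRIGHT_BLOCKS: dict[str, list[str]] = {
    "swissprot37": [
        "-" * 71,
        "This SWISS-PROT entry is copyright. It is produced through a",
        "collaboration between the Swiss Institute of Bioinformatics and the",
        "EMBL outstation. There are no restrictions on its use as long as its",
        "content is in no way modified and this statement is not removed.",
        "-" * 71,
    ],
    "uniprotkb4": [
        "-" * 71,
        "Copyrighted by the UniProt Consortium, see http://www.uniprot.org/terms",
        "-" * 71,
    ],
    "uniprotkb7": [
        "-" * 71,
        "Copyrighted by the UniProt Consortium, see http://www.uniprot.org/terms",
        "Distributed under the Creative Commons Attribution-NoDerivs License",
        "-" * 71,
    ],
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset version.

    The tail of the word-frequency distribution follows the discrete power
    law at (``alpha_true``, ``x_min_true``); ``n_head_types`` extra words get
    uniform counts below ``x_min_true``.  Total token mass is implied by the
    drawn counts; ``tokens_per_entry_dispersion`` only controls how unevenly
    that mass is spread over entries (gamma-weighted multinomial).
    """

    seed: int
    n_entries: int = 40
    alpha_true: float = 2.0
    x_min_true: int = 50
    n_tail_types: int = 300
    n_head_types: int = 200
    tokens_per_entry_dispersion: float = 0.5
    copyright: Optional[str] = None  # None or a COPYRIGHT_BLOCKS key
    creation_date_window: tuple[date, date] = (date(1990, 1, 1), date(1995, 12, 1))
    release_date: date = date(1996, 1, 1)
    version_label: str = "synthetic"
    accessions: Optional[list[str]] = None  # explicit arrival script
    accession_start: int = 1

    def __post_init__(self) -> None:
        if self.n_entries < 1:
            raise ValueError("n_entries must be >= 1")
        if not (1 < self.alpha_true < 5):
            raise ValueError("alpha_true must lie in (1, 5)")
        if self.n_tail_types < 1:
            raise ValueError("vocabulary too small: need at least one tail word type")
        if self.copyright is not None and self.copyright not in COPYRIGHT_BLOCKS:
            raise ValueError(f"unknown copyright signature {self.copyright!r}; "
                             f"known: {sorted(COPYRIGHT_BLOCKS)}")
        if self.accessions is not None and len(self.accessions) != self.n_entries:
            raise ValueError("explicit accession list must match n_entries")


def _month_range(window: tuple[date, date]) -> tuple[int, int]:
    a, b = window
    return a.year * 12 + a.month - 1, b.year * 12 + b.month - 1


_MONTH_ABBR = ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
               "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"]


def _dt_line(d: date) -> str:
    return f"DT   {d.day:02d}-{_MONTH_ABBR[d.month - 1]}-{d.year}, integrated into UniProtKB/Swiss-Prot."


def _wrap(tokens: Sequence[str], width: int = 64) -> list[str]:
    lines, cur = [], ""
    for tok in tokens:
        if cur and len(cur) + 1 + len(tok) > width:
            lines.append(cur)
            cur = tok
        else:
            cur = f"{cur} {tok}" if cur else tok
    if cur:
        lines.append(cur)
    return lines


def _draw_word_counts(spec: SyntheticSpec, rng: np.random.Generator
                      ) -> dict[str, int]:
    tail = sample(PowerLawParams(spec.alpha_true, spec.x_min_true),
                  spec.n_tail_types, seed=rng)
    counts = {f"tw{i:05d}": int(c) for i, c in enumerate(tail)}
    if spec.n_head_types and spec.x_min_true > 1:
        head = rng.integers(1, spec.x_min_true, size=spec.n_head_types)
        counts.update({f"hw{i:05d}": int(c) for i, c in enumerate(head)})
    return counts


def _build_entries(spec: SyntheticSpec, rng: np.random.Generator,
                   meta: Sequence[tuple[str, str, date]], word_counts: dict[str, int]
                   ) -> tuple[str, dict]:
    """Assemble flat-file text for the given entry metadata and word counts."""
    words = list(word_counts)
    stream = np.repeat(np.arange(len(words)), [word_counts[w] for w in words])
    rng.shuffle(stream)

    n = len(meta)
    shape = 1.0 / max(spec.tokens_per_entry_dispersion, 1e-6)
    weights = rng.gamma(shape, size=n)
    alloc = rng.multinomial(stream.size, weights / weights.sum())

    records: list[str] = []
    copyright_spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for (acc, name, created), n_tok in zip(meta, alloc):
        toks = [words[i] for i in stream[pos:pos + n_tok]]
        pos += n_tok
        body = _wrap(toks)
        cc_payloads = []
        if body:
            cc_payloads.append(f"-!- FUNCTION: {body[0]}")
            cc_payloads.extend(f"    {ln}" for ln in body[1:])
        else:
            cc_payloads.append("-!- FUNCTION: uncharacterized")
        if spec.copyright is not None:
            start = len(cc_payloads)
            cc_payloads.extend(COPYRIGHT_BLOCKS[spec.copyright])
            copyright_spans[acc] = (start, len(cc_payloads))

        lines = [
            f"ID   {name:<19} Reviewed;          10 AA.",
            f"AC   {acc};",
            _dt_line(created),
            "DE   RecName: Full=Synthetic record;",
        ]
        lines.extend(f"CC   {p}" for p in cc_payloads)
        lines.append("SQ   SEQUENCE   10 AA;  1000 MW;  0123456789ABCDEF CRC64;")
        lines.append("     MKLVINAAAA")
        lines.append("//")
        records.append("\n".join(lines))

    text = "\n".join(records) + "\n"
    ledger = {
        "version_label": spec.version_label,
        "alpha_true": spec.alpha_true,
        "x_min_true": spec.x_min_true,
        "seed": spec.seed,
        "release_date": spec.release_date.isoformat(),
        "word_counts": _with_fillers(word_counts, alloc),
        "copyright_signature": spec.copyright,
        "copyright_spans": {a: list(s) for a, s in copyright_spans.items()},
        "copyright_word_counts": _copyright_word_counts(spec),
        "entries": [{"accession": a, "entry_name": n, "creation_date": d.isoformat()}
                    for a, n, d in meta],
    }
    return text, ledger


def _with_fillers(word_counts: dict[str, int], alloc: np.ndarray) -> dict[str, int]:
    n_empty = int((alloc == 0).sum())
    if n_empty == 0:
        return dict(word_counts)
    out = dict(word_counts)
    out["uncharacterized"] = out.get("uncharacterized", 0) + n_empty
    return out


def _copyright_word_counts(spec: SyntheticSpec) -> dict[str, int]:
    if spec.copyright is None:
        return {}
    tokens = clean_text("\n".join(COPYRIGHT_BLOCKS[spec.copyright]), CleaningConfig()).split()
    per_entry: dict[str, int] = {}
    for t in tokens:
        per_entry[t] = per_entry.get(t, 0) + 1
    return {w: c * spec.n_entries for w, c in per_entry.items()}


def _entry_meta(spec: SyntheticSpec, rng: np.random.Generator,
                start_index: int = 0) -> list[tuple[str, str, date]]:
    lo, hi = _month_range(spec.creation_date_window)
    months = rng.integers(lo, hi + 1, size=spec.n_entries)
    meta = []
    for i in range(spec.n_entries):
        if spec.accessions is not None:
            acc = spec.accessions[i]
        else:
            acc = f"P{spec.accession_start + start_index + i:05d}"
        name = f"SYN{start_index + i:04d}_TEST"
        y, m0 = divmod(int(months[i]), 12)
        meta.append((acc, name, date(y, m0 + 1, 1)))
    return meta


def generate_corpus(spec: SyntheticSpec) -> tuple[str, dict]:
    """One synthetic dataset version: (flat-file text, ground-truth ledger).

    Deterministic: the same spec (including seed) yields byte-identical text.
    The ledger's ``word_counts`` is exactly what parse -> strip -> count
    recovers when copyright blocks are removed; ``copyright_word_counts``
    lists the extra words present if the copyright pass is skipped.
    """
    rng = np.random.default_rng(spec.seed)
    word_counts = _draw_word_counts(spec, rng)
    meta = _entry_meta(spec, rng)
    return _build_entries(spec, rng, meta, word_counts)


def generate_timeline(specs: Sequence[SyntheticSpec]) -> tuple[list[str], dict]:
    """A scripted sequence of dataset versions with carried-forward entries.

    Each spec contributes ``n_entries`` *new* arrivals (accessions scripted
    explicitly or auto-numbered); earlier entries persist in every later
    version.  Annotation text is regenerated per version at that version's
    ``alpha_true``, so exponent drift across versions is ground truth.
    Returns one flat-file text per version plus a ledger with per-version
    arrival sets and word tables.

    Raises if an explicit arrival script repeats an accession.
    """
    if not specs:
        raise ValueError("need at least one version spec")
    flatfiles: list[str] = []
    versions_ledger: list[dict] = []
    all_meta: list[tuple[str, str, date]] = []
    seen: set[str] = set()
    next_index = 0

    for spec in specs:
        new_meta = _entry_meta(
            spec, np.random.default_rng(spec.seed), start_index=next_index)
        for acc, _, _ in new_meta:
            if acc in seen:
                raise ValueError(f"accession {acc} arrives twice in the timeline script")
            seen.add(acc)
        next_index += spec.n_entries
        all_meta = all_meta + new_meta

        rng = np.random.default_rng(spec.seed + 1)
        # per-version vocabulary is redrawn at this version's exponent and
        # spread over the full (carried + new) entry set
        scaled = SyntheticSpec(
            seed=spec.seed, n_entries=len(all_meta), alpha_true=spec.alpha_true,
            x_min_true=spec.x_min_true, n_tail_types=spec.n_tail_types,
            n_head_types=spec.n_head_types,
            tokens_per_entry_dispersion=spec.tokens_per_entry_dispersion,
            copyright=spec.copyright, creation_date_window=spec.creation_date_window,
            release_date=spec.release_date, version_label=spec.version_label)
        word_counts = _draw_word_counts(scaled, rng)
        text, ledger = _build_entries(scaled, rng, all_meta, word_counts)
        ledger["new_accessions"] = sorted(a for a, _, _ in new_meta)
        ledger["all_accessions"] = sorted(a for a, _, _ in all_meta)
        flatfiles.append(text)
        versions_ledger.append(ledger)

    return flatfiles, {"versions": versions_ledger}


def write_ledger(ledger: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=1)
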