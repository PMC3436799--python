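"""Flat-file parsing, cleaning and copyright detection."""

import string
from datetime import date
from io import StringIO

import pytest
from hypothesis import given
from hypothesis import strategies as st

from annozipf import (
    AnnotationEntry, CleaningConfig, clean_text, count_words, detect_copyright,
    parse_flatfile, strip_structure, validate_counts, write_entry_inventory,
)
from annozipf.flatfile import (
    MalformedRecordError, TruncatedRecordError, parse_dt_date,
)
from annozipf.synthetic import COPYRIGHT_BLOCKS, SyntheticSpec, generate_corpus

THREE_RECORDS = """\
ID   ALPHA_ECOLI             Reviewed;          10 AA.
AC   P00001; P90001;
DT   01-AUG-1988, integrated into UniProtKB/Swiss-Prot.
CC   -!- FUNCTION: Catalyzes hydrolysis.
CC       Of many things.
OS   Escherichia coli.
//
ID   BETA_HUMAN              Reviewed;          10 AA.
AC   P00002;
DT   15-JAN-92 (REL. 21, CREATED)
//
ID   GAMMA_YEAST             Reviewed;          10 AA.
AC   P00003;
DT   03-MAR-2001, integrated into UniProtKB/TrEMBL.
CC   -!- SUBCELLULAR LOCATION: Cytoplasm.
CC   -!- FUNCTION: Binds DNA. (By similarity).
CC   -!- FUNCTION: Second function.
CC       continuation one.
CC       continuation two.
//
"""


class TestParse:
    def test_entry_count_equals_terminators(self):
        entries = parse_flatfile(THREE_RECORDS, "v1")
        assert len(entries) == THREE_RECORDS.count("//\n") == 3

    def test_fields_and_cc_order(self):
        a, b, c = parse_flatfile(THREE_RECORDS, "v1")
        assert a.entry_name == "ALPHA_ECOLI"
        assert a.accessions == ["P00001", "P90001"]
        assert a.creation_date == date(1988, 8, 1)
        assert a.cc_lines == ["-!- FUNCTION: Catalyzes hydrolysis.", "    Of many things."]
        assert b.cc_lines == []  # entries without comments are legal
        assert b.creation_date == date(1992, 1, 15)  # 2-digit year pivots at 1950
        assert len(c.cc_lines) == 5
        assert c.cc_lines == [ln[5:] for ln in THREE_RECORDS.splitlines()
                              if ln.startswith("CC") and "GAMMA" not in ln][2:]
        assert all(e.source_version == "v1" for e in (a, b, c))

    def test_non_annotation_lines_ignored(self):
        a = parse_flatfile(THREE_RECORDS)[0]
        assert "Escherichia" not in " ".join(a.cc_lines)

    def test_malformed_record_is_recoverable(self):
        text = "AC   P00001;\n//\n" + THREE_RECORDS
        result = parse_flatfile(text)
        assert len(result) == 3
        assert len(result.issues) == 1
        assert "missing ID" in result.issues[0].message
        assert result.issues[0].line_span == (0, 2)

    def test_malformed_record_strict_raises(self):
        with pytest.raises(MalformedRecordError):
            parse_flatfile("ID   ONLY_NAME   Reviewed;\n//\n", strict=True)

    def test_truncated_final_record(self):
        with pytest.raises(TruncatedRecordError):
            parse_flatfile(THREE_RECORDS + "ID   TRUNC_HUMAN  Reviewed;\nAC   P09999;\n")

    def test_stream_and_bytes_inputs(self):
        assert len(parse_flatfile(StringIO(THREE_RECORDS))) == 3
        result = parse_flatfile(THREE_RECORDS.encode() + b"ID   X\xffY_Z  Reviewed;\nAC   P1;\n//\n")
        assert len(result) == 4
        assert any("undecodable" in i.message for i in result.issues)

    def test_dt_dialects(self):
        assert parse_dt_date("01-AUG-1988 (REL. 08, CREATED)") == date(1988, 8, 1)
        assert parse_dt_date("15-JAN-92 (REL. 21, CREATED)") == date(1992, 1, 15)
        assert parse_dt_date("15-JAN-49") == date(2049, 1, 15)
        assert parse_dt_date("no date here") is None

    def test_roundtrip_against_generator_ledger(self, plain_corpus, parsed_entries):
        _, _, ledger = plain_corpus
        assert len(parsed_entries) == len(ledger["entries"])
        for entry, truth in zip(parsed_entries, ledger["entries"]):
            assert entry.primary_accession == truth["accession"]
            assert entry.entry_name == truth["entry_name"]
            assert entry.creation_date.isoformat() == truth["creation_date"]

    def test_cross_check_against_biopython(self, plain_corpus):
        """Independent parser oracle: Bio.SwissProt must agree on identity,
        dates and comment text for the synthetic fixture."""
        SwissProt = pytest.importorskip("Bio.SwissProt")
        _, text, _ = plain_corpus
        ours = parse_flatfile(text, "syn")
        theirs = list(SwissProt.parse(StringIO(text)))
        assert len(ours) == len(theirs)
        for mine, ref in zip(ours, theirs):
            assert mine.entry_name == ref.entry_name
            assert mine.accessions == ref.accessions
            assert mine.creation_date == parse_dt_date(ref.created[0])
            mine_cc = " ".join(" ".join(mine.cc_lines).split())
            ref_cc = " ".join(" ".join(f"{c}" for c in ref.comments).split())
            assert mine_cc.replace("-!- ", "") == ref_cc


class TestCleaning:
    def test_heading_removed_and_logged(self):
        e = AnnotationEntry("X_T", ["P1"], None, ["-!- FUNCTION: Catalyzes hydrolysis."])
        cleaned = strip_structure(e)
        assert cleaned.tokens_source == "catalyzes hydrolysis"
        assert cleaned.removed_headings == [("FUNCTION", 1)]
        assert cleaned.removed_copyright is None

    def test_unknown_heading_warned_but_removed(self):
        e = AnnotationEntry("X_T", ["P1"], None, ["-!- WIBBLE FROB: some text."])
        cleaned = strip_structure(e)
        assert cleaned.tokens_source == "some text"
        assert cleaned.removed_headings == [("WIBBLE FROB", 1)]
        assert any("WIBBLE FROB" in w for w in cleaned.warnings)

    def test_no_copyright_is_identity_for_copyright_pass(self, parsed_entries):
        # control property: attempted removal has no effect when nothing is there
        cfg_on = CleaningConfig()
        cfg_off = CleaningConfig(copyright_signatures={})
        for e in parsed_entries[:10]:
            on, off = strip_structure(e, cfg_on), strip_structure(e, cfg_off)
            assert on.removed_copyright is None
            assert on.tokens_source == off.tokens_source

    @given(st.text(st.characters(min_codepoint=9, max_codepoint=126),
                   min_size=0, max_size=300))
    def test_clean_text_idempotent_and_punctuation_free(self, text):
        cfg = CleaningConfig()
        once = clean_text(text, cfg)
        assert clean_text(once, cfg) == once
        assert not set(once) & set(cfg.punctuation)
        assert not any(ch.isupper() for ch in once)
        assert "  " not in once

    def test_strip_structure_output_is_clean(self, cleaned_entries):
        cfg = CleaningConfig()
        for c in cleaned_entries:
            assert not set(c.tokens_source) & set(cfg.punctuation)
            assert "CC" not in c.tokens_source
            assert not any(ch.isupper() for ch in c.tokens_source)

    def test_hyphenated_words_survive(self):
        e = AnnotationEntry("X_T", ["P1"], None, ["-!- FUNCTION: Zinc-dependent protease."])
        assert strip_structure(e).tokens_source == "zinc-dependent protease"


class TestCopyright:
    @pytest.mark.parametrize("sig_id", sorted(COPYRIGHT_BLOCKS))
    def test_injected_block_detected_exactly(self, sig_id):
        spec = SyntheticSpec(seed=7, n_entries=6, n_tail_types=50,
                             n_head_types=20, copyright=sig_id)
        text, ledger = generate_corpus(spec)
        for entry in parse_flatfile(text):
            match = detect_copyright(entry.cc_lines)
            start, end = ledger["copyright_spans"][entry.primary_accession]
            assert (match.start, match.end) == (start, end)
            assert match.signature_id == sig_id

    def test_no_copyright_returns_none(self, parsed_entries):
        assert all(detect_copyright(e.cc_lines) is None for e in parsed_entries)

    def test_identical_blocks_get_identical_ids(self, copyright_corpus):
        _, text, _ = copyright_corpus
        ids = {detect_copyright(e.cc_lines).signature_id for e in parse_flatfile(text)}
        assert ids == {"swissprot37"}

    def test_matching_is_case_and_whitespace_tolerant(self):
        lines = ["THIS  swiss-prot   ENTRY IS   Copyright. Blah."]
        m = detect_copyright(lines)
        assert m is not None and m.signature_id == "swissprot37"

    def test_removal_changes_only_copyright_words(self, copyright_corpus):
        spec, text, ledger = copyright_corpus
        entries = list(parse_flatfile(text))
        with_removal = count_words([strip_structure(e) for e in entries])
        without = count_words(
            [strip_structure(e, CleaningConfig(copyright_signatures={})) for e in entries])
        delta = {w: without.counts.get(w, 0) - with_removal.counts.get(w, 0)
                 for w in set(without.counts) | set(with_removal.counts)}
        assert {w: c for w, c in delta.items() if c} == ledger["copyright_word_counts"]


class TestValidation:
    @pytest.mark.parametrize("parsed,expected,passed,delta", [
        (3, 3, True, 0), (3, 4, False, -1), (0, 0, True, 0)])
    def test_report(self, parsed, expected, passed, delta):
        entries = [AnnotationEntry(f"E{i}_T", [f"P{i}"], None, []) for i in range(parsed)]
        rep = validate_counts(entries, expected)
        assert (rep.passed, rep.delta) == (passed, delta)
        assert f'"parsed": {parsed}' in rep.to_json()

    def test_negative_expected_rejected(self):
        with pytest.raises(ValueError):
            validate_counts([], -1)

    def test_inventory_tsv(self, parsed_entries, tmp_path):
        path = tmp_path / "inv.tsv"
        write_entry_inventory(parsed_entries, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "accession\tentry_name\tcreation_date\tn_cc_lines"
        assert len(lines) == len(parsed_entries) + 1
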