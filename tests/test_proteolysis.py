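"""Digestion, FASTA dialect, N-terminal forms, and decoy construction."""

import collections

import numpy as np
import pytest

from ggscan.proteolysis import (
    DECOY_PREFIX,
    METAP_SUSCEPTIBLE,
    ProteinRecord,
    build_decoy_db,
    cleavage_sites,
    digest,
    enumerate_nterm_forms,
    read_fasta,
    write_fasta,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- FASTA


def test_empty_fasta_yields_empty_list(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    assert read_fasta(path) == []


def test_uniprot_header_dialect(tmp_path):
    path = tmp_path / "db.fasta"
    path.write_text(
        ">sp|P12345|TEST_HUMAN some description\nMKAVLR\n"
        ">tr|Q0TEST|FRAG_HUMAN\nXMAAK\n"
        ">CONTAM_1\nmkwv\n"
    )
    records = read_fasta(path)
    assert [r.accession for r in records] == ["P12345", "Q0TEST", "CONTAM_1"]
    assert records[0].source_db == "reviewed"
    assert records[1].source_db == "unreviewed"
    assert records[1].starts_with_X
    assert not records[0].starts_with_X
    # sequences are uppercased; bare headers default to unreviewed
    assert records[2].sequence == "MKWV"
    assert records[2].source_db == "unreviewed"


def test_illegal_residue_reports_line(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">sp|P1|A\nMKAV\n>sp|P2|B\nMK9V\n")
    with pytest.raises(ValueError, match="line 3"):
        read_fasta(path)


def test_fasta_round_trip(tmp_path, rng):
    records = []
    for i in range(10):
        seq = "M" + "".join(rng.choice(list(AA20), size=30))
        source = "reviewed" if i % 2 == 0 else "unreviewed"
        records.append(ProteinRecord(f"P{i:03d}", seq, source_db=source))
    path = tmp_path / "round.fasta"
    write_fasta(records, path)
    assert read_fasta(path) == records


def test_decoy_accession_flagged_on_read(tmp_path):
    path = tmp_path / "db.fasta"
    path.write_text(f">{DECOY_PREFIX}P1\nRVAKM\n")
    (rec,) = read_fasta(path)
    assert rec.is_decoy


# ---------------------------------------------------------------- digestion


def brute_force_digest(sequence, max_missed, specificity, cleave_before_proline=False):
    """Enumerate all substrings satisfying the terminus and missed-cleavage
    predicates directly — the oracle for the digestion algorithm."""
    n = len(sequence)
    sites = set(cleavage_sites(sequence, cleave_before_proline))
    tryptic_starts = {1} | {i + 1 for i in sites}
    if sequence[0] == "M" and n >= 2 and sequence[1] in METAP_SUSCEPTIBLE:
        tryptic_starts.add(2)
    tryptic_ends = {n} | sites
    out = set()
    for s in range(1, n + 1):
        for e in range(s, n + 1):
            nt, ct = s in tryptic_starts, e in tryptic_ends
            if sum(1 for i in sites if s <= i < e) > max_missed:
                continue
            if specificity == "full" and not (nt and ct):
                continue
            if specificity == "semi" and not (nt or ct):
                continue
            out.add((s, e))
    return out


def test_no_cleavage_site_returns_whole_protein():
    protein = ProteinRecord("P1", "MNQASD")
    peptides = digest(protein, max_missed=0, specificity="full")
    assert len(peptides) == 1
    assert peptides[0].sequence == "MNQASD"
    assert peptides[0].fully_tryptic
    # Asn at position 2 is not MetAP-susceptible, so no Met-clipped form;
    # with a susceptible second residue the clipped peptide appears too
    clipped = digest(ProteinRecord("P2", "MAQASD"), max_missed=0)
    assert {p.sequence for p in clipped} == {"MAQASD", "AQASD"}


def test_proline_suppression_and_missed_cleavage_count():
    # K followed by P is not a countable cleavage site by default
    protein = ProteinRecord("P1", "MQLKPMEINPEMLNKK")
    peptides = {(p.start, p.end): p for p in digest(protein, max_missed=1)}
    assert (1, 15) in peptides
    pep = peptides[(1, 15)]
    assert pep.sequence == "MQLKPMEINPEMLNK"
    assert pep.missed_cleavages == 0
    # with cleavage before proline allowed, K4 becomes a countable site
    allowed = {
        (p.start, p.end): p
        for p in digest(protein, max_missed=1, cleave_before_proline=True)
    }
    assert allowed[(1, 15)].missed_cleavages == 1


@pytest.mark.parametrize("specificity", ["full", "semi"])
@pytest.mark.parametrize("max_missed", [0, 2])
def test_digest_matches_brute_force(rng, specificity, max_missed):
    for _ in range(50):
        length = int(rng.integers(5, 41))
        seq = "".join(rng.choice(list(AA20), size=length))
        protein = ProteinRecord("P1", seq)
        got = {(p.start, p.end) for p in digest(protein, max_missed, specificity)}
        expected = brute_force_digest(seq, max_missed, specificity)
        assert got == expected, seq


def test_emitted_peptides_satisfy_terminus_invariants(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list(AA20), size=int(rng.integers(10, 40))))
        protein = ProteinRecord("P1", seq)
        for p in digest(protein, max_missed=2, specificity="semi"):
            assert p.sequence == seq[p.start - 1 : p.end]
            sites = set(cleavage_sites(seq))
            nt = (
                p.start == 1
                or (p.start == 2 and seq[0] == "M"
                    and seq[1] in METAP_SUSCEPTIBLE)
                or (p.start - 1 in sites)
            )
            ct = p.end == len(seq) or p.end in sites
            assert p.nterm_tryptic == nt
            assert p.cterm_tryptic == ct
            assert p.nterm_tryptic or p.cterm_tryptic


# ---------------------------------------------------------------- N-terminal forms


@pytest.mark.parametrize(
    "sequence,expected_starts",
    [
        ("MAVLKWDNQ", [1, 2]),  # Ala at position 2: MetAP-susceptible
        ("MQLKPMEIN", [1]),  # Gln is not in the susceptible set
        ("AVLKWDNQT", [1]),  # no initiator Met to clip
    ],
)
def test_nterm_forms(sequence, expected_starts):
    forms = enumerate_nterm_forms(ProteinRecord("P1", sequence))
    assert [f.start for f in forms] == expected_starts
    assert forms[0].kind == "initiator_met"
    assert len(forms) <= 2


def test_nterm_forms_follow_metap_rule(rng):
    for second in AA20:
        forms = enumerate_nterm_forms(ProteinRecord("P1", "M" + second + "KWDNQ"))
        assert (len(forms) == 2) == (second in METAP_SUSCEPTIBLE)


def test_nterm_forms_reject_x_start_and_decoys():
    with pytest.raises(ValueError, match="X"):
        enumerate_nterm_forms(
            ProteinRecord("F1", "XMAAK", source_db="unreviewed")
        )
    with pytest.raises(ValueError, match="decoy"):
        enumerate_nterm_forms(
            ProteinRecord("REV_P1", "MKAVL", is_decoy=True)
        )


# ---------------------------------------------------------------- decoys


def test_decoy_is_full_reversal():
    db = build_decoy_db([ProteinRecord("P1", "MKAR")])
    assert len(db) == 2
    decoy = db[1]
    assert decoy.sequence == "RAKM"
    assert decoy.accession == DECOY_PREFIX + "P1"
    assert decoy.is_decoy
    assert not db[0].is_decoy


def test_decoy_of_decoy_rejected():
    db = build_decoy_db([ProteinRecord("P1", "MKAR")])
    with pytest.raises(ValueError, match="decoy"):
        build_decoy_db(db)


def test_duplicate_accessions_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        build_decoy_db([ProteinRecord("P1", "MKAR"), ProteinRecord("P1", "MWQR")])


def test_decoys_preserve_residue_composition(rng):
    records = [
        ProteinRecord(f"P{i}", "".join(rng.choice(list(AA20), size=25)))
        for i in range(10)
    ]
    db = build_decoy_db(records)
    targets, decoys = db[:10], db[10:]
    for t, d in zip(targets, decoys):
        assert collections.Counter(t.sequence) == collections.Counter(d.sequence)
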