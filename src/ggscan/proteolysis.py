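"""Proteome parsing, in-silico tryptic digestion, and decoy construction.

The digestion model is LysC + trypsin treated as a single K/R-specific
protease (their specificities coincide on lysine). Cleavage before proline
is suppressed by default, the classical trypsin rule. Protein coordinates
are 1-based inclusive throughout, matching biological residue numbering.

Two protein N-terminal forms are recognized: the initiator methionine
(start 1) and the Met-clipped neo-N-terminus (start 2), the latter only
when methionine aminopeptidase could have acted, i.e. when the second
residue is one of Ala, Cys, Gly, Pro, Ser, Thr, or Val. Pro is kept in
that set as commonly listed for MetAP susceptibility even though
N-terminal acetyltransferases cannot act on Met-Pro; callers who care can
inspect the emitted form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "METAP_SUSCEPTIBLE",
    "DECOY_PREFIX",
    "ProteinRecord",
    "Peptide",
    "NTerminalForm",
    "read_fasta",
    "write_fasta",
    "digest",
    "enumerate_nterm_forms",
    "build_decoy_db",
]

#: The 20 standard residues plus 'X', the unknown-residue placeholder used by
#: unreviewed (TrEMBL-style) database fragments.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

#: Second residues after which Met aminopeptidase typically clips the
#: initiator methionine.
METAP_SUSCEPTIBLE = set("ACGPSTV")

#: Reserved accession prefix marking reversed decoy entries.
DECOY_PREFIX = "REV_"


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome database entry."""

    accession: str
    sequence: str
    source_db: Literal["reviewed", "unreviewed"] = "reviewed"
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue(s) {sorted(bad)} in sequence"
            )

    @property
    def starts_with_X(self) -> bool:
        return self.sequence[0] == "X"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """A digestion product located within its parent protein.

    ``start``/``end`` are 1-based inclusive coordinates in the parent.
    """

    accession: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    nterm_tryptic: bool
    cterm_tryptic: bool

    @property
    def fully_tryptic(self) -> bool:
        return self.nterm_tryptic and self.cterm_tryptic

    @property
    def semi_tryptic(self) -> bool:
        return self.nterm_tryptic != self.cterm_tryptic


@dataclass(frozen=True)
class NTerminalForm:
    """A valid protein N-terminal start position (initiator or Met-clipped)."""

    accession: str
    start: int
    kind: Literal["initiator_met", "met_clipped"]


def _parse_header(header: str, line_no: int) -> tuple[str, str]:
    """Return (accession, source_db) from a UniProt-style FASTA header."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 2 and parts[0] in ("sp", "tr"):
        source = "reviewed" if parts[0] == "sp" else "unreviewed"
        accession = parts[1]
        if not accession:
            raise ValueError(f"line {line_no}: malformed UniProt header {header!r}")
        return accession, source
    return token, "unreviewed"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA with UniProt-dialect headers.

    ``sp|`` entries become reviewed records, ``tr|`` and anything else
    unreviewed. Accessions beginning with the decoy prefix are flagged as
    decoys. Sequences are uppercased; illegal residues raise a parse error
    naming the offending line.
    """
    records: list[ProteinRecord] = []
    # track line numbers for diagnostics while delegating parsing to Bio.SeqIO
    header_lines: dict[int, int] = {}
    with open(path) as fh:
        idx = 0
        for line_no, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines[idx] = line_no
                idx += 1
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        line_no = header_lines.get(idx, 0)
        accession, source = _parse_header(rec.description, line_no)
        seq = str(rec.seq).upper()
        is_decoy = accession.startswith(DECOY_PREFIX)
        try:
            records.append(
                ProteinRecord(accession, seq, source_db=source, is_decoy=is_decoy)
            )
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records with UniProt-dialect headers (sp|/tr|, decoys verbatim)."""
    out = []
    for rec in records:
        if rec.is_decoy:
            header = rec.accession
        else:
            prefix = "sp" if rec.source_db == "reviewed" else "tr"
            header = f"{prefix}|{rec.accession}|{rec.accession}"
        out.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
    SeqIO.write(out, str(path), "fasta-2line")


def cleavage_sites(sequence: str, cleave_before_proline: bool = False) -> list[int]:
    """1-based positions i such that cleavage may occur between i and i+1."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR":
            if not cleave_before_proline and sequence[i] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    specificity: Literal["full", "semi"] = "full",
    cleave_before_proline: bool = False,
) -> list[Peptide]:
    """Enumerate tryptic peptides of a protein.

    ``full`` returns peptides with both termini tryptic; ``semi``
    additionally returns peptides with exactly one tryptic terminus.
    Protein termini count as tryptic, as does start 2 of a Met-initiated
    protein (the Met-clipped N-terminal form). Peptides containing more
    than ``max_missed`` internal cleavage sites are excluded.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if specificity not in ("full", "semi"):
        raise ValueError(f"unknown specificity {specificity!r}")
    seq = protein.sequence
    n = len(seq)
    sites = cleavage_sites(seq, cleave_before_proline)
    site_set = set(sites)

    tryptic_starts = {1} | {i + 1 for i in sites}
    # the Met-clipped neo-N-terminus counts as tryptic only where MetAP
    # could actually have acted
    if seq[0] == "M" and n >= 2 and seq[1] in METAP_SUSCEPTIBLE:
        tryptic_starts.add(2)
    tryptic_ends = {n} | site_set

    import bisect

    def missed(start: int, end: int) -> int:
        # internal sites i with start <= i < end
        lo = bisect.bisect_left(sites, start)
        hi = bisect.bisect_left(sites, end)
        return hi - lo

    out: dict[tuple[int, int], Peptide] = {}

    def emit(start: int, end: int) -> None:
        if (start, end) in out:
            return
        out[(start, end)] = Peptide(
            accession=protein.accession,
            start=start,
            end=end,
            sequence=seq[start - 1 : end],
            missed_cleavages=missed(start, end),
            nterm_tryptic=start in tryptic_starts,
            cterm_tryptic=end in tryptic_ends,
        )

    for s in sorted(tryptic_starts):
        for e in sorted(tryptic_ends):
            if e < s:
                continue
            if missed(s, e) > max_missed:
                break
            emit(s, e)

    if specificity == "semi":
        for s in sorted(tryptic_starts):
            for e in range(s, n + 1):
                if e in tryptic_ends:
                    continue
                if missed(s, e) > max_missed:
                    break
                emit(s, e)
        for e in sorted(tryptic_ends):
            for s in range(e, 0, -1):
                if s in tryptic_starts:
                    continue
                if missed(s, e) > max_missed:
                    break
                emit(s, e)

    return [out[k] for k in sorted(out)]


def enumerate_nterm_forms(protein: ProteinRecord) -> list[NTerminalForm]:
    """Valid N-terminal start positions for GG attachment.

    Always contains the initiator form (start 1); contains the Met-clipped
    form (start 2) iff residue 1 is Met and residue 2 is MetAP-susceptible.
    """
    if protein.is_decoy:
        raise ValueError(f"{protein.accession}: decoy records have no N-terminal forms")
    if protein.starts_with_X:
        raise ValueError(
            f"{protein.accession}: 'X'-start entries are excluded from "
            "N-terminal form enumeration"
        )
    forms = [NTerminalForm(protein.accession, 1, "initiator_met")]
    seq = protein.sequence
    if len(seq) >= 2 and seq[0] == "M" and seq[1] in METAP_SUSCEPTIBLE:
        forms.append(NTerminalForm(protein.accession, 2, "met_clipped"))
    return forms


def build_decoy_db(proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """Append one reversed decoy per target record.

    Targets are returned unchanged, followed by their decoys (full sequence
    reversal, accession prefixed with the reserved decoy tag).
    """
    seen: set[str] = set()
    for rec in proteins:
        if rec.is_decoy:
            raise ValueError(f"{rec.accession}: refusing to build a decoy of a decoy")
        if rec.accession in seen:
            raise ValueError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    decoys = [
        ProteinRecord(
            accession=DECOY_PREFIX + rec.accession,
            sequence=rec.sequence[::-1],
            source_db=rec.source_db,
            is_decoy=True,
        )
        for rec in proteins
    ]
    return list(proteins) + decoys
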