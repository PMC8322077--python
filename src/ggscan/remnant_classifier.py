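"""Classification of diglycine-bearing PSMs against the proteome.

A tryptic peptide observed with a +114.04293 Da diglycine can arise three
ways: ubiquitin conjugated to a lysine side chain (the canonical K-e-GG
remnant), ubiquitin conjugated to a protein alpha-amino group (N-terminal
ubiquitination), or a genome-encoded Gly-Gly pair immediately preceded by
a trypsin-sensitive K/R, which yields an identical-mass "GGX" peptide with
no ubiquitin involved at all. Telling these apart against the sequence
database is the defining computation of this package.

The decision procedure, in dominance order:

1. no GG modification -> NO_GG
2. GG on a lysine side chain -> K_EPS_GG
3. GG on the peptide N-terminus, and any matching protein encodes "GG"
   immediately before the peptide start preceded by K/R (or at the very
   start of the protein) -> INTERNAL_ENCODED_GGX
4. every matching protein is an 'X'-start unreviewed fragment -> REJECT_X_START
5. the peptide start coincides with a valid protein N-terminal form ->
   NTERM_UB_INITIATOR_MET (start 1) or NTERM_UB_NEO_NTERM (start 2)
6. otherwise -> AMBIGUOUS
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .masscalc import Modification
from .proteolysis import ProteinRecord, enumerate_nterm_forms

__all__ = [
    "Verdict",
    "PSM",
    "GGClassification",
    "ProteomeIndex",
    "classify_gg_psm",
    "find_internal_ggx_motifs",
    "x_position_residue",
    "PeptideMappingError",
]


class Verdict(str, Enum):
    NTERM_UB_INITIATOR_MET = "NTERM_UB_INITIATOR_MET"
    NTERM_UB_NEO_NTERM = "NTERM_UB_NEO_NTERM"
    INTERNAL_ENCODED_GGX = "INTERNAL_ENCODED_GGX"
    K_EPS_GG = "K_EPS_GG"
    REJECT_X_START = "REJECT_X_START"
    AMBIGUOUS = "AMBIGUOUS"
    NO_GG = "NO_GG"


class PeptideMappingError(ValueError):
    """Raised when a PSM's peptide maps to no target protein."""


@dataclass
class PSM:
    """One peptide-spectrum match.

    The peptide sequence is the matched residue string; a diglycine remnant
    is recorded as a Modification (position ``"nterm"`` or a lysine index),
    never as extra sequence letters. Exactly one quantitative payload kind
    is populated per experiment type: TMT reporter intensities with
    isolation specificity, or a label-free peak area with a confidence
    score.
    """

    psm_id: str
    peptide_sequence: str
    mods: list[Modification] = field(default_factory=list)
    charge: int = 2
    observed_mz: float = 0.0
    search_score: float = 0.0
    run_id: str = ""
    sample_id: str = ""
    decoy: bool = False
    # TMT payload
    reporter_intensities: Optional[dict[str, float]] = None
    isolation_specificity: Optional[float] = None
    fraction: Optional[str] = None
    # LFQ payload
    peak_area: Optional[float] = None
    quant_confidence: Optional[float] = None
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        gg_positions = [m.position for m in self.mods if m.name.startswith("GG")]
        if len(gg_positions) > len(set(gg_positions)):
            raise ValueError(f"{self.psm_id}: duplicate GG positions")
        if self.reporter_intensities is not None and self.peak_area is not None:
            raise ValueError(f"{self.psm_id}: both TMT and LFQ payloads present")

    @property
    def gg_mod(self) -> Optional[Modification]:
        for m in self.mods:
            if m.name.startswith("GG"):
                return m
        return None

    @property
    def summed_reporter(self) -> Optional[float]:
        if self.reporter_intensities is None:
            return None
        return float(sum(self.reporter_intensities.values()))


@dataclass(frozen=True)
class GGClassification:
    """The verdict for one GG-bearing PSM plus its mapping evidence."""

    psm_id: str
    verdict: Verdict
    accession: Optional[str] = None
    start: Optional[int] = None
    encoded_gg: bool = False


class ProteomeIndex:
    """Exact-substring lookup of peptides in the target proteome.

    Decoy records are never indexed: decoys enter the FDR estimate but are
    never classified as biological events.
    """

    def __init__(self, proteome: Sequence[ProteinRecord]):
        self.targets = [r for r in proteome if not r.is_decoy]
        self._forms: dict[str, dict[int, str]] = {}
        for rec in self.targets:
            if rec.starts_with_X:
                continue
            self._forms[rec.accession] = {
                f.start: f.kind for f in enumerate_nterm_forms(rec)
            }

    def locate(self, peptide: str) -> list[tuple[ProteinRecord, int]]:
        """All (record, 1-based start) occurrences of ``peptide``."""
        hits: list[tuple[ProteinRecord, int]] = []
        for rec in self.targets:
            pos = rec.sequence.find(peptide)
            while pos != -1:
                hits.append((rec, pos + 1))
                pos = rec.sequence.find(peptide, pos + 1)
        return hits

    def nterm_form_kind(self, accession: str, start: int) -> Optional[str]:
        return self._forms.get(accession, {}).get(start)


def find_internal_ggx_motifs(protein: ProteinRecord) -> list[int]:
    """1-based positions p where residues (p, p+1) are "GG" and residue
    p-1 is K or R — the genome-encoded internal GGX motif exposed by
    trypsin cleavage (R/KGGXXXX)."""
    seq = protein.sequence
    return [
        p
        for p in range(2, len(seq))
        if seq[p - 1] == "G" and seq[p] == "G" and seq[p - 2] in "KR"
    ]


def _encoded_gg_explains(record: ProteinRecord, start: int) -> bool:
    """True when a genome-encoded GG immediately precedes ``start``.

    Fires either when positions (start-2, start-1) are "GG" with a K/R at
    start-3, or when the encoded GG sits at protein positions 1-2 (an
    unmodified N-terminal peptide of a GG-starting protein would be
    indistinguishable)."""
    seq = record.sequence
    if start >= 3 and seq[start - 3 : start - 1] == "GG":
        if start == 3:
            return True
        if seq[start - 4] in "KR":
            return True
    return False


def classify_gg_psm(
    psm: PSM, index: ProteomeIndex, any_start_neo: bool = False
) -> GGClassification:
    """Classify one PSM per the dominance order documented in the module.

    ``any_start_neo`` enables a permissive exploration mode in which any
    internal peptide start (signal-peptide removal, internal proteolysis)
    counts as a neo-N-terminus; by default only Met-clipped start 2 does.
    """
    gg = psm.gg_mod
    if gg is None:
        return GGClassification(psm.psm_id, Verdict.NO_GG)
    if isinstance(gg.position, int):
        # GG on a lysine side chain: canonical ubiquitination remnant
        return GGClassification(psm.psm_id, Verdict.K_EPS_GG)

    hits = index.locate(psm.peptide_sequence)
    if not hits:
        raise PeptideMappingError(
            f"{psm.psm_id}: peptide {psm.peptide_sequence!r} not found in any "
            "target protein"
        )

    for rec, start in hits:
        if _encoded_gg_explains(rec, start):
            return GGClassification(
                psm.psm_id,
                Verdict.INTERNAL_ENCODED_GGX,
                accession=rec.accession,
                start=start,
                encoded_gg=True,
            )

    if all(rec.starts_with_X for rec, _ in hits):
        rec, start = hits[0]
        return GGClassification(
            psm.psm_id, Verdict.REJECT_X_START, accession=rec.accession, start=start
        )

    nterm_hits = [
        (rec, start)
        for rec, start in hits
        if not rec.starts_with_X
        and (
            index.nterm_form_kind(rec.accession, start) is not None
            or (any_start_neo and start > 1)
        )
    ]
    if nterm_hits:
        # initiator-Met matches dominate Met-clipped neo-N-termini
        nterm_hits.sort(key=lambda h: h[1])
        rec, start = nterm_hits[0]
        verdict = (
            Verdict.NTERM_UB_INITIATOR_MET
            if start == 1
            else Verdict.NTERM_UB_NEO_NTERM
        )
        return GGClassification(
            psm.psm_id, verdict, accession=rec.accession, start=start
        )

    rec, start = hits[0]
    return GGClassification(
        psm.psm_id, Verdict.AMBIGUOUS, accession=rec.accession, start=start
    )


def x_position_residue(psm: PSM) -> str:
    """The "X" of a GGX peptide: residue 1 of the matched sequence
    (position 3 counting the two remnant glycines)."""
    gg = psm.gg_mod
    if gg is None or not gg.is_nterm:
        raise ValueError(f"{psm.psm_id}: no N-terminal GG modification")
    return psm.peptide_sequence[0]
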