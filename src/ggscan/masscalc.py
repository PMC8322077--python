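"""Monoisotopic mass arithmetic for peptides and their fragment ions.

Everything downstream of the search engine needs exact neutral masses:
the precursor m/z window filter, the ppm-error feature of the discriminant,
and the theoretical m/z anchors used for cross-run quantification. All
constants are monoisotopic and carried to at least five decimal places;
published modification deltas are conventionally printed at four decimals,
which is treated as reporting precision, not storage precision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASS",
    "WATER",
    "PROTON",
    "Modification",
    "ModificationRegistry",
    "DEFAULT_REGISTRY",
    "TheoreticalIon",
    "peptide_mass",
    "precursor_mz",
    "fragment_ions",
    "ppm_error",
]

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

#: Monoisotopic mass of water (Da), added once per intact peptide.
WATER = 18.0105646

#: Mass of a proton (Da) used for charge-state arithmetic.
PROTON = 1.0072765

# Terminal markers used in Modification.position.
NTERM = "nterm"

_TARGETS = {
    "anywhere",
    "peptide_nterm",
    "protein_nterm",
    "lysine_sidechain",
    "cysteine",
    "methionine",
}


@dataclass(frozen=True)
class Modification:
    """A single localized mass modification on a peptide.

    ``position`` is either the 1-based residue index within the peptide or
    the string ``"nterm"`` for an alpha-amino (peptide N-terminal) attachment.
    """

    name: str
    target: str
    delta_mass: float
    position: int | str = NTERM

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ValueError(f"unknown modification target {self.target!r}")
        if isinstance(self.position, str) and self.position != NTERM:
            raise ValueError(f"bad modification position {self.position!r}")

    @property
    def is_nterm(self) -> bool:
        return self.position == NTERM


class ModificationRegistry:
    """Named modification deltas, serializable as a small TSV."""

    def __init__(self, entries: dict[str, tuple[str, float]] | None = None):
        self._entries: dict[str, tuple[str, float]] = dict(entries or {})

    def add(self, name: str, target: str, delta_mass: float) -> None:
        self._entries[name] = (target, float(delta_mass))

    def delta(self, name: str) -> float:
        return self._entries[name][1]

    def names(self) -> list[str]:
        return sorted(self._entries)

    def make(self, name: str, position: int | str = NTERM) -> Modification:
        target, delta = self._entries[name]
        return Modification(name, target, delta, position)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["name", "target", "delta_mass"])
            for name in self.names():
                target, delta = self._entries[name]
                writer.writerow([name, target, f"{delta:.5f}"])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ModificationRegistry":
        reg = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                reg.add(row["name"], row["target"], float(row["delta_mass"]))
        return reg


#: Built-in registry covering the fixed/variable modifications of the workflow:
#: the diglycine (GG) ubiquitin remnant, carbamidomethyl-Cys, Met oxidation,
#: and the isobaric TMT label.
DEFAULT_REGISTRY = ModificationRegistry(
    {
        "GG": ("peptide_nterm", 114.04293),
        "GG_K": ("lysine_sidechain", 114.04293),
        "Carbamidomethyl": ("cysteine", 57.02146),
        "Oxidation": ("methionine", 15.99491),
        "TMT": ("peptide_nterm", 229.16293),
        "TMT_K": ("lysine_sidechain", 229.16293),
    }
)


@dataclass(frozen=True)
class TheoreticalIon:
    """One b- or y-series fragment ion at a given charge."""

    series: str  # "b" or "y"
    index: int  # ordinal along the series, 1-based
    charge: int
    mz: float


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in MONOISOTOPIC_RESIDUE_MASS:
            raise ValueError(
                f"residue {aa!r} at position {i} has no defined monoisotopic mass"
            )


def _check_mods(sequence: str, mods: Sequence[Modification]) -> None:
    seen: set[int | str] = set()
    for mod in mods:
        if isinstance(mod.position, int):
            if not 1 <= mod.position <= len(sequence):
                raise ValueError(
                    f"modification {mod.name} at position {mod.position} outside "
                    f"peptide of length {len(sequence)}"
                )
        if mod.position in seen:
            raise ValueError(f"multiple modifications at position {mod.position}")
        seen.add(mod.position)


def peptide_mass(sequence: str, mods: Sequence[Modification] = ()) -> float:
    """Neutral monoisotopic mass: residues + one water + modification deltas."""
    _check_sequence(sequence)
    _check_mods(sequence, mods)
    mass = sum(MONOISOTOPIC_RESIDUE_MASS[aa] for aa in sequence) + WATER
    return mass + sum(m.delta_mass for m in mods)


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """m/z of the [M + charge*H]^charge+ ion."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (neutral_mass + charge * PROTON) / charge


def fragment_ions(
    sequence: str,
    mods: Sequence[Modification] = (),
    max_charge: int = 1,
) -> list[TheoreticalIon]:
    """Theoretical b/y fragment ions up to ``max_charge``.

    N-terminal modifications (the GG remnant, TMT) ride with the b series
    from b1 onward; a modification at residue ``p`` contributes to b_i for
    i >= p and to y_j for j >= n - p + 1.
    """
    _check_sequence(sequence)
    _check_mods(sequence, mods)
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(sequence)
    # cumulative residue masses from each terminus
    prefix = [0.0]
    for aa in sequence:
        prefix.append(prefix[-1] + MONOISOTOPIC_RESIDUE_MASS[aa])

    nterm_delta = sum(m.delta_mass for m in mods if m.is_nterm)
    ions: list[TheoreticalIon] = []
    for i in range(1, n):
        b_neutral = prefix[i] + nterm_delta
        y_neutral = (prefix[n] - prefix[n - i]) + WATER
        for m in mods:
            if isinstance(m.position, int):
                if m.position <= i:
                    b_neutral += m.delta_mass
                if m.position > n - i:
                    y_neutral += m.delta_mass
        for z in range(1, max_charge + 1):
            ions.append(TheoreticalIon("b", i, z, (b_neutral + z * PROTON) / z))
            ions.append(TheoreticalIon("y", i, z, (y_neutral + z * PROTON) / z))
    return ions


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def write_ions_tsv(ions: Iterable[TheoreticalIon], path: str | Path) -> None:
    """Export a theoretical spectrum as TSV (series, index, charge, mz)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["series", "index", "charge", "mz"])
        for ion in ions:
            writer.writerow([ion.series, ion.index, ion.charge, f"{ion.mz:.5f}"])
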