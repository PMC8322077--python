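"""Table I/O and the compact modification-string codec.

PSM tables travel as TSV. Modifications are encoded per PSM as a
semicolon-joined token list, e.g. ``GG@nterm;Carbamidomethyl@9;GG_K@6``,
where the suffix after ``@`` is either ``nterm`` or a 1-based residue
position within the peptide.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .masscalc import DEFAULT_REGISTRY, Modification, NTERM

__all__ = [
    "encode_mods",
    "decode_mods",
    "read_psm_table",
    "write_psm_table",
    "read_design",
    "write_design",
]


def encode_mods(mods: Sequence[Modification]) -> str:
    tokens = []
    for m in mods:
        pos = NTERM if m.is_nterm else str(m.position)
        tokens.append(f"{m.name}@{pos}")
    return ";".join(tokens)


def decode_mods(encoded: str) -> list[Modification]:
    if not encoded or pd.isna(encoded):
        return []
    mods = []
    for token in str(encoded).split(";"):
        name, _, pos = token.partition("@")
        position: int | str = NTERM if pos == NTERM else int(pos)
        mods.append(DEFAULT_REGISTRY.make(name, position))
    return mods


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str, "mods": str})
    if "mods" in df.columns:
        df["mods"] = df["mods"].fillna("")
    if "decoy" in df.columns:
        df["decoy"] = df["decoy"].astype(bool)
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
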