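"""Substrate calling, experiment intersection, and sequence-preference
profiling of N-terminally ubiquitinated sites.

A feature (one protein N-terminal site, keyed by accession and site kind)
is called in a contrast when its estimated log2 fold change strictly
exceeds the cutoff and its unadjusted model p-value falls strictly below
the significance gate; a high-confidence substrate passes every required
contrast. Profiling covers the residue frequency at the "X" position of
GGX peptides, position probability / information-content matrices for
sequence logos, and Met-aminopeptidase compatibility annotations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .proteolysis import METAP_SUSCEPTIBLE, ProteinRecord

__all__ = [
    "call_substrates",
    "intersect_experiments",
    "residue_frequency_profile",
    "LogoMatrix",
    "sequence_logo_matrix",
    "metap_compatibility",
]

AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")


def call_substrates(
    results: pd.DataFrame,
    required_contrasts: Sequence[str],
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    use_adjusted_p: bool = False,
) -> pd.DataFrame:
    """Turn contrast results into per-feature substrate calls.

    ``results`` is the long table from :func:`ggscan.quant_stats.fit_contrasts`.
    Pass in a contrast requires log2FC > lfc_min and p < p_max (both
    strict). ``called`` marks a pass in at least one required contrast —
    the per-experiment notion of a substrate; ``high_confidence`` marks a
    pass in every required contrast. Features missing an estimable result
    for a required contrast are flagged (``complete`` False) and cannot be
    high-confidence.
    """
    required = list(required_contrasts)
    if not required:
        raise ValueError("at least one required contrast")
    sub = results[results["contrast"].isin(required)]
    pcol = "p_adj" if use_adjusted_p else "p"
    rows = []
    for feature, grp in sub.groupby("feature_id", sort=True):
        rec: dict = {"feature_id": feature}
        passes = {}
        complete = True
        for contrast in required:
            g = grp[grp["contrast"] == contrast]
            if len(g) == 0 or not bool(g["estimable"].iloc[0]):
                passes[contrast] = False
                complete = False
                rec[f"log2FC_{contrast}"] = np.nan
                rec[f"p_{contrast}"] = np.nan
                continue
            lfc = float(g["log2FC"].iloc[0])
            p = float(g[pcol].iloc[0])
            rec[f"log2FC_{contrast}"] = lfc
            rec[f"p_{contrast}"] = p
            passes[contrast] = (lfc > lfc_min) and (p < p_max)
        for contrast, ok in passes.items():
            rec[f"pass_{contrast}"] = ok
        rec["complete"] = complete
        rec["called"] = any(passes.values())
        rec["high_confidence"] = complete and all(passes.values())
        rows.append(rec)
    return pd.DataFrame(rows)


def intersect_experiments(call_sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Venn region counts across named experiments.

    Returns a mapping from each non-empty membership combination (a sorted
    tuple of experiment names) to the number of items found in exactly
    those experiments. Region counts sum to the union size.
    """
    names = sorted(call_sets)
    if len(names) < 2:
        raise ValueError("need at least two experiments to intersect")
    sets = {n: set(call_sets[n]) for n in names}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            )
            regions[combo] = len(inside - outside)
    return regions


def residue_frequency_profile(
    peptides: Sequence[str], position: int = 1
) -> pd.DataFrame:
    """Residue counts and fractions at a peptide position (default the
    first residue — the "X" of GGX, position 3 counting the remnant
    glycines). Sorted by descending count."""
    if not peptides:
        raise ValueError("empty peptide set")
    residues = [p[position - 1] for p in peptides if len(p) >= position]
    counts = pd.Series(residues).value_counts()
    out = pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
    out.index.name = "residue"
    return out.reset_index()


@dataclass
class LogoMatrix:
    """Position probability matrix with per-position information content.

    Positions are 1-based over a fixed window whose first two positions
    are the remnant glycines. Probabilities at each position sum to one;
    information content is log2(20) minus the Shannon entropy in bits,
    under a uniform 20-letter background.
    """

    probabilities: pd.DataFrame  # positions x residues
    information_bits: np.ndarray

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]


def sequence_logo_matrix(
    peptides: Sequence[str],
    length: int = 6,
    pseudocount: float = 0.5,
) -> LogoMatrix:
    """Smoothed position probabilities for GG-prefixed peptide windows.

    Each peptide is prefixed with the two remnant glycines and padded or
    truncated to ``length``; the pseudocount avoids log(0) at sparse
    positions.
    """
    if not peptides:
        raise ValueError("empty peptide set")
    windows = [("GG" + p)[:length] for p in peptides]
    counts = np.zeros((length, len(AA20)))
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    for w in windows:
        for pos, aa in enumerate(w):
            if aa in aa_index:
                counts[pos, aa_index[aa]] += 1
    probs = counts + pseudocount
    totals = probs.sum(axis=1, keepdims=True)
    probs = np.divide(probs, totals, out=np.full_like(probs, np.nan), where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.log2(len(AA20)) - entropy
    df = pd.DataFrame(probs, index=range(1, length + 1), columns=list(AA20))
    df.index.name = "position"
    return LogoMatrix(df, ic)


def plot_logo(logo: LogoMatrix, path: str) -> None:
    """Minimal information-content bar rendering of a logo matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + logo.length, 3))
    positions = np.arange(1, logo.length + 1)
    bottoms = np.zeros(logo.length)
    for aa in logo.probabilities.columns:
        heights = logo.probabilities[aa].to_numpy() * logo.information_bits
        ax.bar(positions, heights, bottom=bottoms, label=aa, width=0.8)
        bottoms += heights
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_xticks(positions)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def metap_compatibility(
    calls: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    accession_col: str = "accession",
    site_kind_col: str = "site_kind",
) -> pd.DataFrame:
    """Annotate substrate calls with Met-aminopeptidase compatibility.

    For each call: the protein's second residue, whether it is
    MetAP-susceptible (A, C, G, P, S, T, or V), the observed site kind,
    and a ``surprising`` flag for initiator-Met sites whose second residue
    would normally trigger Met removal. Unresolvable accessions are
    flagged rather than dropped.
    """
    by_acc = {r.accession: r for r in proteome if not r.is_decoy}
    rows = []
    for _, call in calls.iterrows():
        acc = call[accession_col]
        kind = call.get(site_kind_col, "")
        rec = by_acc.get(acc)
        if rec is None or len(rec.sequence) < 2:
            rows.append(
                {
                    "accession": acc,
                    "site_kind": kind,
                    "second_residue": None,
                    "metap_susceptible": None,
                    "surprising": None,
                    "resolved": False,
                }
            )
            continue
        second = rec.sequence[1]
        susceptible = second in METAP_SUSCEPTIBLE
        rows.append(
            {
                "accession": acc,
                "site_kind": kind,
                "second_residue": second,
                "metap_susceptible": susceptible,
                "surprising": bool(susceptible and kind == "initiator_met"),
                "resolved": True,
            }
        )
    return pd.DataFrame(rows)
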