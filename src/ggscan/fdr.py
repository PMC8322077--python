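"""Target-decoy discriminant scoring and false-discovery-rate filtering.

PSMs from the reversed-sequence decoy database calibrate the score
threshold: the FDR at threshold t is estimated as the number of decoys
scoring >= t divided by the number of targets scoring >= t. A two-class
linear discriminant (pooled within-class covariance) combines the raw
search score with auxiliary features — absolute precursor ppm error,
peptide length, missed cleavages — into a single score on which the
threshold is set. The asymmetric precursor mass window filter lives here
too, as it is part of the same identification-filtering stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinearDiscriminantScorer",
    "fit_discriminant",
    "FdrResult",
    "compute_fdr_threshold",
    "protein_fdr",
    "mass_tolerance_filter",
]

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = ("search_score", "abs_ppm_error", "length", "missed_cleavages")

MIN_CLASS_SIZE = 20


@dataclass
class LinearDiscriminantScorer:
    """Linear projection oriented so that higher scores are more target-like."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    offset: float
    degenerate: bool = False

    def score(self, features: pd.DataFrame) -> np.ndarray:
        X = features.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        return X @ self.weights - self.offset


def fit_discriminant(
    features: pd.DataFrame,
    is_target: Sequence[bool],
) -> LinearDiscriminantScorer:
    """Fit a two-class LDA on PSM features with decoy labels.

    Requires at least 20 PSMs in each class. The discriminant direction is
    the classical pooled-covariance solution w = S_w^{-1} (mu_t - mu_d).
    If the pooled covariance is numerically degenerate the scorer falls
    back to the raw search score alone, with a logged warning.
    """
    y = np.asarray(is_target, dtype=bool)
    if y.sum() < MIN_CLASS_SIZE or (~y).sum() < MIN_CLASS_SIZE:
        raise ValueError(
            f"need >= {MIN_CLASS_SIZE} targets and >= {MIN_CLASS_SIZE} decoys to "
            "fit the discriminant; fall back to the raw search score"
        )
    names = tuple(features.columns)
    X = features.to_numpy(dtype=float)
    Xt, Xd = X[y], X[~y]
    mu_t, mu_d = Xt.mean(axis=0), Xd.mean(axis=0)
    # pooled within-class covariance
    Sw = (
        (Xt - mu_t).T @ (Xt - mu_t) + (Xd - mu_d).T @ (Xd - mu_d)
    ) / (len(X) - 2)
    degenerate = not np.isfinite(Sw).all() or np.linalg.cond(Sw) > 1e12
    if degenerate:
        logger.warning(
            "pooled covariance is degenerate; falling back to search_score only"
        )
        if "search_score" not in names:
            raise ValueError("degenerate covariance and no search_score feature")
        w = np.array([1.0 if n == "search_score" else 0.0 for n in names])
    else:
        w = np.linalg.solve(Sw, mu_t - mu_d)
    # orient so targets score higher
    if (mu_t - mu_d) @ w < 0:
        w = -w
    offset = float(((mu_t + mu_d) / 2) @ w)
    return LinearDiscriminantScorer(names, w, offset, degenerate)


@dataclass
class FdrResult:
    threshold: float
    retained: np.ndarray  # boolean mask over the input: retained targets
    achieved_fdr: float
    empty: bool = False


def _collapse_best(
    scores: np.ndarray, keys: Sequence | None
) -> tuple[np.ndarray, np.ndarray]:
    """Best-scoring index per key; returns (indices, scores)."""
    if keys is None:
        idx = np.arange(len(scores))
        return idx, scores
    df = pd.DataFrame({"key": list(keys), "score": scores})
    best = df.groupby("key", sort=False)["score"].idxmax().to_numpy()
    return best, scores[best]


def compute_fdr_threshold(
    scores: Sequence[float],
    is_target: Sequence[bool],
    target_fdr: float,
    level: str = "psm",
    peptide_keys: Sequence | None = None,
) -> FdrResult:
    """Choose the most permissive score threshold meeting ``target_fdr``.

    At the peptide level, entries first collapse to the best-scoring PSM
    per peptide key (sequence + modification multiset; charge ignored).
    Candidate thresholds are the observed target scores; the estimate at t
    is (#decoys >= t) / (#targets >= t), and entries scoring exactly t are
    retained (inclusive tie policy). If no threshold achieves the target,
    an empty retained set is returned with a warning.
    """
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must be in (0, 1)")
    if level not in ("psm", "peptide"):
        raise ValueError(f"unknown level {level!r}")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(is_target, dtype=bool)
    if level == "peptide":
        if peptide_keys is None:
            raise ValueError("peptide level requires peptide_keys")
        idx, sc = _collapse_best(scores, peptide_keys)
    else:
        idx, sc = _collapse_best(scores, None)
    yy = y[idx]

    order = np.argsort(-sc, kind="stable")
    sc_sorted = sc[order]
    target_cum = np.cumsum(yy[order])
    decoy_cum = np.cumsum(~yy[order])

    best_threshold = None
    best_fdr = None
    # walk candidate thresholds (observed target scores), most to least strict
    for k in range(len(sc_sorted)):
        if not yy[order][k]:
            continue
        t = sc_sorted[k]
        # include ties at t
        m = np.searchsorted(-sc_sorted, -t, side="right")
        n_t = int(target_cum[m - 1])
        n_d = int(decoy_cum[m - 1])
        est = n_d / n_t if n_t else 0.0
        if est <= target_fdr:
            best_threshold = t
            best_fdr = est
    if best_threshold is None:
        warnings.warn("no threshold achieves the requested FDR; retaining nothing")
        return FdrResult(np.inf, np.zeros(len(scores), dtype=bool), np.nan, empty=True)

    retained_entry = (sc >= best_threshold) & yy
    retained = np.zeros(len(scores), dtype=bool)
    retained[idx[retained_entry]] = True
    if level == "peptide":
        # expand retention from peptides back to all their PSMs
        keys = pd.Series(list(peptide_keys))
        kept_keys = set(keys[retained].tolist())
        retained = (keys.isin(kept_keys) & y).to_numpy()
    return FdrResult(float(best_threshold), retained, float(best_fdr))


def protein_fdr(
    accessions: Sequence[str],
    is_decoy: Sequence[bool],
    scores: Sequence[float] | None = None,
) -> float:
    """Decoy/target ratio after collapsing to the best peptide per protein."""
    acc = pd.Series(list(accessions))
    if len(acc) == 0:
        raise ValueError("no retained peptides to compute protein FDR from")
    df = pd.DataFrame(
        {
            "accession": acc,
            "decoy": np.asarray(is_decoy, dtype=bool),
            "score": np.asarray(scores, dtype=float)
            if scores is not None
            else np.zeros(len(acc)),
        }
    )
    best = df.loc[df.groupby("accession")["score"].idxmax()]
    n_decoy = int(best["decoy"].sum())
    n_target = int((~best["decoy"]).sum())
    if n_target == 0:
        return float("inf")
    return n_decoy / n_target


def mass_tolerance_filter(
    ppm_errors: Sequence[float],
    low_ppm: float = -5.0,
    high_ppm: float = 4.0,
) -> np.ndarray:
    """Boolean mask of PSMs inside the asymmetric precursor window
    (inclusive bounds)."""
    e = np.asarray(ppm_errors, dtype=float)
    return (e >= low_ppm) & (e <= high_ppm)
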