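"""Quantitative core: PSM filters, redundancy collapse, cross-run
quantification, median-polish summarization, and per-feature contrasts.

The TMT branch mirrors an isobaric reporter-ion workflow: enumerated PSM
quality filters, collapse of redundant PSMs within and across fractions,
Tukey median polish from peptide x channel intensities to one abundance
per protein N-terminal site per channel, then a per-feature fixed-effects
linear model with Benjamini-Hochberg adjustment across features. The LFQ
branch swaps reporter intensities for per-run precursor peak areas and
adds match-between-runs completion guided by accurate mass and aligned
retention time.

All abundances are handled on the log2 scale; missing values are never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .masscalc import ppm_error as _ppm_error

__all__ = [
    "filter_tmt_psms",
    "filter_lfq_features",
    "collapse_redundant",
    "match_between_runs",
    "MedianPolishResult",
    "tukey_median_polish",
    "summarize_features",
    "QuantMatrix",
    "fit_contrasts",
    "benjamini_hochberg",
]

TMT_MIN_PEPTIDE_LENGTH = 7
TMT_MIN_ISOLATION_SPECIFICITY = 0.50
TMT_MIN_REPORTER = 256.0
TMT_MIN_SUMMED_REPORTER = 30_000.0
LFQ_MIN_PEPTIDE_LENGTH = 7
LFQ_MIN_CONFIDENCE = 71.0
LFQ_MIN_PEAK_AREA = 256.0


def _require_columns(df: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table is missing required column(s): {missing}")


def filter_tmt_psms(
    psms: pd.DataFrame,
    reporter_columns: Sequence[str],
    min_reporter_rule: str = "min_channel",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the five enumerated TMT PSM filters, in order.

    Removes PSMs that are (1) from decoy proteins; (2) from peptides with
    length < 7; (3) with isolation specificity < 50%; (4) with reporter
    ion intensity less than 256; or (5) with summed reporter intensity
    across all channels lower than 30,000. All inequalities are strict, as
    enumerated. Rule 4 is interpreted as the minimum reporter intensity
    across channels by default (``min_reporter_rule="min_channel"``);
    ``"any_channel"`` is the same thing and kept for clarity of intent.

    Returns the retained table and per-rule removal counts.
    """
    _require_columns(psms, ["decoy", "peptide", "isolation_specificity"])
    _require_columns(psms, reporter_columns)
    if min_reporter_rule not in ("min_channel", "any_channel"):
        raise ValueError(f"unknown min_reporter_rule {min_reporter_rule!r}")
    df = psms.copy()
    counts: dict[str, int] = {}

    rule1 = df["decoy"].astype(bool)
    counts["decoy"] = int(rule1.sum())
    df = df[~rule1]

    rule2 = df["peptide"].str.len() < TMT_MIN_PEPTIDE_LENGTH
    counts["short_peptide"] = int(rule2.sum())
    df = df[~rule2]

    rule3 = df["isolation_specificity"] < TMT_MIN_ISOLATION_SPECIFICITY
    counts["isolation_specificity"] = int(rule3.sum())
    df = df[~rule3]

    rule4 = df[list(reporter_columns)].min(axis=1) < TMT_MIN_REPORTER
    counts["low_reporter"] = int(rule4.sum())
    df = df[~rule4]

    rule5 = df[list(reporter_columns)].sum(axis=1) < TMT_MIN_SUMMED_REPORTER
    counts["low_summed_reporter"] = int(rule5.sum())
    df = df[~rule5]

    return df, counts


def filter_lfq_features(psms: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four enumerated label-free PSM filters, in order.

    Removes PSMs (1) from decoy proteins; (2) from peptides with length
    < 7; (3) with quantification confidence scores < 71; or (4) with peak
    area < 256. Strict inequalities as enumerated.
    """
    _require_columns(psms, ["decoy", "peptide", "quant_confidence", "peak_area"])
    df = psms.copy()
    counts: dict[str, int] = {}

    rule1 = df["decoy"].astype(bool)
    counts["decoy"] = int(rule1.sum())
    df = df[~rule1]

    rule2 = df["peptide"].str.len() < LFQ_MIN_PEPTIDE_LENGTH
    counts["short_peptide"] = int(rule2.sum())
    df = df[~rule2]

    rule3 = df["quant_confidence"] < LFQ_MIN_CONFIDENCE
    counts["low_confidence"] = int(rule3.sum())
    df = df[~rule3]

    rule4 = df["peak_area"] < LFQ_MIN_PEAK_AREA
    counts["low_peak_area"] = int(rule4.sum())
    df = df[~rule4]

    return df, counts


def collapse_redundant(
    psms: pd.DataFrame,
    mode: str,
    reporter_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Collapse redundant PSMs to one record per peptide.

    TMT: per peptide and fraction, take the channel-wise maximum reporter
    intensity across PSMs; then keep the fraction whose summed reporter
    intensity is maximal. LFQ: per peptide and run, take the maximum peak
    area.
    """
    if mode == "tmt":
        _require_columns(psms, ["peptide", "fraction"])
        _require_columns(psms, reporter_columns)
        rep = list(reporter_columns)
        keep_first = {
            c: "first"
            for c in psms.columns
            if c not in rep + ["peptide", "fraction"]
        }
        agg = {**{c: "max" for c in rep}, **keep_first}
        per_fraction = (
            psms.groupby(["peptide", "fraction"], sort=False, as_index=False).agg(agg)
        )
        summed = per_fraction[rep].sum(axis=1)
        per_fraction = per_fraction.assign(_summed=summed)
        best = per_fraction.loc[
            per_fraction.groupby("peptide", sort=False)["_summed"].idxmax()
        ]
        return best.drop(columns="_summed").reset_index(drop=True)
    if mode == "lfq":
        _require_columns(psms, ["peptide", "run_id", "peak_area"])
        keep_first = {
            c: "first"
            for c in psms.columns
            if c not in ["peptide", "run_id", "peak_area"]
        }
        agg = {"peak_area": "max", **keep_first}
        return (
            psms.groupby(["peptide", "run_id"], sort=False, as_index=False)
            .agg(agg)
            .reset_index(drop=True)
        )
    raise ValueError(f"unknown collapse mode {mode!r}")


def match_between_runs(
    quantified: pd.DataFrame,
    run_features: pd.DataFrame,
    theoretical_mz: dict[str, float],
    runs: Sequence[str],
    ppm_tol: float = 10.0,
    rt_tol: float = 2.0,
) -> pd.DataFrame:
    """Complete a peptide x run peak-area table using accurate precursor
    mass and aligned retention time.

    ``quantified`` holds directly identified anchors (columns: peptide,
    run_id, peak_area, retention_time); ``run_features`` is the full
    feature list per run (columns: run_id, mz, retention_time, area).
    Retention times are aligned by a per-run median shift estimated from
    the anchors. For each peptide missing in a run, candidate features
    within ``ppm_tol`` of the theoretical m/z and ``rt_tol`` minutes of
    the shifted median anchor RT are searched; the maximum-area candidate
    is transferred. No candidate leaves the cell missing.

    Returns rows (peptide, run_id, peak_area, retention_time, matched)
    where ``matched`` marks transferred (not directly identified) values.
    """
    _require_columns(quantified, ["peptide", "run_id", "peak_area", "retention_time"])
    _require_columns(run_features, ["run_id", "mz", "retention_time", "area"])

    ref_rt = quantified.groupby("peptide")["retention_time"].median()
    # per-run monotone correction: median offset of anchors from reference
    shifts: dict[str, float] = {}
    for run in runs:
        sub = quantified[quantified["run_id"] == run]
        if len(sub):
            shifts[run] = float(
                (sub["retention_time"] - ref_rt[sub["peptide"]].to_numpy()).median()
            )
        else:
            shifts[run] = 0.0

    rows = [
        quantified.assign(matched=False)[
            ["peptide", "run_id", "peak_area", "retention_time", "matched"]
        ]
    ]
    have = set(zip(quantified["peptide"], quantified["run_id"]))
    features_by_run = {run: run_features[run_features["run_id"] == run] for run in runs}
    new_rows = []
    for peptide, mz_theo in theoretical_mz.items():
        if peptide not in ref_rt.index:
            continue  # never identified anywhere: nothing to anchor on
        for run in runs:
            if (peptide, run) in have:
                continue
            feats = features_by_run[run]
            if not len(feats):
                continue
            ppm = 1e6 * (feats["mz"] - mz_theo) / mz_theo
            expected_rt = ref_rt[peptide] + shifts[run]
            ok = (ppm.abs() <= ppm_tol) & (
                (feats["retention_time"] - expected_rt).abs() <= rt_tol
            )
            if ok.any():
                best = feats.loc[ok].sort_values("area", ascending=False).iloc[0]
                new_rows.append(
                    {
                        "peptide": peptide,
                        "run_id": run,
                        "peak_area": float(best["area"]),
                        "retention_time": float(best["retention_time"]),
                        "matched": True,
                    }
                )
    if new_rows:
        rows.append(pd.DataFrame(new_rows))
    return pd.concat(rows, ignore_index=True)


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int

    @property
    def col_abundance(self) -> np.ndarray:
        """Per-column (per-sample) abundance: overall + column effect."""
        return self.overall + self.col_effects


def tukey_median_polish(
    matrix: np.ndarray,
    eps: float = 0.01,
    max_iter: int = 10,
) -> MedianPolishResult:
    """Robust additive decomposition x = overall + row + col + residual.

    Alternating row/column median sweeps with re-centering, following the
    reference R implementation (``stats::medpolish``): iterate until the
    sum of absolute residuals changes by less than ``eps`` relatively, or
    ``max_iter`` sweeps. Missing values are ignored in the medians; an
    all-missing column yields a missing column effect. The reconstruction
    identity holds exactly at every observed cell by construction.
    """
    z = np.array(matrix, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median polish needs a non-empty 2-D matrix")
    nr, nc = z.shape
    t = 0.0
    r = np.zeros(nr)
    c = np.zeros(nc)
    oldsum = 0.0
    n_iter = 0
    with np.errstate(all="ignore"):
        import warnings as _w

        for it in range(1, max_iter + 1):
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                rdelta = np.nanmedian(z, axis=1)
            rdelta = np.where(np.isnan(rdelta), 0.0, rdelta)
            z = z - rdelta[:, None]
            r = r + rdelta
            delta = np.median(c)
            c = c - delta
            t = t + delta

            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                cdelta = np.nanmedian(z, axis=0)
            cdelta = np.where(np.isnan(cdelta), 0.0, cdelta)
            z = z - cdelta[None, :]
            c = c + cdelta
            delta = np.median(r)
            r = r - delta
            t = t + delta

            n_iter = it
            newsum = float(np.nansum(np.abs(z)))
            converged = newsum == 0 or abs(newsum - oldsum) < eps * newsum
            oldsum = newsum
            if converged:
                break
    c = np.where(np.all(np.isnan(matrix), axis=0), np.nan, c)
    return MedianPolishResult(float(t), r, c, z, n_iter)


def summarize_features(
    long_table: pd.DataFrame,
    samples: Sequence[str],
    feature_col: str = "feature_id",
    peptide_col: str = "peptide",
    sample_col: str = "sample_id",
    value_col: str = "log2_intensity",
) -> pd.DataFrame:
    """Median-polish peptide-level log2 intensities to one abundance per
    feature per sample. Returns a feature x sample DataFrame (NaN where a
    sample had no observation)."""
    out = {}
    for feature, sub in long_table.groupby(feature_col, sort=True):
        mat = sub.pivot_table(
            index=peptide_col, columns=sample_col, values=value_col, aggfunc="max"
        )
        mat = mat.reindex(columns=list(samples))
        res = tukey_median_polish(mat.to_numpy())
        out[feature] = res.col_abundance
    return pd.DataFrame.from_dict(out, orient="index", columns=list(samples))


@dataclass
class QuantMatrix:
    """Feature x sample log2 abundance matrix with its design."""

    values: pd.DataFrame  # features x samples
    design: pd.DataFrame  # columns: sample_id, condition (optionally batch)

    def __post_init__(self) -> None:
        if "sample_id" not in self.design or "condition" not in self.design:
            raise ValueError("design table needs sample_id and condition columns")
        missing = set(self.values.columns) - set(self.design["sample_id"])
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")

    def condition_of(self, sample: str) -> str:
        row = self.design.loc[self.design["sample_id"] == sample, "condition"]
        return str(row.iloc[0])


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def _moderate_variances(s2: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Method-of-moments shrinkage of per-feature variances toward their
    cross-feature mean. A light-weight stand-in for empirical-Bayes
    moderation: the prior weight is chosen so the shrunken variances have
    the dispersion expected under a chi-square sampling model."""
    ok = np.isfinite(s2) & (df > 0)
    if ok.sum() < 2:
        return s2
    s0 = float(np.mean(s2[ok]))
    d = float(np.mean(df[ok]))
    var_s2 = float(np.var(s2[ok], ddof=1))
    expected_sampling_var = 2 * s0**2 / d if d > 0 else 0.0
    excess = max(var_s2 - expected_sampling_var, 0.0)
    # prior df from excess dispersion; large when features look homogeneous
    d0 = np.inf if excess == 0 else max(2 * s0**2 / excess, 1.0)
    out = s2.copy()
    if np.isinf(d0):
        out[ok] = s0
    else:
        out[ok] = (d0 * s0 + df[ok] * s2[ok]) / (d0 + df[ok])
    return out


def fit_contrasts(
    matrix: QuantMatrix,
    contrasts: Sequence[tuple[str, str, str]],
    moderate: bool = False,
    min_obs_per_group: int = 2,
) -> pd.DataFrame:
    """Per-feature fixed-effects linear model and condition contrasts.

    The model is a one-way layout abundance ~ condition per feature, the
    degenerate form of a mixed-effects model in a single-batch design.
    For each contrast (name, plus_condition, minus_condition): log2FC is
    the condition-mean difference, the standard error comes from the
    pooled residual variance across all conditions, and the two-sided p
    from a t distribution with the residual degrees of freedom. Features
    quantified in fewer than ``min_obs_per_group`` samples in either
    compared condition are flagged missing and excluded from BH, which is
    applied per contrast across features.
    """
    X = matrix.values.to_numpy(dtype=float)
    samples = list(matrix.values.columns)
    conditions = [matrix.condition_of(s) for s in samples]
    uniq = sorted(set(conditions))
    cond_masks = {c: np.array([cc == c for cc in conditions]) for c in uniq}

    obs = ~np.isnan(X)
    n_by_cond = {c: obs[:, m].sum(axis=1) for c, m in cond_masks.items()}
    mean_by_cond = {}
    ss_within = np.zeros(X.shape[0])
    groups_present = np.zeros(X.shape[0], dtype=int)
    with np.errstate(invalid="ignore"):
        for c, m in cond_masks.items():
            vals = X[:, m]
            n = n_by_cond[c]
            mu = np.where(n > 0, np.nansum(vals, axis=1) / np.maximum(n, 1), np.nan)
            mean_by_cond[c] = mu
            dev = vals - mu[:, None]
            ss_within += np.nansum(dev**2, axis=1)
            groups_present += (n > 0).astype(int)
    n_total = obs.sum(axis=1)
    df_resid = (n_total - groups_present).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df_resid > 0, ss_within / np.maximum(df_resid, 1), np.nan)
    if moderate:
        s2 = _moderate_variances(s2, df_resid)

    results = []
    features = list(matrix.values.index)
    for name, plus, minus in contrasts:
        if plus not in cond_masks or minus not in cond_masks:
            raise ValueError(f"contrast {name!r}: unknown condition")
        n_p, n_m = n_by_cond[plus], n_by_cond[minus]
        estimable = (
            (n_p >= min_obs_per_group)
            & (n_m >= min_obs_per_group)
            & (df_resid > 0)
            & np.isfinite(s2)
        )
        log2fc = mean_by_cond[plus] - mean_by_cond[minus]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(s2 * (1.0 / np.maximum(n_p, 1) + 1.0 / np.maximum(n_m, 1)))
            tval = log2fc / se
        pval = np.full(len(features), np.nan)
        ok = estimable & np.isfinite(tval)
        zero_var = estimable & (se == 0)
        pval[ok] = 2 * stats.t.sf(np.abs(tval[ok]), df_resid[ok])
        # noiseless data: a nonzero difference with zero residual variance
        pval[zero_var & (log2fc != 0)] = 0.0
        pval[zero_var & (log2fc == 0)] = 1.0
        padj = benjamini_hochberg(np.where(estimable, pval, np.nan))
        for i, feat in enumerate(features):
            results.append(
                {
                    "feature_id": feat,
                    "contrast": name,
                    "log2FC": log2fc[i] if estimable[i] else np.nan,
                    "SE": se[i] if estimable[i] else np.nan,
                    "df": df_resid[i] if estimable[i] else np.nan,
                    "t": tval[i] if estimable[i] else np.nan,
                    "p": pval[i] if estimable[i] else np.nan,
                    "p_adj": padj[i],
                    "estimable": bool(estimable[i]),
                }
            )
    return pd.DataFrame(results)
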