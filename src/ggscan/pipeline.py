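"""End-to-end orchestration: digest/classify -> ppm + FDR filtering ->
quantitative filters and summarization -> contrasts -> substrate calls ->
sequence profiles.

The stages operate on in-memory tables and are equally usable from the
command line (:mod:`ggscan.cli`) or directly from Python. Every stage
records its input/output counts in ``PipelineResult.log``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fdr as fdr_mod
from . import quant_stats as qs
from .io import decode_mods, encode_mods
from .masscalc import peptide_mass, ppm_error, precursor_mz
from .proteolysis import ProteinRecord, cleavage_sites
from .remnant_classifier import (
    PSM,
    ProteomeIndex,
    Verdict,
    classify_gg_psm,
)
from .substrate_calls import (
    call_substrates,
    metap_compatibility,
    residue_frequency_profile,
    sequence_logo_matrix,
)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (
    ("UBE2W-Control", "UBE2W", "Control"),
    ("Combo-RNF4", "Combo", "RNF4"),
)


@dataclass
class PipelineParams:
    """All printed thresholds of the workflow, as defaults."""

    mode: str = "tmt"  # or "lfq"
    peptide_fdr: float = 0.03  # pilot preset: 0.05
    ppm_low: float = -5.0
    ppm_high: float = 4.0
    lfc_min: float = 1.0
    p_max: float = 0.05
    contrasts: Sequence[tuple[str, str, str]] = DEFAULT_CONTRASTS
    required_contrasts: Sequence[str] = ("UBE2W-Control", "Combo-RNF4")
    mbr_ppm_tol: float = 10.0
    mbr_rt_tol: float = 2.0
    moderate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tmt", "lfq"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.peptide_fdr < 1:
            raise ValueError("peptide_fdr must be in (0, 1)")
        if self.ppm_low > self.ppm_high:
            raise ValueError("ppm window inverted")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")


@dataclass
class PipelineResult:
    classifications: pd.DataFrame
    retained_psms: pd.DataFrame
    quant_matrix: Optional[qs.QuantMatrix]
    contrast_results: pd.DataFrame
    calls: pd.DataFrame
    x_profile: Optional[pd.DataFrame]
    logo: Optional[object]
    metap: Optional[pd.DataFrame]
    filter_report: pd.DataFrame
    log: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.classifications.to_csv(out / "classifications.tsv", sep="\t", index=False)
        self.retained_psms.to_csv(out / "retained_psms.tsv", sep="\t", index=False)
        self.contrast_results.to_csv(out / "contrast_results.tsv", sep="\t", index=False)
        self.calls.to_csv(out / "substrate_calls.tsv", sep="\t", index=False)
        self.filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
        if self.quant_matrix is not None:
            self.quant_matrix.values.to_csv(out / "quant_matrix.tsv", sep="\t")
        if self.x_profile is not None:
            self.x_profile.to_csv(out / "x_position_profile.tsv", sep="\t", index=False)
        if self.logo is not None:
            self.logo.probabilities.assign(
                information_bits=self.logo.information_bits
            ).to_csv(out / "logo_matrix.tsv", sep="\t")
        if self.metap is not None:
            self.metap.to_csv(out / "metap_compatibility.tsv", sep="\t", index=False)
        with open(out / "pipeline_log.json", "w") as fh:
            json.dump(self.log, fh, indent=1, sort_keys=True, default=str)


def _missed_cleavages(peptide: str) -> int:
    return len(cleavage_sites(peptide))


def _theoretical_mz(row: pd.Series) -> float:
    mods = decode_mods(row["mods"]) if "mods" in row else []
    try:
        return precursor_mz(peptide_mass(row["peptide"], mods), int(row["charge"]))
    except ValueError:
        return float("nan")


def run_pipeline(
    proteome: Sequence[ProteinRecord],
    psms: pd.DataFrame,
    design: pd.DataFrame,
    params: PipelineParams,
    run_features: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Execute all stages on a PSM table against a target+decoy proteome."""
    log: dict = {"stages": []}
    report_rows = []

    def stage(name: str, n_in: int, n_out: int, **extra) -> None:
        entry = {"stage": name, "n_in": int(n_in), "n_out": int(n_out), **extra}
        log["stages"].append(entry)
        report_rows.append(entry)
        logger.info("%s: %d -> %d", name, n_in, n_out)

    df = psms.copy().reset_index(drop=True)
    if "mods" not in df.columns:
        df["mods"] = ""
    df["mods"] = df["mods"].fillna("")

    # ---- precursor mass window -------------------------------------------
    n0 = len(df)
    df["theoretical_mz"] = df.apply(_theoretical_mz, axis=1)
    df["ppm_error"] = 1e6 * (df["observed_mz"] - df["theoretical_mz"]) / df[
        "theoretical_mz"
    ]
    keep = fdr_mod.mass_tolerance_filter(
        df["ppm_error"].to_numpy(), params.ppm_low, params.ppm_high
    )
    df = df[keep & np.isfinite(df["theoretical_mz"])].reset_index(drop=True)
    stage("mass_tolerance_filter", n0, len(df))

    # ---- discriminant + peptide-level FDR --------------------------------
    n0 = len(df)
    features = pd.DataFrame(
        {
            "search_score": df["search_score"].to_numpy(dtype=float),
            "abs_ppm_error": df["ppm_error"].abs().to_numpy(dtype=float),
            "length": df["peptide"].str.len().to_numpy(dtype=float),
            "missed_cleavages": df["peptide"].map(_missed_cleavages).to_numpy(
                dtype=float
            ),
        }
    )
    is_target = ~df["decoy"].to_numpy(dtype=bool)
    try:
        scorer = fdr_mod.fit_discriminant(features, is_target)
        scores = scorer.score(features)
    except ValueError:
        logger.warning("too few decoys for LDA; using the raw search score")
        scores = df["search_score"].to_numpy(dtype=float)
    df["discriminant_score"] = scores
    peptide_keys = df["peptide"] + "//" + df["mods"]
    fdr_result = fdr_mod.compute_fdr_threshold(
        scores,
        is_target,
        target_fdr=params.peptide_fdr,
        level="peptide",
        peptide_keys=peptide_keys,
    )
    retained_decoys = df[
        df["decoy"] & (df["discriminant_score"] >= fdr_result.threshold)
    ]
    df_retained = df[fdr_result.retained].reset_index(drop=True)
    stage(
        "peptide_fdr_filter",
        n0,
        len(df_retained),
        threshold=fdr_result.threshold,
        achieved_peptide_fdr=fdr_result.achieved_fdr,
    )
    # protein-level FDR over retained peptides plus decoys above threshold
    prot_pool = pd.concat([df_retained, retained_decoys], ignore_index=True)
    try:
        protein_fdr_est = fdr_mod.protein_fdr(
            prot_pool["protein"],
            prot_pool["decoy"],
            prot_pool["discriminant_score"],
        )
    except (ValueError, KeyError):
        protein_fdr_est = float("nan")
    log["protein_fdr"] = protein_fdr_est

    # ---- classification ---------------------------------------------------
    index = ProteomeIndex(proteome)
    cls_rows = []
    for _, row in df_retained.iterrows():
        psm = PSM(
            psm_id=str(row["psm_id"]),
            peptide_sequence=row["peptide"],
            mods=decode_mods(row["mods"]),
            charge=int(row["charge"]),
            observed_mz=float(row["observed_mz"]),
            search_score=float(row["search_score"]),
            decoy=False,
        )
        c = classify_gg_psm(psm, index)
        cls_rows.append(
            {
                "psm_id": c.psm_id,
                "verdict": c.verdict.value,
                "accession": c.accession,
                "start": c.start,
                "encoded_gg": c.encoded_gg,
            }
        )
    classifications = pd.DataFrame(cls_rows)
    verdict_counts = (
        classifications["verdict"].value_counts().to_dict()
        if len(classifications)
        else {}
    )
    log["verdict_counts"] = verdict_counts

    nterm_map = {
        Verdict.NTERM_UB_INITIATOR_MET.value: "initiator_met",
        Verdict.NTERM_UB_NEO_NTERM.value: "met_clipped",
    }
    merged = df_retained.merge(classifications, on="psm_id")
    nterm = merged[merged["verdict"].isin(nterm_map)].copy()
    nterm["site_kind"] = nterm["verdict"].map(nterm_map)
    nterm["feature_id"] = nterm["accession"] + "|" + nterm["site_kind"]
    stage("nterm_selection", len(merged), len(nterm))

    # ---- quantitative filters, collapse, summarization -------------------
    samples = list(design["sample_id"])
    quant_matrix = None
    contrast_results = pd.DataFrame(
        columns=["feature_id", "contrast", "log2FC", "SE", "df", "t", "p", "p_adj",
                 "estimable"]
    )
    calls = pd.DataFrame(columns=["feature_id", "called", "high_confidence"])
    if len(nterm):
        if params.mode == "tmt":
            reporter_cols = [f"reporter_{s}" for s in samples]
            filtered, counts = qs.filter_tmt_psms(nterm, reporter_cols)
            stage("tmt_psm_filters", len(nterm), len(filtered), **counts)
            collapsed = qs.collapse_redundant(filtered, "tmt", reporter_cols)
            stage("collapse_redundant", len(filtered), len(collapsed))
            long_rows = []
            for _, row in collapsed.iterrows():
                for s in samples:
                    long_rows.append(
                        {
                            "feature_id": row["feature_id"],
                            "peptide": row["peptide"],
                            "sample_id": s,
                            "log2_intensity": float(
                                np.log2(row[f"reporter_{s}"])
                            ),
                        }
                    )
            long = pd.DataFrame(long_rows)
        else:
            filtered, counts = qs.filter_lfq_features(nterm)
            stage("lfq_psm_filters", len(nterm), len(filtered), **counts)
            collapsed = qs.collapse_redundant(filtered, "lfq")
            stage("collapse_redundant", len(filtered), len(collapsed))
            if run_features is not None and len(collapsed):
                theo = (
                    collapsed.groupby("peptide")["theoretical_mz"].first().to_dict()
                )
                completed = qs.match_between_runs(
                    collapsed.rename(columns={})[
                        ["peptide", "run_id", "peak_area", "retention_time"]
                    ],
                    run_features,
                    theo,
                    runs=samples,
                    ppm_tol=params.mbr_ppm_tol,
                    rt_tol=params.mbr_rt_tol,
                )
                n_matched = int(completed["matched"].sum())
                stage(
                    "match_between_runs",
                    len(collapsed),
                    len(completed),
                    transferred=n_matched,
                )
                feat_of = collapsed.set_index("peptide")["feature_id"].to_dict()
                completed["feature_id"] = completed["peptide"].map(feat_of)
                long = completed.assign(
                    sample_id=completed["run_id"],
                    log2_intensity=np.log2(completed["peak_area"]),
                )[["feature_id", "peptide", "sample_id", "log2_intensity"]]
            else:
                long = collapsed.assign(
                    sample_id=collapsed["run_id"],
                    log2_intensity=np.log2(collapsed["peak_area"]),
                )[["feature_id", "peptide", "sample_id", "log2_intensity"]]

        if len(long):
            values = qs.summarize_features(long, samples)
            quant_matrix = qs.QuantMatrix(values, design)
            stage("median_polish_summarization", long["feature_id"].nunique(),
                  len(values))
            contrast_results = qs.fit_contrasts(
                quant_matrix, list(params.contrasts), moderate=params.moderate
            )
            calls = call_substrates(
                contrast_results,
                params.required_contrasts,
                lfc_min=params.lfc_min,
                p_max=params.p_max,
            )
            stage("substrate_calls", len(values), int(calls["called"].sum()),
                  high_confidence=int(calls["high_confidence"].sum()))

    # ---- sequence profiles ------------------------------------------------
    x_profile = logo = metap = None
    nterm_peptides = list(dict.fromkeys(nterm["peptide"])) if len(nterm) else []
    if nterm_peptides:
        x_profile = residue_frequency_profile(nterm_peptides)
        logo = sequence_logo_matrix(nterm_peptides)
    if len(calls) and calls["called"].any():
        called = calls[calls["called"]].copy()
        parts = called["feature_id"].str.split("|", expand=True)
        called["accession"], called["site_kind"] = parts[0], parts[1]
        metap = metap_compatibility(called, proteome)

    return PipelineResult(
        classifications=classifications,
        retained_psms=df_retained,
        quant_matrix=quant_matrix,
        contrast_results=contrast_results,
        calls=calls,
        x_profile=x_profile,
        logo=logo,
        metap=metap,
        filter_report=pd.DataFrame(report_rows),
        log=log,
    )
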