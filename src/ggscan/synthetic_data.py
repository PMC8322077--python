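"""Synthetic study-shaped inputs with known ground truth.

The generator emulates the inputs of a diglycine-remnant immunoaffinity
experiment driven by inducible E2 expression: a proteome with planted
internal [K/R]GG motifs and 'X'-start unreviewed fragments, reversed
decoys, GG-modified N-terminal peptides on a designated substrate set,
canonical K-eps-GG peptides, and condition-dependent log-scale abundances
with log-normal noise under the study's four-condition replicated design
(control n=3, E2 only n=3, E3 only n=2, combo n=3 — an 11-channel
layout). All randomness flows from a single integer seed through one
numpy ``default_rng`` (PCG64) stream per public operation, so outputs are
byte-identical across platforms for a fixed seed.

Planted differential effects are drawn uniformly from a log2FC interval
(default [1, 2]) spanning the substrate-calling cutoff up to clearly
detectable, emulating the spread of effect sizes such experiments report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import encode_mods
from .masscalc import DEFAULT_REGISTRY, peptide_mass, precursor_mz
from .proteolysis import (
    METAP_SUSCEPTIBLE,
    ProteinRecord,
    build_decoy_db,
    cleavage_sites,
)

__all__ = [
    "SyntheticTruth",
    "generate_proteome",
    "generate_experiment",
    "evaluate_recovery",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_CONDITIONS = ("Control", "UBE2W", "RNF4", "Combo")
DEFAULT_REPLICATES = (3, 3, 2, 3)
DEFAULT_EFFECT_CONDITIONS = ("UBE2W", "Combo")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated data set."""

    seed: int
    substrates: dict = field(default_factory=dict)  # feature_id -> info
    null_features: list = field(default_factory=list)
    internal_motifs: dict = field(default_factory=dict)  # accession -> [positions]
    x_start_accessions: list = field(default_factory=list)
    decoy_accessions: list = field(default_factory=list)
    psm_truth: dict = field(default_factory=dict)  # psm_id -> expected verdict
    keps_psms: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_proteome(
    n_proteins: int = 500,
    length_range: tuple[int, int] = (60, 120),
    frac_internal_motif: float = 0.2,
    frac_x_start: float = 0.05,
    seed: int = 0,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Random proteome with planted internal GGX motifs and 'X'-start entries.

    Background residue frequencies are uniform over the 20 standard amino
    acids; non-fragment entries start with Met. The stated fraction of
    entries receive one internal "K/R + GG" motif at a recorded position;
    the stated fraction are 'X'-start unreviewed fragments.
    """
    if not (0 <= frac_internal_motif <= 1 and 0 <= frac_x_start <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if frac_internal_motif + frac_x_start > 1:
        raise ValueError("motif and X-start fractions exceed the proteome")
    lo, hi = length_range
    if lo < 20:
        raise ValueError("minimum protein length is 20")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    records: list[ProteinRecord] = []

    n_x = round(n_proteins * frac_x_start)
    n_motif = round(n_proteins * frac_internal_motif)
    roles = ["x_start"] * n_x + ["motif"] * n_motif
    roles += ["plain"] * (n_proteins - len(roles))
    rng.shuffle(roles)

    for i, role in enumerate(roles):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(AA20), size=length))
        if role == "x_start":
            seq[0] = "X"
            accession = f"F{i:05d}"
            source = "unreviewed"
        else:
            seq[0] = "M"
            accession = f"P{i:05d}"
            source = "reviewed"
        g = None
        if role == "motif":
            # plant K/R + GG at a recorded position; GG occupies (g, g+1)
            g = int(rng.integers(6, length - 12))
            seq[g - 2] = str(rng.choice(["K", "R"]))
            seq[g - 1] = "G"
            seq[g] = "G"
            truth.internal_motifs[accession] = [g]
        # scrub accidental [K/R]GG motifs so the planted ones are the only
        # internal GGX explanations in the proteome
        for i in range(length - 2):
            if g is not None and i == g - 2:
                continue
            if seq[i] in "KR" and seq[i + 1] == "G" and seq[i + 2] == "G":
                seq[i + 1] = "A"
        records.append(
            ProteinRecord(accession, "".join(seq), source_db=source)
        )
        if role == "x_start":
            truth.x_start_accessions.append(records[-1].accession)
    truth.params["proteome"] = {
        "n_proteins": n_proteins,
        "length_range": list(length_range),
        "frac_internal_motif": frac_internal_motif,
        "frac_x_start": frac_x_start,
    }
    return records, truth


def _nterm_peptidoforms(
    sequence: str, start: int, max_forms: int = 4
) -> list[str]:
    """Peptidoforms of the N-terminal site at ``start`` (1-based): the
    fully tryptic peptide, a missed-cleavage extension, and ragged
    (semi-tryptic) C-terminal variants, all of length >= 7."""
    sites = [s for s in cleavage_sites(sequence) if s >= start + 6]
    if not sites:
        return []
    forms = [sequence[start - 1 : sites[0]]]
    if len(sites) > 1:
        forms.append(sequence[start - 1 : sites[1]])
    for ragged in (1, 2):
        end = sites[0] - ragged
        if end - start + 1 >= 7:
            forms.append(sequence[start - 1 : end])
    return forms[:max_forms]


def _keps_peptide(sequence: str) -> Optional[tuple[str, int]]:
    """A fully tryptic peptide with one internal GG-modified lysine
    (missed cleavage at the modified residue), or None."""
    sites = [0] + cleavage_sites(sequence) + [len(sequence)]
    for a, b, c in zip(sites, sites[1:], sites[2:]):
        pep = sequence[a:c]
        if len(pep) >= 7 and sequence[b - 1] == "K":
            return pep, b - a  # 1-based K position within peptide
    return None


def generate_experiment(
    proteome: Sequence[ProteinRecord],
    truth: SyntheticTruth,
    mode: str = "tmt",
    seed: int = 0,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    replicates: Sequence[int] = DEFAULT_REPLICATES,
    effect_conditions: Sequence[str] = DEFAULT_EFFECT_CONDITIONS,
    n_substrates: int = 60,
    n_null_nterm: int = 120,
    n_internal: int = 60,
    n_keps: int = 50,
    n_decoy_psms: int = 250,
    n_xstart_psms: int = 10,
    effect_range: tuple[float, float] = (1.0, 2.0),
    sigma: float = 0.25,
    frac_met_clipped: float = 0.15,
    baseline_log2: float = 18.0,
    score_separation: float = 2.5,
    n_fractions: int = 2,
    mbr_dropout: float = 0.08,
    n_background_features: int = 300,
) -> dict:
    """Emit PSM tables, the design table, and completed ground truth.

    Returns a dict with keys ``psms`` (DataFrame), ``design`` (DataFrame),
    ``proteome`` (targets + reversed decoys), ``truth``, and for LFQ mode
    ``run_features`` (the per-run feature lists that drive cross-run
    quantification).
    """
    if mode not in ("tmt", "lfq"):
        raise ValueError(f"unknown mode {mode!r}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    rng = np.random.default_rng(seed)
    registry = DEFAULT_REGISTRY

    full_db = build_decoy_db(list(proteome))
    decoys = [r for r in full_db if r.is_decoy]
    truth.decoy_accessions = [r.accession for r in decoys]

    samples: list[str] = []
    design_rows = []
    for cond, n_rep in zip(conditions, replicates):
        for r in range(1, n_rep + 1):
            sid = f"{cond}_{r}"
            samples.append(sid)
            design_rows.append({"sample_id": sid, "condition": cond, "replicate": r})
    design = pd.DataFrame(design_rows)
    effect_mask = np.array(
        [d["condition"] in effect_conditions for d in design_rows]
    )

    # ---- choose proteins -------------------------------------------------
    motif_accs = set(truth.internal_motifs)
    xstart_accs = set(truth.x_start_accessions)
    eligible = [
        r
        for r in proteome
        if not r.is_decoy
        and r.accession not in motif_accs
        and r.accession not in xstart_accs
        and _nterm_peptidoforms(r.sequence, 1)
    ]
    if len(eligible) < n_substrates + n_null_nterm:
        raise ValueError("proteome too small for the requested feature counts")
    order = rng.permutation(len(eligible))
    chosen = [eligible[i] for i in order[: n_substrates + n_null_nterm]]
    substrate_recs = chosen[:n_substrates]
    null_recs = chosen[n_substrates:]

    psm_rows: list[dict] = []
    psm_counter = 0

    def next_id() -> str:
        nonlocal psm_counter
        psm_counter += 1
        return f"PSM{psm_counter:06d}"

    def mz_pair(pep: str, mods) -> tuple[float, float, int]:
        charge = int(rng.choice([2, 3]))
        theo = precursor_mz(peptide_mass(pep, mods), charge)
        obs = theo * (1.0 + rng.normal(0.0, 1.2) * 1e-6)
        return theo, obs, charge

    # ---- N-terminal GG features (substrates + nulls) ---------------------
    nterm_features: list[dict] = []
    for rec in substrate_recs + null_recs:
        is_substrate = rec in substrate_recs
        start, kind = 1, "initiator_met"
        if (
            is_substrate
            and len(rec.sequence) > 2
            and rec.sequence[1] in METAP_SUSCEPTIBLE
            and rng.random() < frac_met_clipped
        ):
            forms2 = _nterm_peptidoforms(rec.sequence, 2)
            if forms2:
                start, kind = 2, "met_clipped"
        forms = _nterm_peptidoforms(rec.sequence, start)
        if not forms:
            continue
        effect = float(rng.uniform(*effect_range)) if is_substrate else 0.0
        feature_id = f"{rec.accession}|{kind}"
        nterm_features.append(
            {
                "record": rec,
                "feature_id": feature_id,
                "start": start,
                "kind": kind,
                "forms": forms,
                "effect": effect,
                "substrate": is_substrate,
            }
        )
        if is_substrate:
            truth.substrates[feature_id] = {
                "accession": rec.accession,
                "site_kind": kind,
                "start": start,
                "effect": effect,
            }
        else:
            truth.null_features.append(feature_id)

    expected_nterm_verdict = {1: "NTERM_UB_INITIATOR_MET", 2: "NTERM_UB_NEO_NTERM"}

    def base_row(pep: str, mods, rec_acc: str, decoy: bool) -> dict:
        theo, obs, charge = mz_pair(pep, mods)
        return {
            "psm_id": next_id(),
            "peptide": pep,
            "mods": encode_mods(mods),
            "charge": charge,
            "observed_mz": obs,
            "search_score": float(
                rng.normal(0.0 if decoy else score_separation, 1.0)
            ),
            "protein": rec_acc,
            "decoy": decoy,
        }

    run_feature_rows: list[dict] = []
    rt_shift = {s: float(rng.uniform(-1.0, 1.0)) for s in samples}

    def emit_quant_rows(
        feature: Optional[dict],
        pep: str,
        mods,
        rec_acc: str,
        effect: float,
        verdict: Optional[str],
    ) -> None:
        """One quantified peptidoform: TMT rows per fraction, or LFQ rows
        per run with occasional identification dropout for cross-run
        matching to recover."""
        offset = float(rng.normal(0.0, 1.0))
        feature_id = feature["feature_id"] if feature else ""
        if mode == "tmt":
            for fr in range(1, n_fractions + 1):
                row = base_row(pep, mods, rec_acc, decoy=False)
                row.update(
                    {
                        "run_id": "TMT1",
                        "sample_id": "",
                        "fraction": f"F{fr}",
                        "isolation_specificity": float(rng.uniform(0.45, 1.0)),
                        "feature_hint": feature_id,
                    }
                )
                values = (
                    baseline_log2
                    + offset
                    + effect * effect_mask
                    + rng.normal(0.0, sigma, size=len(samples))
                )
                for s, v in zip(samples, values):
                    row[f"reporter_{s}"] = float(2.0**v)
                if verdict:
                    truth.psm_truth[row["psm_id"]] = verdict
                psm_rows.append(row)
        else:
            theo_charge = int(rng.choice([2, 3]))
            theo_mz = precursor_mz(peptide_mass(pep, mods), theo_charge)
            form_rt = float(rng.uniform(10.0, 100.0))
            values = (
                baseline_log2
                + offset
                + effect * effect_mask
                + rng.normal(0.0, sigma, size=len(samples))
            )
            dropout = rng.random(len(samples)) < mbr_dropout
            for j, (s, v) in enumerate(zip(samples, values)):
                area = float(2.0**v)
                rt = form_rt + rt_shift[s] + float(rng.normal(0.0, 0.05))
                run_feature_rows.append(
                    {
                        "run_id": s,
                        "mz": theo_mz * (1.0 + rng.normal(0.0, 1.0) * 1e-6),
                        "retention_time": rt,
                        "area": area,
                    }
                )
                if dropout[j]:
                    continue  # identification lost; recoverable by m/z + RT
                row = base_row(pep, mods, rec_acc, decoy=False)
                row.update(
                    {
                        "run_id": s,
                        "sample_id": s,
                        "charge": theo_charge,
                        "observed_mz": theo_mz * (1.0 + rng.normal(0.0, 1.2) * 1e-6),
                        "peak_area": area,
                        "quant_confidence": float(
                            rng.uniform(40.0, 70.0)
                            if rng.random() < 0.03
                            else rng.uniform(75.0, 100.0)
                        ),
                        "retention_time": rt,
                        "feature_hint": feature_id,
                    }
                )
                if verdict:
                    truth.psm_truth[row["psm_id"]] = verdict
                psm_rows.append(row)

    gg_nterm_mod = [registry.make("GG", "nterm")]
    for feature in nterm_features:
        verdict = expected_nterm_verdict[feature["start"]]
        for pep in feature["forms"]:
            emit_quant_rows(
                feature,
                pep,
                gg_nterm_mod,
                feature["record"].accession,
                feature["effect"],
                verdict,
            )

    # ---- internal encoded GGX peptides (abundant, condition-invariant) ---
    by_acc = {r.accession: r for r in proteome}
    internal_done = 0
    for acc, positions in truth.internal_motifs.items():
        if internal_done >= n_internal:
            break
        rec = by_acc[acc]
        g = positions[0]
        start = g + 2  # the X position: peptide begins right after the GG
        sites = [s for s in cleavage_sites(rec.sequence) if s >= start + 6]
        if not sites:
            continue
        pep = rec.sequence[start - 1 : sites[0]]
        emit_quant_rows(None, pep, gg_nterm_mod, acc, 0.0, "INTERNAL_ENCODED_GGX")
        internal_done += 1

    # ---- canonical K-eps-GG peptides -------------------------------------
    keps_done = 0
    for rec in proteome:
        if keps_done >= n_keps or rec.is_decoy or rec.starts_with_X:
            continue
        found = _keps_peptide(rec.sequence)
        if found is None:
            continue
        pep, kpos = found
        mods = [registry.make("GG_K", kpos)]
        row_ids_before = psm_counter
        emit_quant_rows(None, pep, mods, rec.accession, 0.0, "K_EPS_GG")
        truth.keps_psms.extend(
            f"PSM{i:06d}" for i in range(row_ids_before + 1, psm_counter + 1)
        )
        keps_done += 1

    # ---- 'X'-start fragments observed as N-terminal GG PSMs --------------
    xstart_done = 0
    for acc in truth.x_start_accessions:
        if xstart_done >= n_xstart_psms:
            break
        rec = by_acc[acc]
        forms = _nterm_peptidoforms(rec.sequence, 2)  # skip the leading X
        if not forms:
            continue
        emit_quant_rows(None, forms[0], gg_nterm_mod, acc, 0.0, "REJECT_X_START")
        xstart_done += 1

    # ---- decoy PSMs (score calibration only) -----------------------------
    decoy_done = 0
    while decoy_done < n_decoy_psms:
        rec = decoys[int(rng.integers(len(decoys)))]
        sites = cleavage_sites(rec.sequence)
        if not sites:
            continue
        end = sites[int(rng.integers(len(sites)))]
        length = int(rng.integers(8, 17))
        start = max(1, end - length + 1)
        pep = rec.sequence[start - 1 : end]
        if "X" in pep or len(pep) < 7:
            continue
        row = base_row(pep, [], rec.accession, decoy=True)
        if mode == "tmt":
            row.update(
                {
                    "run_id": "TMT1",
                    "sample_id": "",
                    "fraction": "F1",
                    "isolation_specificity": float(rng.uniform(0.45, 1.0)),
                    "feature_hint": "",
                }
            )
            for s in samples:
                row[f"reporter_{s}"] = float(2.0 ** rng.normal(12.0, 1.0))
        else:
            s = samples[int(rng.integers(len(samples)))]
            row.update(
                {
                    "run_id": s,
                    "sample_id": s,
                    "peak_area": float(2.0 ** rng.normal(12.0, 1.0)),
                    "quant_confidence": float(rng.uniform(40.0, 100.0)),
                    "retention_time": float(rng.uniform(10.0, 100.0)),
                    "feature_hint": "",
                }
            )
        psm_rows.append(row)
        decoy_done += 1

    psms = pd.DataFrame(psm_rows)
    truth.params["experiment"] = {
        "mode": mode,
        "seed": seed,
        "conditions": list(conditions),
        "replicates": list(replicates),
        "effect_conditions": list(effect_conditions),
        "n_substrates": n_substrates,
        "n_null_nterm": n_null_nterm,
        "effect_range": list(effect_range),
        "sigma": sigma,
        "score_separation": score_separation,
    }

    out = {"psms": psms, "design": design, "proteome": full_db, "truth": truth}
    if mode == "lfq":
        # pad each run with unrelated background features
        for _ in range(n_background_features):
            s = samples[int(rng.integers(len(samples)))]
            run_feature_rows.append(
                {
                    "run_id": s,
                    "mz": float(rng.uniform(300.0, 1500.0)),
                    "retention_time": float(rng.uniform(5.0, 110.0)),
                    "area": float(2.0 ** rng.normal(14.0, 2.0)),
                }
            )
        out["run_features"] = pd.DataFrame(run_feature_rows)
    return out


def evaluate_recovery(
    calls: pd.DataFrame,
    truth: SyntheticTruth,
    rmse_contrast: str = "UBE2W-Control",
) -> dict:
    """Confusion metrics of substrate calls against generator truth.

    Sensitivity counts planted substrates with a passing call; the
    false-call fraction counts planted null features called; the RMSE
    compares estimated against planted log2 fold changes over called
    substrates in ``rmse_contrast``.
    """
    substrates = set(truth.substrates)
    nulls = set(truth.null_features)
    if not substrates:
        raise ValueError("truth contains no substrates")
    call_features = set(calls["feature_id"])
    if not (call_features & (substrates | nulls)) and len(call_features):
        raise ValueError("calls and truth share no feature identifiers")
    called = set(calls.loc[calls["called"], "feature_id"])
    tp = called & substrates
    sensitivity = len(tp) / len(substrates)
    false_calls = called & nulls
    false_call_fraction = len(false_calls) / len(nulls) if nulls else 0.0
    lfc_col = f"log2FC_{rmse_contrast}"
    rmse = float("nan")
    if lfc_col in calls.columns and tp:
        sub = calls.set_index("feature_id").loc[sorted(tp)]
        est = sub[lfc_col].to_numpy(dtype=float)
        planted = np.array([truth.substrates[f]["effect"] for f in sorted(tp)])
        ok = np.isfinite(est)
        if ok.sum():
            rmse = float(np.sqrt(np.mean((est[ok] - planted[ok]) ** 2)))
    return {
        "n_substrates": len(substrates),
        "n_nulls": len(nulls),
        "n_called": len(called),
        "true_positives": len(tp),
        "false_calls": len(false_calls),
        "sensitivity": sensitivity,
        "false_call_fraction": false_call_fraction,
        "log2fc_rmse": rmse,
    }
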