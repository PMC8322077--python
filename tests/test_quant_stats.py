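"""Quantitative filters, collapse, cross-run matching, median polish,
and contrast statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ggscan.quant_stats import (
    QuantMatrix,
    benjamini_hochberg,
    collapse_redundant,
    filter_lfq_features,
    filter_tmt_psms,
    fit_contrasts,
    match_between_runs,
    summarize_features,
    tukey_median_polish,
)

REP = [f"reporter_S{i}" for i in range(1, 12)]


def tmt_row(peptide="PEPTIDEK", decoy=False, iso=0.9, reporter=5000.0, **over):
    row = {
        "peptide": peptide,
        "decoy": decoy,
        "isolation_specificity": iso,
        "fraction": "F1",
    }
    for c in REP:
        row[c] = reporter
    row.update(over)
    return row


# ---------------------------------------------------------------- TMT filters


def test_tmt_filters_apply_printed_boundaries():
    rows = [
        tmt_row(),  # clean
        tmt_row(decoy=True),  # rule 1
        tmt_row(peptide="SHORTK"),  # rule 2: length 6 < 7
        tmt_row(peptide="LONGENOUGHK"),  # length 11: kept
        tmt_row(iso=0.499),  # rule 3
        tmt_row(iso=0.50),  # exactly 50%: kept (strict <)
        tmt_row(**{REP[0]: 255.9}),  # rule 4: one channel below 256
        tmt_row(**{REP[0]: 256.0}),  # boundary channel kept
        tmt_row(reporter=29999.0 / 11),  # rule 5: summed 29,999
        tmt_row(reporter=30000.0 / 11),  # summed exactly 30,000: kept
    ]
    df = pd.DataFrame(rows)
    kept, counts = filter_tmt_psms(df, REP)
    assert counts == {
        "decoy": 1,
        "short_peptide": 1,
        "isolation_specificity": 1,
        "low_reporter": 1,
        "low_summed_reporter": 1,
    }
    assert len(kept) == 5


def test_tmt_filter_missing_column_names_field():
    df = pd.DataFrame([{"peptide": "PEPTIDEK", "decoy": False}])
    with pytest.raises(ValueError, match="isolation_specificity"):
        filter_tmt_psms(df, REP)


# ---------------------------------------------------------------- LFQ filters


def lfq_row(peptide="PEPTIDEK", decoy=False, conf=90.0, area=5000.0):
    return {
        "peptide": peptide,
        "decoy": decoy,
        "quant_confidence": conf,
        "peak_area": area,
    }


def test_lfq_filters_apply_printed_boundaries():
    rows = [
        lfq_row(),
        lfq_row(decoy=True, conf=10.0, area=1.0),  # decoy removed first
        lfq_row(peptide="SHORTK"),
        lfq_row(conf=70.0),  # removed: < 71
        lfq_row(conf=71.0),  # kept
        lfq_row(area=255.0),  # removed: < 256
        lfq_row(area=256.0),  # kept
    ]
    kept, counts = filter_lfq_features(pd.DataFrame(rows))
    assert counts == {
        "decoy": 1,
        "short_peptide": 1,
        "low_confidence": 1,
        "low_peak_area": 1,
    }
    assert len(kept) == 3


# ---------------------------------------------------------------- collapse


def test_collapse_single_psm_is_identity():
    df = pd.DataFrame([tmt_row()])
    out = collapse_redundant(df, "tmt", REP)
    assert len(out) == 1
    assert out.iloc[0][REP[0]] == 5000.0


def test_collapse_keeps_highest_summed_fraction():
    df = pd.DataFrame(
        [
            tmt_row(fraction="F1", reporter=1e6 / 11),
            tmt_row(fraction="F2", reporter=2e6 / 11),
        ]
    )
    out = collapse_redundant(df, "tmt", REP)
    assert len(out) == 1
    assert out.iloc[0]["fraction"] == "F2"


def test_collapse_takes_channel_max_within_fraction():
    r1 = tmt_row(**{REP[0]: 100.0, REP[1]: 900.0})
    r2 = tmt_row(**{REP[0]: 800.0, REP[1]: 200.0})
    out = collapse_redundant(pd.DataFrame([r1, r2]), "tmt", REP)
    assert out.iloc[0][REP[0]] == 800.0
    assert out.iloc[0][REP[1]] == 900.0


def test_lfq_collapse_matches_groupby_oracle(rng):
    n = 200
    df = pd.DataFrame(
        {
            "peptide": rng.choice(["A", "B", "C", "D"], size=n),
            "run_id": rng.choice(["r1", "r2", "r3"], size=n),
            "peak_area": rng.uniform(100, 10000, size=n),
        }
    )
    out = collapse_redundant(df, "lfq")
    oracle = df.groupby(["peptide", "run_id"])["peak_area"].max()
    assert len(out) == len(oracle)
    for _, row in out.iterrows():
        assert row["peak_area"] == oracle[(row["peptide"], row["run_id"])]


# ---------------------------------------------------------------- MBR


def anchors(runs, rt=50.0, area=1000.0):
    return pd.DataFrame(
        [
            {"peptide": "PEPTIDEK", "run_id": r, "peak_area": area,
             "retention_time": rt}
            for r in runs
        ]
    )


def test_identical_runs_stay_complete():
    runs = ["r1", "r2"]
    out = match_between_runs(
        anchors(runs), pd.DataFrame(columns=["run_id", "mz", "retention_time",
                                             "area"]),
        {"PEPTIDEK": 450.0}, runs,
    )
    assert len(out) == 2
    assert not out["matched"].any()


def test_constant_rt_shift_is_recovered():
    runs = ["r1", "r2", "r3"]
    # peptide quantified in r1/r2 at rt 50; r3 runs 5 minutes late
    q = pd.concat(
        [
            anchors(["r1", "r2"]),
            pd.DataFrame(
                [
                    {"peptide": "OTHERPEPK", "run_id": r,
                     "peak_area": 500.0, "retention_time": rt}
                    for r, rt in [("r1", 30.0), ("r2", 30.0), ("r3", 35.0)]
                ]
            ),
        ],
        ignore_index=True,
    )
    feats = pd.DataFrame(
        [{"run_id": "r3", "mz": 450.0, "retention_time": 55.0, "area": 777.0}]
    )
    out = match_between_runs(q, feats, {"PEPTIDEK": 450.0, "OTHERPEPK": 460.0},
                             runs)
    got = out[(out["peptide"] == "PEPTIDEK") & (out["run_id"] == "r3")]
    assert len(got) == 1
    assert got.iloc[0]["peak_area"] == 777.0
    assert got.iloc[0]["matched"]


def test_feature_outside_ppm_window_not_transferred():
    runs = ["r1", "r2"]
    feats = pd.DataFrame(
        [
            {"run_id": "r2", "mz": 450.0 * (1 + 12e-6),
             "retention_time": 50.0, "area": 999.0}
        ]
    )
    out = match_between_runs(anchors(["r1"]), feats, {"PEPTIDEK": 450.0}, runs)
    assert not ((out["peptide"] == "PEPTIDEK") & (out["run_id"] == "r2")).any()


# ---------------------------------------------------------------- median polish


def test_additive_matrix_has_zero_residuals():
    row = np.array([0.0, 1.0, 2.0])
    col = np.array([10.0, 20.0, 30.0, 40.0])
    m = row[:, None] + col[None, :]
    res = tukey_median_polish(m, eps=1e-12, max_iter=50)
    assert np.allclose(res.residuals, 0.0, atol=1e-9)
    recon = res.overall + res.row_effects[:, None] + res.col_effects[None, :]
    assert np.allclose(recon, m, atol=1e-9)


def test_constant_matrix():
    res = tukey_median_polish(np.full((3, 4), 7.5))
    assert res.overall == pytest.approx(7.5)
    assert np.allclose(res.row_effects, 0.0)
    assert np.allclose(res.col_effects, 0.0)


# Expected decompositions computed with R's stats::medpolish
# (eps=1e-12, maxiter=100).
R_CASES = [
    (
        [[13, 17, 26, 62], [23, 38, 41, 61], [15, 30, 12, 81]],
        31.0,
        [-6.0, 8.0, 0.0],
        [-16.0, -1.0, 1.0, 37.0],
    ),
    (
        [[1.2, 2.4, 3.1], [0.7, 5.5, 1.9], [2.2, 4.4, 3.3]],
        2.4,
        [0.0, -0.5, 0.9],
        [-1.2, 1.1, 0.0],
    ),
]


@pytest.mark.parametrize("matrix,overall,row,col", R_CASES)
def test_median_polish_matches_r_oracle(matrix, overall, row, col):
    res = tukey_median_polish(np.array(matrix, float), eps=1e-12, max_iter=100)
    assert res.overall == pytest.approx(overall, abs=1e-9)
    assert np.allclose(res.row_effects, row, atol=1e-9)
    assert np.allclose(res.col_effects, col, atol=1e-9)


def independent_median_polish(matrix, eps=0.01, max_iter=10):
    """Plain-Python re-implementation used as an in-test oracle."""
    import statistics

    z = [list(r) for r in matrix]
    nr, nc = len(z), len(z[0])
    t, r, c = 0.0, [0.0] * nr, [0.0] * nc
    oldsum = 0.0

    def med(vals):
        vals = [v for v in vals if v == v]  # drop NaN
        return statistics.median(vals) if vals else 0.0

    for _ in range(max_iter):
        for i in range(nr):
            d = med(z[i])
            for j in range(nc):
                z[i][j] -= d
            r[i] += d
        d = statistics.median(c)
        c = [x - d for x in c]
        t += d
        for j in range(nc):
            d = med([z[i][j] for i in range(nr)])
            for i in range(nr):
                z[i][j] -= d
            c[j] += d
        d = statistics.median(r)
        r = [x - d for x in r]
        t += d
        newsum = sum(abs(v) for row in z for v in row if v == v)
        if newsum == 0 or abs(newsum - oldsum) < eps * newsum:
            break
        oldsum = newsum
    return t, r, c, z


def test_median_polish_matches_independent_oracle(rng):
    for _ in range(20):
        nr = int(rng.integers(3, 11))
        nc = int(rng.integers(3, 9))
        m = rng.normal(10.0, 2.0, size=(nr, nc))
        res = tukey_median_polish(m)
        t, r, c, z = independent_median_polish(m.tolist())
        assert res.overall == pytest.approx(t, abs=1e-9)
        assert np.allclose(res.row_effects, r, atol=1e-9)
        assert np.allclose(res.col_effects, c, atol=1e-9)
        assert np.allclose(res.residuals, np.array(z), atol=1e-9)


def test_reconstruction_identity_with_missing_cells(rng):
    m = rng.normal(size=(6, 5))
    m[rng.random(m.shape) < 0.2] = np.nan
    res = tukey_median_polish(m)
    recon = res.overall + res.row_effects[:, None] + res.col_effects[None, :] \
        + res.residuals
    obs = ~np.isnan(m)
    assert np.allclose(recon[obs], m[obs], atol=1e-9)


def test_row_permutation_leaves_sample_abundance_unchanged(rng):
    m = rng.normal(size=(5, 4))
    res1 = tukey_median_polish(m)
    res2 = tukey_median_polish(m[::-1])
    assert np.allclose(res1.col_abundance, res2.col_abundance, atol=1e-9)


def test_all_missing_column_yields_missing_abundance():
    m = np.array([[1.0, np.nan], [2.0, np.nan]])
    res = tukey_median_polish(m)
    assert np.isnan(res.col_abundance[1])
    assert np.isfinite(res.col_abundance[0])


# ---------------------------------------------------------------- contrasts


def design_for(conditions):
    return pd.DataFrame(
        [{"sample_id": s, "condition": c} for s, c in conditions.items()]
    )


def test_noiseless_planted_effect_recovered_exactly():
    samples = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
    values = pd.DataFrame(
        {s: [5.0 + (2.0 if c == "B" else 0.0)] for s, c in samples.items()},
        index=["feat1"],
    )
    qm = QuantMatrix(values, design_for(samples))
    res = fit_contrasts(qm, [("B-A", "B", "A")])
    assert res.iloc[0]["log2FC"] == pytest.approx(2.0, abs=1e-12)
    assert res.iloc[0]["p"] == 0.0


def test_balanced_contrast_equals_pooled_t_test(rng):
    samples = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
    X = rng.normal(size=(50, 8))
    values = pd.DataFrame(X, index=[f"f{i}" for i in range(50)],
                          columns=list(samples))
    qm = QuantMatrix(values, design_for(samples))
    res = fit_contrasts(qm, [("B-A", "B", "A")])
    a = X[:, :4]
    b = X[:, 4:]
    t_ref, p_ref = sps.ttest_ind(b, a, axis=1, equal_var=True)
    assert np.allclose(res["t"].to_numpy(), t_ref, atol=1e-9)
    assert np.allclose(res["p"].to_numpy(), p_ref, atol=1e-9)
    assert np.allclose(res["log2FC"].to_numpy(), b.mean(1) - a.mean(1), atol=1e-9)


def test_underpopulated_condition_flagged_not_tested():
    samples = {"a1": "A", "a2": "A", "b1": "B"}
    values = pd.DataFrame({"a1": [1.0], "a2": [1.5], "b1": [9.0]}, index=["f"])
    qm = QuantMatrix(values, design_for(samples))
    res = fit_contrasts(qm, [("B-A", "B", "A")])
    assert not res.iloc[0]["estimable"]
    assert np.isnan(res.iloc[0]["p_adj"])


def test_unknown_condition_raises():
    samples = {"a1": "A", "a2": "A"}
    values = pd.DataFrame({"a1": [1.0], "a2": [1.5]}, index=["f"])
    qm = QuantMatrix(values, design_for(samples))
    with pytest.raises(ValueError, match="unknown condition"):
        fit_contrasts(qm, [("C-A", "C", "A")])


def brute_force_bh(p):
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        val = min(prev, p[idx] * n / rank)
        adj[idx] = val
        prev = val
    return adj


def test_bh_matches_step_up_oracle(rng):
    for _ in range(10):
        p = rng.uniform(size=int(rng.integers(1, 60)))
        assert np.allclose(benjamini_hochberg(p), brute_force_bh(p), atol=1e-12)


def test_moderation_shrinks_variance_spread(rng):
    samples = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}
    X = rng.normal(size=(200, 6)) * rng.uniform(0.1, 3.0, size=(200, 1))
    values = pd.DataFrame(X, index=[f"f{i}" for i in range(200)],
                          columns=list(samples))
    qm = QuantMatrix(values, design_for(samples))
    plain = fit_contrasts(qm, [("B-A", "B", "A")], moderate=False)
    mod = fit_contrasts(qm, [("B-A", "B", "A")], moderate=True)
    assert mod["SE"].var() < plain["SE"].var()


def test_effect_recovery_rmse_under_default_noise(rng):
    """Planted log2FC of 1 and 2 with 3 replicates and sigma 0.25 noise per
    peptidoform observation: median-polish summarization plus the linear
    model keeps the estimation RMSE within 0.15 over 300 features."""
    samples = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}
    design = design_for(samples)
    n_feat, n_pep = 300, 4
    effects = np.where(np.arange(n_feat) % 2 == 0, 1.0, 2.0)
    rows = []
    for f in range(n_feat):
        base = rng.normal(18.0, 1.0)
        for p in range(n_pep):
            for s, c in samples.items():
                rows.append(
                    {
                        "feature_id": f"feat{f:04d}",
                        "peptide": f"PEP{f}_{p}",
                        "sample_id": s,
                        "log2_intensity": base
                        + (effects[f] if c == "B" else 0.0)
                        + rng.normal(0.0, 0.25),
                    }
                )
    long = pd.DataFrame(rows)
    values = summarize_features(long, list(samples))
    qm = QuantMatrix(values, design)
    res = fit_contrasts(qm, [("B-A", "B", "A")]).set_index("feature_id")
    est = np.array([res.loc[f"feat{f:04d}", "log2FC"] for f in range(n_feat)])
    rmse = float(np.sqrt(np.mean((est - effects) ** 2)))
    assert rmse <= 0.15
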