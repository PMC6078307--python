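"""Partial Spearman screen: arithmetic oracles, rank invariances,
FDR worked examples, and the cross-block record assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gutbrainnet import (CrossBlockSpearman, VariableBlock,
                        assemble_results_table, bh_fdr, block_correlations,
                        partial_spearman)


def oracle_partial_spearman(x, y, Z):
    """Independent arithmetic oracle: rank -> OLS residual -> Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    D = np.column_stack([np.ones(len(x))] +
                        [stats.rankdata(Z[:, j]) for j in range(Z.shape[1])])
    H = D @ np.linalg.pinv(D)
    ex = rx - H @ rx
    ey = ry - H @ ry
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


def test_perfect_monotone_with_inert_covariate():
    x = [1, 2, 3, 4, 5]
    y = [10, 20, 30, 40, 50]
    res = partial_spearman(x, y, np.ones((5, 1)))
    assert res.r == pytest.approx(1.0)
    x = [1, 2, 3, 4]
    y = [8, 6, 4, 2]
    res = partial_spearman(x, y, np.ones((4, 1)))
    assert res.r == pytest.approx(-1.0)


def test_matches_independent_oracle_with_confounder(rng):
    z = rng.standard_normal(12)
    y = z + 0.3 * rng.standard_normal(12)
    x = z + 0.3 * rng.standard_normal(12)
    res = partial_spearman(x, y, z[:, None])
    assert res.r == pytest.approx(oracle_partial_spearman(x, y, z[:, None]),
                                  abs=1e-10)
    assert res.n == 12 and res.df == 12 - 2 - 1


def test_oracle_agreement_random_two_covariates(rng):
    for _ in range(30):
        n = int(rng.integers(10, 40))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        Z = rng.standard_normal((n, 2))
        res = partial_spearman(x, y, Z)
        assert res.r == pytest.approx(oracle_partial_spearman(x, y, Z),
                                      abs=1e-10)


def test_constant_covariates_reduce_to_plain_spearman(rng):
    x = rng.standard_normal(30)
    y = rng.standard_normal(30)
    res = partial_spearman(x, y, np.full((30, 2), 7.0))
    rho = stats.spearmanr(x, y).statistic
    assert res.r == pytest.approx(rho, abs=1e-12)


def test_cross_check_against_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    for _ in range(10):
        df = pd.DataFrame(rng.standard_normal((35, 4)),
                          columns=["x", "y", "a", "b"])
        res = partial_spearman(df["x"], df["y"], df[["a", "b"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"],
                                    method="spearman")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


@given(st.integers(0, 2 ** 32 - 1))
def test_monotone_transform_invariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(25)
    y = rng.standard_normal(25)
    Z = rng.standard_normal((25, 2))
    base = partial_spearman(x, y, Z).r
    assert partial_spearman(np.exp(x), y ** 3 + 2 * y, Z).r == \
        pytest.approx(base, abs=1e-10)


def test_missing_values_use_pairwise_complete(rng):
    x = rng.standard_normal(30)
    y = rng.standard_normal(30)
    Z = rng.standard_normal((30, 2))
    x_miss = x.copy()
    x_miss[25:] = np.nan
    res = partial_spearman(x_miss, y, Z)
    ref = partial_spearman(x[:25], y[:25], Z[:25])
    assert res.n == 25
    assert res.r == pytest.approx(ref.r, abs=1e-12)


def test_too_few_cases_and_zero_variance(rng):
    with pytest.raises(ValueError, match="complete cases"):
        partial_spearman([1, 2, 3], [1, 2, 3], np.ones((3, 1)))
    res = partial_spearman(np.ones(10), rng.standard_normal(10),
                           rng.standard_normal((10, 1)))
    assert np.isnan(res.r)


# -- BH-FDR -----------------------------------------------------------

def test_bh_worked_examples():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    q = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
    assert q == pytest.approx([0.05] * 5)
    q = bh_fdr([0.005, 0.03, 0.5])
    assert q == pytest.approx([0.015, 0.045, 0.5])


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_fdr([])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=40))
def test_bh_properties(ps):
    p = np.asarray(ps)
    q = bh_fdr(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p


# -- cross-block assembly --------------------------------------------

def _blocks(rng, n=63, n_brain=48, yfas_missing=21, anat_missing=1):
    ids = [f"sub-{i:03d}" for i in range(n)]
    met = pd.DataFrame(rng.lognormal(size=(n, 3)),
                       columns=["indole", "skatole", "iaa"], index=ids)
    clin = pd.DataFrame(rng.standard_normal((n, 3)),
                        columns=["bmi", "yfas", "had_anxiety"], index=ids)
    clin.iloc[n - yfas_missing:, 1] = np.nan
    brain_cols = ([f"func:v{i}" for i in range(n_brain // 2)] +
                  [f"anat:v{i}" for i in range(n_brain // 2)])
    brain = pd.DataFrame(rng.standard_normal((n, n_brain)),
                         columns=brain_cols, index=ids)
    if anat_missing:
        brain.iloc[n - anat_missing:, n_brain // 2:] = np.nan
    cov = pd.DataFrame({"age": rng.uniform(18, 60, n),
                        "sex": rng.integers(0, 2, n)}, index=ids)
    return [VariableBlock("metabolite", met), VariableBlock("clinical", clin),
            VariableBlock("brain", brain)], cov


def test_record_count_and_sample_sizes(rng):
    blocks, cov = _blocks(rng)
    rec = block_correlations(blocks, cov)
    assert len(rec) == 3 * 48 + 3 * 3 + 3 * 48  # no within-block pairs
    met_func = rec[(rec.block_a == "metabolite") &
                   (rec.modality == "functional")]
    assert (met_func.n == 63).all()
    met_anat = rec[(rec.block_a == "metabolite") &
                   (rec.modality == "anatomical")]
    assert (met_anat.n == 62).all()
    yfas = rec[(rec.variable_a == "yfas") | (rec.variable_b == "yfas")]
    assert yfas.n.max() == 42
    # both df conventions carried
    row = met_func.iloc[0]
    assert row.df_test == 63 - 2 - 2 and row.df_printed == 62


def test_family_keys(rng):
    blocks, cov = _blocks(rng, n=30, n_brain=8, yfas_missing=5)
    rec = block_correlations(blocks, cov, family_key="pooled")
    assert set(rec.family) == {"all"}
    rec = block_correlations(blocks, cov, family_key="block_pair")
    assert len(set(rec.family)) == 3
    rec = block_correlations(blocks, cov, family_key="block_pair_modality")
    assert len(set(rec.family)) == 5
    with pytest.raises(ValueError, match="family_key"):
        block_correlations(blocks, cov, family_key="bonferroni")


def test_records_match_standalone_partial_spearman(rng):
    blocks, cov = _blocks(rng, n=40, n_brain=6, yfas_missing=8)
    rec = block_correlations(blocks, cov)
    row = rec[(rec.variable_a == "yfas") &
              (rec.variable_b == "func:v1")].iloc[0]
    ref = partial_spearman(blocks[1].data["yfas"],
                           blocks[2].data["func:v1"], cov.to_numpy())
    assert row.r == pytest.approx(ref.r, abs=1e-12)
    assert row.p == pytest.approx(ref.p, abs=1e-12)
    assert row.n == ref.n


def test_all_missing_yfas_flagged_not_fatal(rng):
    blocks, cov = _blocks(rng, n=20, n_brain=4, yfas_missing=20,
                          anat_missing=0)
    rec = block_correlations(blocks, cov)
    yfas = rec[(rec.variable_a == "yfas") | (rec.variable_b == "yfas")]
    assert yfas.excluded.all()
    assert rec[~rec.excluded].q.notna().all()


def test_q_within_family_monotone_and_bounded(rng):
    blocks, cov = _blocks(rng, n=40, n_brain=10, yfas_missing=5)
    rec = block_correlations(blocks, cov)
    ok = rec[~rec.excluded]
    assert ((ok.q >= ok.p - 1e-12) & (ok.q <= 1 + 1e-12)).all()
    for _, grp in ok.groupby("family"):
        g = grp.sort_values("p")
        assert (np.diff(g.q) >= -1e-12).all()


def test_misaligned_blocks_rejected(rng):
    blocks, cov = _blocks(rng, n=10, n_brain=4, yfas_missing=2)
    blocks[1].data = blocks[1].data.iloc[:-1]
    with pytest.raises(ValueError, match="aligned"):
        block_correlations(blocks, cov)


def test_results_table_sorting_and_roundtrip(rng, tmp_path):
    blocks, cov = _blocks(rng, n=30, n_brain=6, yfas_missing=5)
    rec = block_correlations(blocks, cov)
    table = assemble_results_table(rec)
    assert {"Indole", "Skatole", "IAA"} <= set(table.variable_a)
    for _, grp in table.groupby("family"):
        assert (grp.q.fillna(np.inf).diff().dropna() >= -1e-12).all()
    path = tmp_path / "results.tsv"
    table.to_csv(path, sep="\t", index=False)
    back = pd.read_csv(path, sep="\t")
    assert np.allclose(back["r"].to_numpy(dtype=float),
                       table["r"].to_numpy(dtype=float), equal_nan=True)
    empty = assemble_results_table(rec.iloc[0:0])
    assert len(empty) == 0 and "sig_q05" in empty.columns


def test_estimator_interface(rng):
    blocks, cov = _blocks(rng, n=25, n_brain=4, yfas_missing=4)
    est = CrossBlockSpearman(family_key="pooled")
    assert est.get_params() == {"family_key": "pooled"}
    est.fit(blocks, cov)
    assert len(est.records_) == 3 * 4 + 9 + 3 * 4
    assert "sig_q05" in est.results_table_.columns


def test_planted_correlation_recovered_in_screen(rng):
    """A planted metabolite-brain correlation of 0.6 lands near 0.6."""
    from gutbrainnet import CohortSpec, generate_metric_block, \
        generate_subjects
    spec = CohortSpec(seed=17, effect_map=(("indole", "func:S_R_NAcc", 0.6),))
    subj = generate_subjects(spec).set_index("subject_id")
    brain = generate_metric_block(generate_subjects(spec), spec) \
        .set_index("subject_id")
    blocks = [VariableBlock("metabolite", subj[["indole", "skatole", "iaa"]]),
              VariableBlock("clinical", subj[["bmi", "yfas", "had_anxiety"]]),
              VariableBlock("brain", brain)]
    rec = block_correlations(blocks, subj[["age", "sex"]])
    row = rec[(rec.variable_a == "indole") &
              (rec.variable_b == "func:S_R_NAcc")].iloc[0]
    assert row.r == pytest.approx(0.6, abs=0.2)  # single replicate
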