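import shutil
import subprocess
import textwrap
import warnings

import numpy as np
import pytest

from mirscreen.plates import (
    PlateGrid,
    b_score,
    median_polish,
    replicate_agreement,
    select_mts_timepoint,
    welch_t_test,
    z_score_vs_controls,
)
from mirscreen.simulate import PlateSimParams, simulate_plate


def additive(n_rows=4, n_cols=6, overall=10.0):
    rows = np.arange(float(n_rows))
    cols = np.arange(float(n_cols))
    return overall + rows[:, None] + cols[None, :]


# ---------------------------------------------------------------------------
# median polish


def test_additive_matrix_polishes_to_zero_residuals():
    vals = additive()
    fit = median_polish(vals)
    assert np.abs(fit.residuals).max() <= 1e-9
    np.testing.assert_allclose(vals, fit.fitted() + fit.residuals, atol=1e-9)
    assert fit.converged


def test_single_outlier_lands_in_its_own_residual():
    vals = additive()
    vals[1, 2] += 100.0
    fit = median_polish(vals)
    resid = fit.residuals.copy()
    assert resid[1, 2] == pytest.approx(100.0, abs=1e-6)
    resid[1, 2] = 0.0
    assert np.abs(resid).max() <= 1e-6


def test_constant_matrix_decomposes_trivially():
    fit = median_polish(np.full((5, 5), 7.0))
    assert fit.overall == pytest.approx(7.0, abs=1e-12)
    assert np.abs(fit.row_effects).max() <= 1e-12
    assert np.abs(fit.col_effects).max() <= 1e-12
    assert np.abs(fit.residuals).max() <= 1e-12


def test_decomposition_identity_on_noisy_masked_plates():
    rng = np.random.default_rng(0)
    for _ in range(5):
        vals = additive(8, 12) + rng.normal(0, 2, (8, 12))
        mask = rng.random((8, 12)) > 0.1
        # keep >= 2 unmasked wells per row/column
        mask[:, :2] = True
        mask[:2, :] = True
        plate = PlateGrid(values=vals, mask=mask)
        fit = median_polish(plate)
        recon = fit.fitted() + np.where(mask, fit.residuals, 0.0)
        np.testing.assert_allclose(vals[mask], recon[mask], atol=1e-9)


def test_fully_masked_row_is_named_in_error():
    mask = np.ones((4, 6), dtype=bool)
    mask[2, :] = False
    with pytest.raises(ValueError, match="row C"):
        median_polish(PlateGrid(values=additive(), mask=mask))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_residuals_agree_with_reference_median_polish(tmp_path):
    """Cross-check against stats::medpolish on an outlier fixture; the two
    converge to the same decomposition up to centring convention."""
    rng = np.random.default_rng(4)
    vals = additive(8, 12) + rng.normal(0, 1, (8, 12))
    vals[2, 5] += 100
    np.savetxt(tmp_path / "plate.csv", vals, delimiter=",")
    fit = median_polish(vals)
    np.savetxt(tmp_path / "py.csv", fit.residuals, delimiter=",")
    script = textwrap.dedent(
        f"""
        x <- as.matrix(read.csv("{tmp_path}/plate.csv", header=FALSE))
        p <- as.matrix(read.csv("{tmp_path}/py.csv", header=FALSE))
        f <- medpolish(x, eps=1e-9, maxiter=200, trace.iter=FALSE)
        cat(max(abs(f$residuals - p)))
        """
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    assert float(out.stdout.strip().split()[-1]) < 0.1


# ---------------------------------------------------------------------------
# B-scores


def test_pure_noise_bscores_are_roughly_standard():
    frac_ok = []
    for seed in range(100):
        plate = simulate_plate(PlateSimParams(noise_sd=1.0), seed=seed)
        g = b_score(plate)
        frac_ok.append(np.mean(np.abs(g.b) < 3))
    assert np.mean(frac_ok) >= 0.95


def test_additive_only_plate_is_degenerate():
    with pytest.warns(UserWarning, match="degenerate"):
        g = b_score(PlateGrid(values=additive(8, 12)))
    assert g.degenerate
    assert np.all(g.b[g.mask] == 0.0)


def test_outlier_has_dominant_bscore():
    rng = np.random.default_rng(3)
    vals = additive(8, 12) + rng.normal(0, 1, (8, 12))
    vals[4, 7] += 100
    g = b_score(PlateGrid(values=vals))
    assert np.abs(g.b).max() == abs(g.b[4, 7])
    assert abs(g.b[4, 7]) > 10


def test_outlier_robustness_as_simulation_oracle_supports():
    """A +100 outlier always dominates; the typical (median over seeds)
    worst off-target B-score shift stays below 0.5.  Row medians on an
    even-width plate can shift by ~half an order-statistic gap, so the
    worst case is not bounded by 0.5 in every seed."""
    max_shifts = []
    rng0 = np.random.default_rng(123)
    for seed in range(50):
        rng = np.random.default_rng(seed)
        base = additive(8, 12) + rng.normal(0, 1, (8, 12))
        r, c = rng0.integers(0, 8), rng0.integers(0, 12)
        pert = base.copy()
        pert[r, c] += 100
        b0 = b_score(PlateGrid(values=base)).b
        b1 = b_score(PlateGrid(values=pert)).b
        assert abs(b1[r, c]) > 10
        d = np.abs(b1 - b0)
        d[r, c] = 0.0
        max_shifts.append(d.max())
    assert np.median(max_shifts) < 0.5


def test_bscore_exactly_invariant_to_plate_and_row_offsets():
    """Whole-plate and per-row offsets are removed exactly by the first row
    sweep, so B-scores are identical to numerical precision."""
    rng = np.random.default_rng(5)
    vals = rng.normal(0, 1, (8, 12))
    g0 = b_score(PlateGrid(values=vals))
    for shifted in (vals + 100.0, vals + rng.normal(0, 3, 8)[:, None] + 7.0):
        g1 = b_score(PlateGrid(values=shifted))
        assert np.abs(g1.b - g0.b).max() <= 1e-9


def test_bscore_typically_invariant_to_generic_offsets():
    """Generic column offsets can flip which wells sit at a row median, so
    median polish may converge to a different (equally valid) fixed point;
    the typical deviation over random offset draws is still ~0."""
    devs = []
    for seed in range(40):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, (8, 12))
        shifted = (
            vals + 100.0 + rng.normal(0, 3, 8)[:, None] + rng.normal(0, 3, 12)[None, :]
        )
        g0 = b_score(PlateGrid(values=vals))
        g1 = b_score(PlateGrid(values=shifted))
        devs.append(np.abs(g1.b - g0.b).max())
    assert np.median(devs) <= 1e-6


# ---------------------------------------------------------------------------
# replicate agreement


def _noise_grid(seed, hits=None):
    params = PlateSimParams(noise_sd=1.0, hit_wells=hits or {})
    return b_score(simulate_plate(params, seed=seed))


def test_identical_replicates_correlate_perfectly():
    g = _noise_grid(0)
    r = replicate_agreement(g, g)
    assert r["pearson_r"] == pytest.approx(1.0)
    assert r["spearman_rho"] == pytest.approx(1.0)


def test_negated_replicate_anticorrelates():
    g = _noise_grid(1)
    neg = b_score(simulate_plate(PlateSimParams(noise_sd=1.0), seed=1))
    neg.b = -neg.b
    r = replicate_agreement(g, neg)
    assert r["pearson_r"] == pytest.approx(-1.0)


def test_too_few_paired_wells_rejected():
    g1 = b_score(PlateGrid(values=np.random.default_rng(0).normal(size=(2, 2))))
    with pytest.raises(ValueError, match="at least 3"):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        g1.mask = mask
        replicate_agreement(g1, g1)


def test_shared_hits_drive_duplicate_correlation():
    """Three shared -5 hits on unit-noise plates give a reliably positive
    duplicate correlation (signal variance 3/93 * 25 ~ 0.8 vs noise 1, so
    r centres near 0.45); without shared hits r centres at 0."""
    hits = {"B03": -5.0, "D07": -5.0, "F11": -5.0}
    with_hits, without = [], []
    for seed in range(60):
        g1 = _noise_grid(2 * seed, hits)
        g2 = _noise_grid(2 * seed + 1, hits)
        with_hits.append(replicate_agreement(g1, g2)["pearson_r"])
        h1 = _noise_grid(2 * seed)
        h2 = _noise_grid(2 * seed + 1)
        without.append(replicate_agreement(h1, h2)["pearson_r"])
    with_hits, without = np.array(with_hits), np.array(without)
    assert np.mean(with_hits >= 0.2) >= 0.90
    assert np.median(with_hits) > np.median(without) + 0.2


# ---------------------------------------------------------------------------
# z-scores and t-test


def test_z_zero_at_control_mean():
    z = z_score_vs_controls([1.0], [0.0, 2.0])
    assert z[0] == 0.0


def test_z_closed_form():
    z = z_score_vs_controls([1 + 3 * np.sqrt(2)], [0.0, 2.0])
    assert z[0] == pytest.approx(3.0, abs=1e-12)


def test_z_requires_control_variance():
    with pytest.raises(ValueError, match="variance"):
        z_score_vs_controls([1.0], [2.0, 2.0])


def test_z_affine_equivariance():
    rng = np.random.default_rng(0)
    x, ctrl = rng.normal(size=8), rng.normal(size=6)
    z0 = z_score_vs_controls(x, ctrl)
    z1 = z_score_vs_controls(3.5 * x - 2.0, 3.5 * ctrl - 2.0)
    np.testing.assert_allclose(z0, z1, atol=1e-10)


def _welch_closed_form(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    from scipy import stats

    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


@pytest.mark.parametrize(
    "a,b",
    [
        ([1.0, 2.0, 3.0], [11.2, 12.1, 12.9]),
        ([0.5, 0.7, 0.9, 1.4], [0.2, 0.6]),
        ([10, 20, 30, 40, 50], [12, 19, 33]),
    ],
)
def test_welch_matches_textbook_formula(a, b):
    res = welch_t_test(a, b)
    t, df, p = _welch_closed_form(a, b)
    assert res.t == pytest.approx(t, abs=1e-10)
    assert res.df == pytest.approx(df, abs=1e-10)
    assert res.p_two_tailed == pytest.approx(p, abs=1e-10)


def test_welch_identical_groups_null():
    res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0 and res.p_two_tailed == 1.0


def test_welch_shifted_groups_significant():
    res = welch_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    assert res.p_two_tailed < 0.01


def test_welch_degenerate_conventions():
    same = welch_t_test([2.0, 2.0], [2.0, 2.0])
    assert same.p_two_tailed == 1.0
    diff = welch_t_test([2.0, 2.0], [3.0, 3.0])
    assert diff.p_two_tailed == 0.0 and "limit" in diff.note


# ---------------------------------------------------------------------------
# MTS timepoint selection


def test_monotone_series_picks_last_timepoint():
    series = np.outer(np.linspace(0.2, 1.0, 10), np.arange(1.0, 5.0))
    choice = select_mts_timepoint(series, saturation_limit=100.0)
    assert choice.index == series.shape[1] - 1


def test_saturating_well_excludes_last_timepoint():
    series = np.outer(np.linspace(0.2, 1.0, 10), np.arange(1.0, 5.0))
    series[-1, -1] = 200.0
    choice = select_mts_timepoint(series, saturation_limit=100.0)
    assert choice.index == series.shape[1] - 2
    assert not choice.saturated_fallback


def test_logistic_kinetics_match_enumeration_oracle():
    t = np.linspace(0.0, 4.0, 9)
    scale = np.linspace(0.3, 1.05, 12)
    series = np.array([3.0 / (1 + np.exp(-(t - 2) / 0.5)) * a for a in scale])
    limit = 2.8
    choice = select_mts_timepoint(series, limit)
    # brute force over timepoints
    best, best_dr = None, -np.inf
    for j in range(series.shape[1]):
        if (series[:, j] > limit).any():
            continue
        dr = np.percentile(series[:, j], 95) - np.percentile(series[:, j], 5)
        if dr > best_dr:
            best, best_dr = j, dr
    assert choice.index == best
    assert choice.dynamic_range == pytest.approx(best_dr)


def test_all_saturating_falls_back_with_flag():
    series = np.full((6, 3), 10.0)
    series[:, 0] = [1, 1, 1, 1, 1, 20]
    with pytest.warns(UserWarning, match="saturate"):
        choice = select_mts_timepoint(series, saturation_limit=5.0)
    assert choice.saturated_fallback
    assert choice.index == 0


def test_single_timepoint_warns():
    with pytest.warns(UserWarning, match="single"):
        choice = select_mts_timepoint(np.ones((4, 1)), 5.0)
    assert choice.index == 0


# ---------------------------------------------------------------------------
# group separation under the arrayed-screen design (6 wells per group)


def test_group_separation_rates_match_simulation_oracle():
    """With 6 wells per group, an 8*SD effect makes every sample well a
    >3-SD outlier with Welch p < 1e-4 in nearly all seeds; a 5*SD effect
    does so only ~3/4 of the time (the n=6 control SD estimate and the
    minimum over six wells keep the joint event noisy)."""
    rates = {}
    for effect in (5.0, 8.0):
        ok = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ctrl = rng.normal(0.0, 1.0, 6)
            samp = rng.normal(effect, 1.0, 6)
            z = z_score_vs_controls(samp, ctrl)
            t = welch_t_test(samp, ctrl)
            ok += bool(np.all(np.abs(z) > 3) and t.p_two_tailed < 1e-4)
        rates[effect] = ok / 200
    assert rates[8.0] >= 0.95
    assert 0.55 <= rates[5.0] <= 0.92
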