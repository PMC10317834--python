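"""Tests for filtering, CPM, TMM and the NB likelihood-ratio test."""

import math

import numpy as np
import pandas as pd
import pytest

from mirlink.diffexpr import (CountMatrix, NormalizationState, cpm,
                              filter_low_counts, nb_fit_dispersion, nb_lrt,
                              select_signature, tmm_factors)


def _cm(counts, ftype="mRNA"):
    counts = np.asarray(counts)
    return CountMatrix(counts, [f"f{i}" for i in range(counts.shape[0])],
                       [f"s{j}" for j in range(counts.shape[1])], ftype)


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

def test_count_matrix_validation():
    with pytest.raises(ValueError, match="nonnegative"):
        _cm([[1, -1]])
    with pytest.raises(ValueError, match="integers"):
        _cm([[1.5, 2.0]])
    with pytest.raises(ValueError, match="duplicate feature"):
        CountMatrix([[1], [2]], ["a", "a"], ["s1"])


# ---------------------------------------------------------------------------
# CPM
# ---------------------------------------------------------------------------

def test_cpm_known_values():
    m = _cm([[10], [90]])
    vals = cpm(m).to_numpy().ravel()
    assert vals == pytest.approx([1e5, 9e5])
    assert cpm(m).sum(axis=0).to_numpy() == pytest.approx([1e6])


def test_log2_cpm_formula():
    m = CountMatrix(np.array([[0], [999_999]]), ["a", "b"], ["s"])
    norm = NormalizationState([1e6], [1.0])
    val = cpm(m, norm, log2=True, prior=0.5).loc["a", "s"]
    assert val == pytest.approx(math.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-9)
    assert val == pytest.approx(-1.0000014, abs=1e-6)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_boundaries_and_report():
    # library sizes 100 and 200; feature CPMs computed by hand
    counts = np.array([
        [0, 0],      # undetectable
        [1, 0],      # cpm (1e4, 0): above 1 in one sample only
        [1, 2],      # cpm (1e4, 1e4): >= min_cpm in both samples
        [0, 1],      # cpm (0, 5e3)
        [98, 197],   # bulk of the library
    ])
    m = _cm(counts)
    kept, report = filter_low_counts(m, min_cpm=1.0, min_samples=2)
    assert kept.feature_ids == ["f2", "f4"]
    assert (report.n_input, report.n_undetectable, report.n_filtered,
            report.n_retained) == (5, 1, 2, 2)


def test_filter_boundary_is_inclusive():
    # one feature at exactly min_cpm in exactly min_samples samples
    counts = np.array([[1, 1, 0], [999, 999, 1000]])
    m = _cm(counts)
    # library size 1000 in every sample, so f0 sits at exactly 1000 CPM in
    # exactly two samples
    kept, _ = filter_low_counts(m, min_cpm=1000.0, min_samples=2)
    assert "f0" in kept.feature_ids


def test_filter_empty_result_raises():
    with pytest.raises(ValueError, match="filtering"):
        filter_low_counts(_cm([[1, 1], [1, 1]]), min_cpm=1e9, min_samples=1)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_oracle_pair(obs, ref):
    """Straightforward loop implementation of the published TMM recipe."""
    n_o, n_r = obs.sum(), ref.sum()
    rows = []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m = math.log2((o / n_o) / (r / n_r))
            a = 0.5 * math.log2((o / n_o) * (r / n_r))
            w = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
            rows.append((m, a, w))
    if not rows or max(abs(m) for m, _, _ in rows) < 1e-6:
        return 1.0
    n = len(rows)
    by_m = sorted(range(n), key=lambda i: rows[i][0])
    by_a = sorted(range(n), key=lambda i: rows[i][1])
    lo_m, hi_m = math.floor(n * 0.3), n - math.floor(n * 0.3)
    lo_a, hi_a = math.floor(n * 0.05), n - math.floor(n * 0.05)
    keep = set(by_m[lo_m:hi_m]) & set(by_a[lo_a:hi_a])
    sw = sum(rows[i][2] for i in keep)
    sm = sum(rows[i][0] * rows[i][2] for i in keep)
    return 2 ** (sm / sw) if sw > 0 else 1.0


def test_tmm_identical_samples_and_pure_scaling():
    counts = np.array([[10, 10], [20, 20], [5, 5], [100, 100]])
    assert tmm_factors(_cm(counts)).tmm_factors == pytest.approx([1, 1])
    doubled = np.c_[counts[:, 0], counts[:, 0] * 2]
    assert tmm_factors(_cm(doubled)).tmm_factors == pytest.approx([1, 1])


def test_tmm_matches_independent_oracle():
    rng = np.random.default_rng(0)
    base = rng.poisson(200, size=50) + 1
    b = base.copy()
    b[:5] *= 4  # a few features quadrupled in the perturbed sample
    # two identical copies of the base sample pin the reference choice
    counts = np.c_[base, base, b]
    got = tmm_factors(_cm(counts)).tmm_factors
    f = tmm_oracle_pair(b.astype(float), base.astype(float))
    expected = np.array([1.0, 1.0, f]) / f ** (1 / 3)
    assert got == pytest.approx(expected, rel=1e-9)


def test_tmm_scaling_one_sample_changes_only_its_effective_size():
    # CPMs are unchanged by an integer rescaling of one sample, so effective
    # sizes scale (almost) proportionally; the small slack reflects TMM's
    # count-dependent precision weights, which are not scale-free
    rng = np.random.default_rng(1)
    counts = rng.poisson(100, size=(200, 4))
    m = _cm(counts)
    norm = tmm_factors(m)
    scaled = counts.copy()
    scaled[:, 2] *= 3
    norm2 = tmm_factors(_cm(scaled))
    ratio = norm2.effective_sizes / norm.effective_sizes
    assert ratio[2] == pytest.approx(3.0, rel=5e-3)
    assert ratio[[0, 1, 3]] == pytest.approx(np.ones(3), rel=5e-3)
    # the DE table is stable: rescaling one of ten group members only mildly
    # re-weights it in the library-size-weighted group mean
    counts = rng.poisson(100, size=(200, 20))
    groups = ["A"] * 10 + ["B"] * 10
    m = _cm(counts)
    scaled = counts.copy()
    scaled[:, 12] *= 3
    det = nb_lrt(m, groups, contrast=("A", "B"), norm=tmm_factors(m), dispersion=0.05)
    det2 = nb_lrt(_cm(scaled), groups, contrast=("A", "B"),
                  norm=tmm_factors(_cm(scaled)), dispersion=0.05)
    assert det2["log2fc"].to_numpy() == pytest.approx(det["log2fc"].to_numpy(), abs=0.1)
    assert np.corrcoef(det2["p"], det["p"])[0, 1] > 0.99


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def test_dispersion_recovery():
    rng = np.random.default_rng(2)
    mu = np.exp(rng.normal(4, 1.5, 2000))
    groups = ["A"] * 10 + ["B"] * 10
    phi = 0.2
    r = 1 / phi
    y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 20))
    fit = nb_fit_dispersion(_cm(y), groups)
    assert 0.15 <= fit.common <= 0.25
    y0 = rng.poisson(np.broadcast_to(mu[:, None], (2000, 20)))
    fit0 = nb_fit_dispersion(_cm(y0), groups)
    assert fit0.common <= 0.01


def test_dispersion_floor_for_constant_counts():
    y = np.full((5, 6), 7)
    fit = nb_fit_dispersion(_cm(y), ["A"] * 3 + ["B"] * 3)
    assert fit.common == pytest.approx(1e-4)
    assert np.all(fit.per_feature >= 1e-4)


# ---------------------------------------------------------------------------
# NB LRT
# ---------------------------------------------------------------------------

def test_lrt_log2fc_of_constant_groups():
    y = np.tile(np.array([[10] * 4 + [40] * 4]), (3, 1))
    m = _cm(y)
    norm = NormalizationState(np.ones(8) * 1000, np.ones(8))
    det = nb_lrt(m, ["A"] * 4 + ["B"] * 4, contrast=("A", "B"), norm=norm,
                 dispersion=0.1)
    assert det["log2fc"].to_numpy() == pytest.approx(2.0, abs=0.02)
    assert (det["direction"] == "up").all()


def test_lrt_identical_groups_is_null():
    rng = np.random.default_rng(3)
    y = rng.poisson(50, size=(50, 8))
    y = np.c_[y, y]
    det = nb_lrt(_cm(y), ["A"] * 8 + ["B"] * 8, contrast=("A", "B"),
                 norm=NormalizationState(np.ones(16), np.ones(16)), dispersion=0.05)
    assert np.abs(det["log2fc"]).max() < 1e-6
    assert det["p"].min() > 0.9


def test_lrt_invariant_to_row_and_column_order():
    rng = np.random.default_rng(4)
    y = rng.poisson(30, size=(40, 10))
    groups = np.array(["A"] * 5 + ["B"] * 5)
    m = _cm(y)
    det = nb_lrt(m, groups, contrast=("A", "B"), dispersion=0.1)
    perm_s = rng.permutation(10)
    perm_f = rng.permutation(40)
    m2 = CountMatrix(y[np.ix_(perm_f, perm_s)],
                     [m.feature_ids[i] for i in perm_f],
                     [m.sample_ids[j] for j in perm_s])
    det2 = nb_lrt(m2, groups[perm_s], contrast=("A", "B"), dispersion=0.1)
    joined = det.join(det2, lsuffix="_a", rsuffix="_b")
    assert joined["log2fc_a"].to_numpy() == pytest.approx(joined["log2fc_b"].to_numpy(),
                                                          abs=1e-8)
    assert joined["p_a"].to_numpy() == pytest.approx(joined["p_b"].to_numpy(), abs=1e-8)


def test_lrt_null_calibration():
    rng = np.random.default_rng(5)
    phi = 0.1
    r = 1 / phi
    mu = np.exp(rng.normal(4, 1, 2000))
    y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 26))
    m = _cm(y)
    groups = ["A"] * 13 + ["B"] * 13
    disp = nb_fit_dispersion(m, groups)
    det = nb_lrt(m, groups, contrast=("A", "B"), dispersion=disp)
    frac = float((det["p"] <= 0.05).mean())
    assert 0.02 <= frac <= 0.10


# ---------------------------------------------------------------------------
# signature selection
# ---------------------------------------------------------------------------

def _table(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "log2fc", "mean_log2cpm", "p", "fdr"])
    df["direction"] = np.where(df.log2fc > 0, "up", "down")
    return df.set_index("feature_id")


def test_signature_ranking_and_truncation():
    t = _table([("a", 2, 5, 1e-5, 1e-4), ("b", -3, 5, 1e-3, 1e-2),
                ("c", 1.5, 5, 1e-4, 1e-3), ("d", 1.2, 5, 2e-3, 2e-2),
                ("e", 0.5, 5, 1e-9, 1e-8)])  # e fails the fold-change threshold
    assert select_signature(t, 0.05, 1.0, top_n=3) == ["a", "c", "b"]


def test_signature_tie_breaks():
    t = _table([("b", 1.0, 5, 1e-3, 1e-2), ("a", 1.0, 5, 1e-3, 1e-2),
                ("c", 2.0, 5, 1e-3, 1e-2)])
    assert select_signature(t, 0.05, 1.0) == ["c", "a", "b"]


def test_signature_warns_when_short():
    t = _table([("a", 2, 5, 1e-5, 1e-4), ("b", 3, 5, 1e-3, 1e-2)])
    with pytest.warns(UserWarning, match="only 2"):
        ids = select_signature(t, 0.05, 1.0, top_n=200)
    assert len(ids) == 2


def test_planted_recovery_on_generator_output(small_dataset):
    ds = small_dataset
    meta = ds.metadata
    keep = meta.isin(["M-CLL-S", "U-CLL-S"])
    m = ds.mrna_counts.select_samples(list(meta.index[keep]))
    lab = meta[keep]
    mf, _ = filter_low_counts(m, 1.0, 13)
    norm = tmm_factors(mf)
    disp = nb_fit_dispersion(mf, lab, norm)
    det = nb_lrt(mf, lab, contrast=("M-CLL-S", "U-CLL-S"), norm=norm, dispersion=disp)
    truth = {g: fc for g, fc in ds.truth.de_genes.items() if g in det.index}
    err = (det.loc[list(truth), "log2fc"] - pd.Series(truth)).abs()
    assert err.median() <= 0.25
    sig = set(select_signature(det, 0.05, 1.0))
    assert np.mean([g in sig for g in truth]) >= 0.9
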