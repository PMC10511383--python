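"""Tests of the region taxonomy and nonparametric statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations

from ogdenfit.stats import (
    ANATOMICAL_REGIONS,
    GOVERNING_MAP,
    GOVERNING_REGIONS,
    holm_adjust,
    kruskal_wallis,
    map_governing_region,
    paired_differences,
    pairwise_mann_whitney_holm,
    shapiro_wilk,
    summarize,
    wilcoxon_paired,
)


# ------------------------------------------------------------------ taxonomy

EXPECTED_MAP = {
    "Am": "Am", "CC": "CC", "CI": "C", "CR": "CR", "FC": "C", "Hi": "Hi",
    "M": "M", "MC": "C", "Me": "BS", "NC": "BG", "P": "BS", "Pa": "BG",
    "Pu": "BG", "TL": "C", "Th": "M", "VC": "C", "WM": "CR", "cN": "CB",
    "cWM": "CB",
}


@pytest.mark.parametrize("anatomical, governing", sorted(EXPECTED_MAP.items()))
def test_governing_region_assignment(anatomical, governing):
    assert map_governing_region(anatomical) == governing


def test_taxonomy_is_total_with_nine_targets():
    assert len(ANATOMICAL_REGIONS) == 19
    assert set(GOVERNING_MAP) == set(ANATOMICAL_REGIONS)
    assert set(GOVERNING_MAP.values()) == set(GOVERNING_REGIONS)
    assert len(GOVERNING_REGIONS) == 9


def test_unknown_region_lists_valid_codes():
    with pytest.raises(KeyError, match="Am"):
        map_governing_region("XX")


# -------------------------------------------------------------- shapiro gate

def test_shapiro_requires_three_nonconstant_values():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 1.0, 1.0])


def test_shapiro_calibration_on_normal_samples():
    rng = np.random.default_rng(100)
    passes = sum(
        shapiro_wilk(rng.normal(size=50)).p_raw > 0.05 for _ in range(100)
    )
    assert passes >= 90


def test_shapiro_detects_heavy_tails():
    rng = np.random.default_rng(101)
    rejects = 0
    for _ in range(100):
        x = rng.normal(size=50)
        rejects += shapiro_wilk(np.sign(x) * x**2).p_raw < 0.05
    assert rejects >= 90


# ------------------------------------------------------------ kruskal-wallis

def test_kruskal_wallis_hand_example():
    """Groups [1,2] vs [3,4]: rank sums give H = 2.4 exactly."""
    res = kruskal_wallis({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    assert res.statistic == pytest.approx(2.4, rel=1e-12)


def test_kruskal_wallis_identical_groups():
    res = kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_raw > 0.9


def test_kruskal_wallis_single_group_rejected():
    with pytest.raises(ValueError):
        kruskal_wallis({"a": [1.0, 2.0]})


def test_kruskal_wallis_type_one_error_calibrated():
    """Permuting null labels: empirical rejection rate ~ alpha = 0.05."""
    rng = np.random.default_rng(7)
    data = rng.normal(size=24)
    rejections = 0
    n_perm = 1000
    for _ in range(n_perm):
        perm = rng.permutation(data)
        res = kruskal_wallis({"a": perm[:8], "b": perm[8:16], "c": perm[16:]})
        rejections += res.p_raw < 0.05
    assert 0.03 <= rejections / n_perm <= 0.07


# --------------------------------------------------------------- mann-whitney

def test_mann_whitney_exact_hand_example():
    """[1,2] vs [3,4]: U = 0, exact two-sided p = 2/6."""
    res = pairwise_mann_whitney_holm({"a": [1.0, 2.0], "b": [3.0, 4.0]})[0]
    assert res.statistic == 0.0
    assert res.p_raw == pytest.approx(1.0 / 3.0, rel=1e-12)


def _exact_mw_p(x, y):
    """Exhaustive two-sided Mann-Whitney p by enumerating all splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))

    def u_stat(ix):
        xx = pooled[list(ix)]
        yy = np.delete(pooled, list(ix))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xx for yj in yy)

    u_obs = u_stat(range(n1))
    n2 = len(y)
    dev = abs(u_obs - n1 * n2 / 2)
    count = total = 0
    for ix in combinations(idx, n1):
        total += 1
        count += abs(u_stat(ix) - n1 * n2 / 2) >= dev - 1e-12
    return count / total


@pytest.mark.parametrize("n1, n2", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4)])
def test_mann_whitney_matches_exhaustive_enumeration(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    x = rng.normal(size=n1)
    y = rng.normal(size=n2) + 0.5
    res = pairwise_mann_whitney_holm({"a": x, "b": y})[0]
    assert res.p_raw == pytest.approx(_exact_mw_p(x, y), rel=1e-9)


def test_mann_whitney_identical_groups_capped():
    res = pairwise_mann_whitney_holm(
        {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
    )[0]
    assert res.p_adjusted == 1.0
    assert not res.significant


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        pairwise_mann_whitney_holm({"a": [1.0], "b": []})


# ----------------------------------------------------------------------- holm

def test_holm_hand_example():
    np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])


@given(
    ps=st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=10)
)
@settings(max_examples=50, deadline=None)
def test_holm_monotone_and_dominates_raw(ps):
    adj = holm_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-15)


# ------------------------------------------------------------------- wilcoxon

def test_wilcoxon_hand_example():
    """All-positive differences [1,2,3]: negative-rank sum W = 0."""
    res = wilcoxon_paired([1.0, 2.0, 3.0], min_nonzero=3)
    assert res.statistic == 0.0


def test_wilcoxon_symmetric_differences():
    res = wilcoxon_paired([-2.0, -1.0, 1.0, 2.0], min_nonzero=4)
    assert res.p_raw == pytest.approx(1.0)


def test_wilcoxon_zero_handling_and_power():
    with pytest.raises(ValueError):
        wilcoxon_paired([0.0, 0.0])
    rng = np.random.default_rng(8)
    shifted = rng.normal(loc=1.0, size=30)
    assert wilcoxon_paired(shifted).p_raw < 0.05


# ------------------------------------------------------------------ summaries

def _toy_cohort():
    rows = []
    rng = np.random.default_rng(3)
    for region, mu0 in (("CC", 100.0), ("CR", 200.0)):
        for i in range(4):
            for cyc, nu in ((1, 0.45), (1, 0.49)):
                rows.append(
                    {
                        "specimen_id": f"{region}{i}",
                        "brain_id": i % 2 + 1,
                        "anatomical_region": region,
                        "governing_region": region,
                        "cycle": cyc,
                        "nu": nu,
                        "mu": mu0 + (10.0 if nu == 0.49 else 0.0) + rng.normal(),
                        "alpha": -15.0,
                        "rmse": 5.0,
                    }
                )
    return pd.DataFrame(rows)


def test_summarize_recovers_group_means():
    df = _toy_cohort()
    s = summarize(df, by="region")
    cc = s[(s.governing_region == "CC") & (s.nu == 0.45)]
    assert cc["mu_mean"].iloc[0] == pytest.approx(100.0, abs=2.0)
    assert (s["n"] == 4).all()


def test_summarize_single_row_flagged():
    df = _toy_cohort().iloc[:1]
    s = summarize(df, by="region")
    assert s["single_observation"].iloc[0]
    assert s["mu_std"].iloc[0] == 0.0


def test_summarize_empty_rejected():
    with pytest.raises(ValueError):
        summarize(pd.DataFrame(), by="region")


def test_paired_differences_median_direction():
    df = _toy_cohort()
    d = paired_differences(df, (1, 0.45), (1, 0.49))
    assert len(d) == 8
    assert d["d_mu"].median() == pytest.approx(-10.0, abs=1.0)


def test_region_effect_detected_only_in_mu():
    """A mu-only region effect yields significant mu comparisons while the
    shared alpha stays null (up to the nominal false-positive rate)."""
    mu_hits = alpha_hits = 0
    n_rep = 8
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        mus = {
            "CC": 100 * np.exp(rng.normal(0, 0.15, size=10)),
            "CR": 400 * np.exp(rng.normal(0, 0.15, size=10)),
        }
        alphas = {g: -15 + rng.normal(0, 1.0, size=10) for g in mus}
        mu_hits += pairwise_mann_whitney_holm(mus)[0].significant
        alpha_hits += pairwise_mann_whitney_holm(alphas)[0].significant
    assert mu_hits == n_rep
    assert alpha_hits <= 1
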