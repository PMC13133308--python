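"""Accuracy statistics: confusion, intervals, kappa, FPC margin, OR, PPV."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ardscreen.evaluate import (Confusion2x2, LabelMismatchError,
                                clopper_pearson_ci, cohen_kappa, confusion,
                                dx_metrics, fpc_margin, odds_ratio_2x2,
                                ppv_gradient, round_half_away, wilson_ci)


def _labels(n_ards, n_poss, n_non):
    rows = ([("A%d" % i, "ARDS") for i in range(n_ards)]
            + [("P%d" % i, "POSSIBLE") for i in range(n_poss)]
            + [("N%d" % i, "NON_ARDS_AHRF") for i in range(n_non)])
    return pd.DataFrame(rows, columns=["stay_id", "label"])


def test_confusion_reproduces_published_icd_counts():
    """756/993 flagged ARDS and 451/879 flagged non-ARDS, POSSIBLE excluded."""
    labels = _labels(993, 128, 879)
    flags = {f"A{i}": i < 756 for i in range(993)}
    flags.update({f"N{i}": i < 451 for i in range(879)})
    flags.update({f"P{i}": True for i in range(128)})
    c = confusion(labels, flags, possible_handling="EXCLUDE")
    assert (c.tp, c.fn, c.fp, c.tn) == (756, 237, 451, 428)
    m = dx_metrics(c)
    assert m.sensitivity.value == pytest.approx(756 / 993)
    assert round_half_away(100 * m.sensitivity.value) == 76
    assert m.specificity.value == pytest.approx(428 / 879)


def test_confusion_all_positive_degenerate():
    labels = _labels(5, 0, 0)
    c = confusion(labels, {s: True for s in labels["stay_id"]})
    assert c.fp == 0 and c.tn == 0 and c.tp == 5


def test_confusion_matches_elementwise_tally_oracle():
    rng = np.random.default_rng(0)
    for _ in range(25):
        labels = _labels(rng.integers(0, 8), rng.integers(0, 8), rng.integers(0, 8))
        flags = {s: bool(rng.random() < 0.5) for s in labels["stay_id"]}
        for handling in ("EXCLUDE", "AS_NEGATIVE"):
            c = confusion(labels, flags, possible_handling=handling)
            tp = fp = fn = tn = 0
            for s, l in zip(labels["stay_id"], labels["label"]):
                if l == "POSSIBLE" and handling == "EXCLUDE":
                    continue
                pos = l == "ARDS"
                f = flags[s]
                tp += pos and f; fp += (not pos) and f
                fn += pos and not f; tn += (not pos) and not f
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


def test_flagged_stay_without_label_raises():
    with pytest.raises(LabelMismatchError, match="GHOST"):
        confusion(_labels(2, 0, 2), {"GHOST": True})


def test_undefined_metrics_are_none_not_zero():
    m = dx_metrics(Confusion2x2(tp=0, fp=0, fn=3, tn=5))
    assert m.ppv is None
    assert m.sensitivity.value == 0.0


# ---------------------------------------------------------------------------
# binomial intervals

def _wilson_oracle(x, n, conf=0.95):
    z = stats.norm.ppf((1 + conf) / 2)
    p = x / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


def test_wilson_worked_example_and_boundaries():
    lo, hi = wilson_ci(6, 100)
    assert (round(lo, 4), round(hi, 4)) == (0.0278, 0.1248)
    assert lo == pytest.approx(0.027787, abs=1e-6)
    assert hi == pytest.approx(0.124768, abs=1e-6)
    assert wilson_ci(0, 10)[0] == pytest.approx(0.0, abs=1e-12)
    assert wilson_ci(10, 10)[1] == pytest.approx(1.0, abs=1e-12)


@given(st.integers(1, 400).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
def test_wilson_matches_closed_form_and_score_inversion(nx):
    n, x = nx
    lo, hi = wilson_ci(x, n)
    olo, ohi = _wilson_oracle(x, n)
    assert lo == pytest.approx(olo, abs=1e-9)
    assert hi == pytest.approx(ohi, abs=1e-9)
    assert 0.0 <= lo <= x / n <= hi <= 1.0
    # the endpoints solve the score equation |p̂-p| = z*sqrt(p(1-p)/n)
    z = stats.norm.ppf(0.975)
    for p in (lo, hi):
        if 0 < p < 1:
            assert abs(x / n - p) == pytest.approx(z * math.sqrt(p * (1 - p) / n), abs=1e-7)


@given(st.integers(2, 200).flatmap(lambda n: st.tuples(st.just(n), st.integers(1, n - 1))))
def test_clopper_pearson_matches_beta_inversion(nx):
    n, x = nx
    lo, hi = clopper_pearson_ci(x, n)
    assert lo == pytest.approx(stats.beta.ppf(0.025, x, n - x + 1), abs=1e-9)
    assert hi == pytest.approx(stats.beta.ppf(0.975, x + 1, n - x), abs=1e-9)
    assert 0.0 <= lo <= x / n <= hi <= 1.0


def test_clopper_pearson_wider_than_wilson_at_worked_example():
    wlo, whi = wilson_ci(6, 100)
    clo, chi = clopper_pearson_ci(6, 100)
    assert clo < wlo and chi > whi


def test_interval_coverage_at_known_p_seeded():
    rng = np.random.default_rng(123)
    p, n, reps = 0.3, 50, 2000
    xs = rng.binomial(n, p, size=reps)
    cover_w = np.mean([lo <= p <= hi for lo, hi in (wilson_ci(x, n) for x in xs)])
    cover_cp = np.mean([lo <= p <= hi for lo, hi in (clopper_pearson_ci(x, n) for x in xs)])
    assert cover_w >= 0.93
    assert cover_cp >= 0.95


def test_wilson_requires_positive_n():
    with pytest.raises(ValueError):
        wilson_ci(0, 0)


# ---------------------------------------------------------------------------
# kappa

def test_kappa_identities_and_oracle():
    assert cohen_kappa(np.diag([10, 5, 7])).kappa == pytest.approx(1.0)
    # independent margins: outer product of (0.5,0.3,0.2) scaled
    m = np.outer([50, 30, 20], [50, 30, 20]) / 100.0
    assert cohen_kappa(m).kappa == pytest.approx(0.0, abs=1e-12)
    t = [[40, 5, 0], [5, 20, 5], [0, 5, 20]]
    res = cohen_kappa(t)
    assert res.p_o == pytest.approx(0.8)
    assert res.p_e == pytest.approx(0.355)
    assert res.kappa == pytest.approx((0.8 - 0.355) / (1 - 0.355))


def test_kappa_agrees_with_sklearn_on_label_vectors():
    from sklearn.metrics import cohen_kappa_score
    rng = np.random.default_rng(5)
    a = rng.integers(0, 3, 200)
    b = np.where(rng.random(200) < 0.6, a, rng.integers(0, 3, 200))
    table = np.zeros((3, 3))
    for i, j in zip(a, b):
        table[i, j] += 1
    assert cohen_kappa(table).kappa == pytest.approx(cohen_kappa_score(a, b))


def test_kappa_invariant_under_category_permutation():
    rng = np.random.default_rng(8)
    t = rng.integers(0, 30, (3, 3)).astype(float)
    k0 = cohen_kappa(t).kappa
    perm = [2, 0, 1]
    assert cohen_kappa(t[np.ix_(perm, perm)]).kappa == pytest.approx(k0)


# ---------------------------------------------------------------------------
# finite-population margin, odds ratio, PPV gradient

def test_fpc_margin_for_review_sample_design():
    # 2000 reviews of a 3940-subject screen-positive population at p=0.5
    m = fpc_margin(0.5, 2000, 3940)
    assert round(100 * m, 1) == 1.5
    assert m == pytest.approx(0.01538, abs=5e-5)


def test_fpc_margin_census_and_large_population_limits():
    assert fpc_margin(0.5, 100, 100) == pytest.approx(0.0, abs=1e-12)
    big = fpc_margin(0.5, 2000, 10**9)
    srs = stats.norm.ppf(0.975) * math.sqrt(0.25 / 2000)
    assert big == pytest.approx(srs, rel=1e-3)
    with pytest.raises(ValueError):
        fpc_margin(0.5, 200, 100)


def test_odds_ratio_from_published_mortality_counts():
    res = odds_ratio_2x2(276, 717, 304, 575)
    assert res.odds_ratio == pytest.approx(276 * 575 / (717 * 304), rel=1e-12)
    assert res.odds_ratio == pytest.approx(0.728, abs=5e-4)
    assert res.ci_low < res.odds_ratio < res.ci_high
    assert not res.haldane_corrected


def test_odds_ratio_identities():
    assert odds_ratio_2x2(10, 20, 5, 10).odds_ratio == pytest.approx(1.0)
    a = odds_ratio_2x2(12, 7, 9, 30)
    b = odds_ratio_2x2(9, 30, 12, 7)
    assert a.odds_ratio == pytest.approx(1 / b.odds_ratio)
    assert odds_ratio_2x2(5, 0, 3, 7).haldane_corrected


def test_ppv_gradient_worked_example_and_oracle():
    grad = ppv_gradient({"48": ["ARDS"] * 21 + ["POSSIBLE"] * 5 + ["NON_ARDS_AHRF"] * 74})
    row = grad.iloc[0]
    assert row["ppv"] == pytest.approx(0.21)
    assert row["ppv_with_possible"] == pytest.approx(0.26)
    assert row["ppv_ci_low"] <= row["ppv"] <= row["ppv_ci_high"]
    all_ards = ppv_gradient({"72": ["ARDS"] * 30}).iloc[0]
    assert all_ards["ppv"] == pytest.approx(1.0)
    rng = np.random.default_rng(2)
    for _ in range(10):
        lbls = list(rng.choice(["ARDS", "POSSIBLE", "NON_ARDS_AHRF"], size=rng.integers(1, 40)))
        row = ppv_gradient({"w": lbls}).iloc[0]
        assert row["ppv"] == pytest.approx(lbls.count("ARDS") / len(lbls))
        assert row["n_ards"] + row["n_possible"] + row["n_non"] == row["n_reviewed"]
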