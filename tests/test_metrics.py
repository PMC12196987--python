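"""Evaluation metrics against independently coded brute-force oracles,
plus the invariances each metric must satisfy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beatbp.metrics import (SequencePair, mae_seq, rseq, diff_seq, ve,
                            classify_state, classification_report,
                            beat_averaged, me_sd, aami_check, bhs_grade,
                            bland_altman, evaluate_pairs)
from beatbp.autodiff import Tensor
from beatbp.train import loss_l1


# ----------------------------------------------------- brute-force oracles

def oracle_mae(pairs):
    tot, cnt = 0.0, 0
    for p in pairs:
        for x, y in zip(p.gt, p.pred):
            tot += abs(x - y)
            cnt += 1
    return tot / cnt


def oracle_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def oracle_rseq(pairs):
    rs = [oracle_pearson(p.gt, p.pred) for p in pairs]
    return sum(rs) / len(rs)


def oracle_ve(pairs):
    tot = 0.0
    for p in pairs:
        n = len(p.gt)
        s = 0.0
        for j in range(1, n):
            s += abs((p.gt[j] - p.gt[j - 1]) - (p.pred[j] - p.pred[j - 1]))
        tot += s / (n - 1)
    return tot / len(pairs)


def oracle_me_sd(pairs):
    errs = [y - x for p in pairs for x, y in zip(p.gt, p.pred)]
    me = sum(errs) / len(errs)
    var = sum((e - me) ** 2 for e in errs) / len(errs)
    return me, var**0.5


def oracle_bhs_pcts(errs):
    out = []
    for t in (5.0, 10.0, 15.0):
        out.append(100.0 * sum(1 for e in errs if abs(e) <= t) / len(errs))
    return tuple(out)


def oracle_bland_altman(pairs):
    d = [y - x for p in pairs for x, y in zip(p.gt, p.pred)]
    m = sum(d) / len(d)
    sd = (sum((v - m) ** 2 for v in d) / len(d)) ** 0.5
    lo, hi = m - 1.96 * sd, m + 1.96 * sd
    within = 100.0 * sum(1 for v in d if lo <= v <= hi) / len(d)
    return m, lo, hi, within


def random_pairs(m, n=60, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        gt = 120.0 + rng.normal(0, 8, size=n).cumsum() * 0.2
        pred = gt + rng.normal(0, 4, size=n)
        out.append(SequencePair(gt, pred))
    return out


# ------------------------------------------------------- oracle equivalence

def test_metrics_match_oracles_on_1000_pairs():
    pairs = random_pairs(1000, seed=99)
    assert abs(mae_seq(pairs) - oracle_mae(pairs)) < 1e-10
    assert abs(rseq(pairs) - oracle_rseq(pairs)) < 1e-10
    assert abs(ve(pairs) - oracle_ve(pairs)) < 1e-10
    me, sd = me_sd(pairs)
    ome, osd = oracle_me_sd(pairs)
    assert abs(me - ome) < 1e-10 and abs(sd - osd) < 1e-10
    errs = np.concatenate([p.pred - p.gt for p in pairs])
    got = bhs_grade(errs)
    exp = oracle_bhs_pcts(errs)
    assert max(abs(a - b) for a, b in
               zip((got["pct5"], got["pct10"], got["pct15"]), exp)) < 1e-10
    ba = bland_altman(pairs)
    oba = oracle_bland_altman(pairs)
    assert max(abs(a - b) for a, b in
               zip((ba["mean_diff"], ba["loa_low"], ba["loa_high"],
                    ba["pct_within"]), oba)) < 1e-10


def test_diff_seq_matches_oracle():
    rng = np.random.default_rng(5)
    seq = rng.normal(120, 10, size=60)
    oracle = [seq[j] - seq[j - 1] for j in range(1, 60)]
    np.testing.assert_allclose(diff_seq(seq), oracle, atol=1e-15)
    np.testing.assert_array_equal(diff_seq([100.0, 110.0, 105.0]), [10.0, -5.0])
    np.testing.assert_array_equal(diff_seq(np.full(10, 7.0)), np.zeros(9))


# ------------------------------------------------------------- hand examples

def test_mae_hand_values():
    assert mae_seq([SequencePair([100, 110, 105], [102, 108, 105])]) == \
        pytest.approx(4.0 / 3.0)
    pairs = random_pairs(10, seed=1)
    exact = [SequencePair(p.gt, p.gt.copy()) for p in pairs]
    assert mae_seq(exact) == 0.0
    shifted = [SequencePair(p.gt, p.gt + 3.0) for p in pairs]
    assert mae_seq(shifted) == pytest.approx(3.0)


def test_rseq_hand_values():
    pairs = random_pairs(5, seed=2)
    affine = [SequencePair(p.gt, 2.0 * p.gt + 3.0) for p in pairs]
    assert rseq(affine) == pytest.approx(1.0)
    neg = [SequencePair(p.gt, -p.gt) for p in pairs]
    assert rseq(neg) == pytest.approx(-1.0)
    up = np.arange(10.0)
    both = [SequencePair(up, up * 2), SequencePair(up, -up)]
    assert rseq(both) == pytest.approx(0.0)


def test_rseq_excludes_zero_variance():
    flat = SequencePair(np.full(10, 120.0), np.arange(10.0))
    ok = SequencePair(np.arange(10.0), np.arange(10.0))
    assert rseq([flat, ok]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        rseq([flat])


def test_ve_hand_values():
    assert ve([SequencePair([100, 110, 105], [100, 105, 110])]) == \
        pytest.approx(7.5)
    pairs = random_pairs(5, seed=3)
    assert ve([SequencePair(p.gt, p.gt + 7.0) for p in pairs]) == \
        pytest.approx(0.0)
    assert ve([SequencePair(p.gt, p.gt.copy()) for p in pairs]) == 0.0


def test_me_sd_hand_values():
    p = random_pairs(1, seed=4)[0]
    assert me_sd([SequencePair(p.gt, p.gt + 3.0)]) == (pytest.approx(3.0),
                                                       pytest.approx(0.0))
    errs = SequencePair(np.zeros(2), np.array([-1.0, 1.0]))
    assert me_sd([errs]) == (pytest.approx(0.0), pytest.approx(1.0))


# ---------------------------------------------------------------- invariances

@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(-50, 50))
def test_ve_level_shift_invariance(seed, c):
    pairs = random_pairs(3, seed=seed)
    shifted = [SequencePair(p.gt, p.pred + c) for p in pairs]
    assert ve(shifted) == pytest.approx(ve(pairs), abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10), st.floats(-50, 50))
def test_rseq_positive_affine_invariance(seed, a, b):
    pairs = random_pairs(3, seed=seed)
    scaled = [SequencePair(p.gt, a * p.pred + b) for p in pairs]
    assert rseq(scaled) == pytest.approx(rseq(pairs), abs=1e-9)


def test_mae_not_shift_invariant():
    pairs = random_pairs(3, seed=8)
    assert mae_seq([SequencePair(p.gt, p.pred + 10) for p in pairs]) != \
        pytest.approx(mae_seq(pairs))


def test_mae_equals_l1_loss_on_stacked_batch():
    pairs = random_pairs(16, seed=9)
    gt = np.stack([p.gt for p in pairs])
    pred = np.stack([p.pred for p in pairs])
    assert mae_seq(pairs) == pytest.approx(loss_l1(Tensor(pred), gt).data,
                                           abs=1e-12)


# ------------------------------------------------------------- classification

@pytest.mark.parametrize("span,expected", [(12.0, "unsteady"), (8.0, "steady"),
                                           (10.0, "steady")])
def test_classify_state_boundary(span, expected):
    seq = np.full(60, 110.0)
    seq[0] -= span / 2
    seq[1] += span / 2
    assert classify_state(seq) == expected


def test_classification_report_hand_counts():
    gt = ["unsteady"] * 10 + ["steady"] * 10
    pred = ["unsteady"] * 8 + ["steady"] * 2 + ["unsteady"] * 2 + ["steady"] * 8
    rep = classification_report(gt, pred)
    assert (rep["tp"], rep["fp"], rep["fn"], rep["tn"]) == (8, 2, 2, 8)
    for k in ("acc", "precision", "recall", "f1"):
        assert rep[k] == pytest.approx(0.8)
    assert rep["tp"] + rep["fp"] + rep["fn"] + rep["tn"] == len(gt)


def test_classification_report_degenerate():
    rep = classification_report(["unsteady", "steady"], ["steady", "steady"])
    assert rep["recall"] == 0.0 and rep["f1"] == 0.0
    perfect = classification_report(["unsteady", "steady"],
                                    ["unsteady", "steady"])
    assert perfect["acc"] == 1.0 and perfect["f1"] == 1.0


def test_classification_matches_sklearn():
    sklearn = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(17)
    gt = rng.choice(["steady", "unsteady"], size=200)
    pred = rng.choice(["steady", "unsteady"], size=200)
    rep = classification_report(gt, pred)
    assert rep["acc"] == pytest.approx(sklearn.accuracy_score(gt, pred))
    assert rep["f1"] == pytest.approx(
        sklearn.f1_score(gt, pred, pos_label="unsteady"))
    assert rep["precision"] == pytest.approx(
        sklearn.precision_score(gt, pred, pos_label="unsteady"))
    assert rep["recall"] == pytest.approx(
        sklearn.recall_score(gt, pred, pos_label="unsteady"))


# ---------------------------------------------------------------- aggregation

def test_beat_averaged_shapes_and_values():
    pairs = random_pairs(3, seed=10)
    ba = beat_averaged(pairs, window=10)
    assert all(len(p.gt) == 6 for p in ba)
    const = SequencePair(np.full(60, 111.0), np.full(60, 111.0))
    bc = beat_averaged([const])[0]
    np.testing.assert_allclose(bc.gt, 111.0)
    alt = np.tile([100.0, 110.0], 30)
    np.testing.assert_allclose(beat_averaged([SequencePair(alt, alt)])[0].gt,
                               105.0)
    # brute-force oracle
    p = pairs[0]
    oracle = [sum(p.gt[i * 10 : (i + 1) * 10]) / 10 for i in range(6)]
    np.testing.assert_allclose(ba[0].gt, oracle, atol=1e-12)


# ------------------------------------------------------------------ standards

@pytest.mark.parametrize("me,sd,n,ok", [
    (-0.238, 5.120, 238, True),   # printed validation row
    (5.1, 4.0, 100, False),       # ME bound violated
    (0.0, 0.0, 84, False),        # subject floor
    (5.0, 8.0, 85, True),         # inclusive boundaries
    (0.0, 8.1, 238, False),
])
def test_aami_check(me, sd, n, ok):
    assert aami_check(me, sd, n)["pass"] is ok


def _errors_with_pcts(p5, p10, p15, total=10000):
    n5 = round(p5 / 100 * total)
    n10 = round(p10 / 100 * total) - n5
    n15 = round(p15 / 100 * total) - n5 - n10
    rest = total - n5 - n10 - n15
    return np.concatenate([np.zeros(n5), np.full(n10, 7.0),
                           np.full(n15, 12.0), np.full(rest, 20.0)])


@pytest.mark.parametrize("pcts,grade", [
    ((82.88, 94.39, 97.43), "A"),   # printed result row
    ((60.0, 85.0, 95.0), "A"),      # inclusive grade-A boundary
    ((45.0, 70.0, 88.0), "C"),      # fails B's middle threshold
    ((50.0, 75.0, 90.0), "B"),
    ((39.0, 90.0, 99.0), "D"),      # all three thresholds required
])
def test_bhs_grade(pcts, grade):
    res = bhs_grade(_errors_with_pcts(*pcts))
    assert res["grade"] == grade
    assert (res["pct5"], res["pct10"], res["pct15"]) == \
        (pytest.approx(pcts[0]), pytest.approx(pcts[1]),
         pytest.approx(pcts[2]))


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_bhs_percentages_monotone(seed):
    rng = np.random.default_rng(seed)
    res = bhs_grade(rng.normal(0, 8, size=500))
    assert res["pct5"] <= res["pct10"] <= res["pct15"]


# --------------------------------------------------------------- bland-altman

def test_bland_altman_exact_prediction():
    p = random_pairs(1, seed=11)[0]
    res = bland_altman([SequencePair(p.gt, p.gt.copy())])
    assert res["mean_diff"] == 0.0
    assert res["loa_low"] == res["loa_high"] == 0.0
    assert res["pct_within"] == 100.0


def test_bland_altman_alternating_errors():
    gt = np.zeros(100)
    pred = np.tile([-1.0, 1.0], 50)
    res = bland_altman([SequencePair(gt, pred)])
    assert res["mean_diff"] == pytest.approx(0.0)
    assert res["loa_low"] == pytest.approx(-1.96)
    assert res["loa_high"] == pytest.approx(1.96)


def test_bland_altman_gaussian_95pct():
    rng = np.random.default_rng(12)
    gt = np.zeros(100000)
    res = bland_altman([SequencePair(gt, rng.normal(size=gt.size))])
    assert res["pct_within"] == pytest.approx(95.0, abs=1.0)


# --------------------------------------------------------------------- report

def test_evaluation_report_complete(tmp_path):
    pairs = random_pairs(40, seed=13)
    rep = evaluate_pairs(pairs, n_subjects=10)
    assert rep.n_sequences == 40
    assert 0 <= rep.class_table["acc"] <= 1
    assert rep.bhs["pct5"] <= rep.bhs["pct10"] <= rep.bhs["pct15"]
    js = rep.to_json(tmp_path / "rep.json")
    import json

    parsed = json.loads(js)
    for key in ("mae", "rseq", "ve", "me", "sd", "beat_avg", "class_table",
                "bhs", "aami", "bland_altman"):
        assert key in parsed
    assert "MAE" in rep.summary()
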