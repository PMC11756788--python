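"""Integrated Gradients, hot spots, motif scanning, enrichment, and the
logistic-weight target ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from irdhs import (
    BassetClassifier,
    InterpretConfig,
    enrichment_scores,
    extract_hot_spots,
    integrated_gradients,
    interpret_sequences,
    one_hot,
    one_hot_batch,
    rank_lr_targets,
    scan_motif,
    select_confident,
    top_bottom_intersection,
)
from irdhs.interpretation import (
    completeness_error,
    hotspot_motif_matches,
    permutation_pvalues,
)
from irdhs.motifs import PWM


class LinearModel:
    """f(x) = sum(w * x) + b — closed-form reference for IG."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = b

    def value_and_input_grad(self, X):
        X = np.asarray(X, dtype=float)
        vals = (X * self.w).sum(axis=(1, 2)) + self.b
        grads = np.broadcast_to(self.w, X.shape).copy()
        return vals, grads


# ---------------------------------------------------------------------------
# integrated gradients


def test_ig_zero_when_input_equals_baseline():
    rng = np.random.default_rng(0)
    model = LinearModel(rng.normal(size=(4, 30)))
    x = rng.random((4, 30))
    attr = integrated_gradients(model, x, baseline=x, steps=16)
    assert np.allclose(attr.values, 0.0)


@pytest.mark.parametrize("steps", [1, 7, 50])
def test_ig_linear_model_closed_form(steps):
    """For f(x) = w.x + b the attribution is exactly w * (x - baseline),
    independent of the step count."""
    rng = np.random.default_rng(1)
    model = LinearModel(rng.normal(size=(4, 25)), b=0.3)
    x = one_hot("".join(rng.choice(list("ACGT"), 25)))
    baseline = np.zeros_like(x)
    attr = integrated_gradients(model, x, baseline, steps=steps)
    assert np.allclose(attr.values, model.w * (x - baseline), atol=1e-12)


@pytest.fixture(scope="module")
def trained_cnn(small_motif_data):
    seqs, labels, _ = small_motif_data
    X = one_hot_batch(seqs)
    clf = BassetClassifier(
        conv_channels=(32, 16), conv_kernels=(12, 5), pool_sizes=(2, -1),
        dense_units=(16,), max_epochs=12, patience=12, batch_size=32, seed=0,
    )
    clf.fit(X, labels)
    return clf, X, labels


def test_ig_completeness_error_shrinks_with_steps(trained_cnn):
    """|sum(IG) - (f(x) - f(baseline))| decreases from 10 to 200 steps on a
    trained two-conv CNN."""
    clf, X, _ = trained_cnn
    x = X[0]
    errs = {s: completeness_error(clf, x, steps=s) for s in (10, 50, 200)}
    assert errs[200] < errs[10]
    f_x, _ = clf.value_and_input_grad(x[None])
    f_0, _ = clf.value_and_input_grad(np.zeros_like(x)[None])
    gap = abs(f_x[0] - f_0[0])
    assert errs[200] < 0.01 * gap


def test_ig_records_model_probability(trained_cnn):
    clf, X, _ = trained_cnn
    attr = integrated_gradients(clf, X[3], steps=8, seq_id=3)
    assert attr.model_prob == pytest.approx(clf.predict_proba(X[3:4])[0, 1])
    assert attr.values.shape == X[3].shape


# ---------------------------------------------------------------------------
# confident-sequence selection


class StubModel:
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.probs, self.probs])


def test_select_confident_is_symmetric_in_true_class():
    probs = [0.71, 0.69, 0.20, 0.31, 0.95]
    y = np.array([1, 1, 0, 0, 0])
    mask, counts = select_confident(StubModel(probs), np.zeros((5, 4, 1)), y, 0.7)
    # IR kept iff p > 0.7; non-IR kept iff 1 - p > 0.7
    assert mask.tolist() == [True, False, True, False, False]
    assert counts == {"IR": 1, "nonIR": 1}


def test_select_confident_keeps_all_for_perfect_model():
    y = np.array([1, 0, 1])
    mask, _ = select_confident(StubModel([0.99, 0.01, 0.98]), None, y, 0.7)
    assert mask.all()


# ---------------------------------------------------------------------------
# hot spots


def _attr_from_scalars(scalars):
    """Build (attr, onehot) whose observed-base scalars equal `scalars`."""
    n = len(scalars)
    onehot = one_hot("A" * n)
    attr = np.zeros((4, n))
    attr[0] = scalars
    return attr, onehot


def test_hot_spots_fractional_threshold_rule():
    attr, onehot = _attr_from_scalars([1.0, 0.5, 0.8])
    assert extract_hot_spots(attr, onehot, frac=0.7).tolist() == [0, 2]


def test_hot_spots_all_equal_positive_scalars():
    attr, onehot = _attr_from_scalars([0.4, 0.4, 0.4, 0.4])
    assert extract_hot_spots(attr, onehot, frac=0.7).tolist() == [0, 1, 2, 3]


def test_hot_spots_nonpositive_scalars_follow_rule_as_written():
    """With signed attributions and max <= 0, frac * max >= max, so the
    strict inequality never holds: enumerate small cases."""
    for scalars in itertools.product([-1.0, -0.5, 0.0], repeat=3):
        attr, onehot = _attr_from_scalars(list(scalars))
        got = set(extract_hot_spots(attr, onehot, frac=0.7).tolist())
        m = max(scalars)
        expected = {i for i, s in enumerate(scalars) if s > 0.7 * m}
        assert got == expected


def test_hot_spots_absolute_mode():
    attr, onehot = _attr_from_scalars([-1.0, 0.2, 0.8])
    assert extract_hot_spots(attr, onehot, frac=0.7, use_abs=True).tolist() == [0, 2]


def test_hot_spots_all_n_sequence_empty():
    onehot = one_hot("NNNN")
    attr = np.ones((4, 4))
    assert extract_hot_spots(attr, onehot, frac=0.7).size == 0


def test_hot_spots_invariant_to_positive_rescaling():
    rng = np.random.default_rng(2)
    onehot = one_hot("".join(rng.choice(list("ACGT"), 50)))
    attr = rng.normal(size=(4, 50))
    a = extract_hot_spots(attr, onehot, 0.7)
    b = extract_hot_spots(37.5 * attr, onehot, 0.7)
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# motif scanning


@pytest.fixture
def dinuc_pwm():
    counts = np.array([[80, 4], [8, 80], [8, 8], [4, 8]], dtype=float)  # ~"AC"
    return PWM.from_counts(counts, id="DI", name="di")


def test_scan_consensus_matches_at_any_fraction(dinuc_pwm):
    seq = "GG" + dinuc_pwm.consensus + "GG"
    assert scan_motif(seq, 2, dinuc_pwm, score_frac=1.0)
    assert scan_motif(seq, 3, dinuc_pwm, score_frac=1.0)


def test_scan_matches_exhaustive_dinucleotide_oracle(dinuc_pwm):
    """All 16 dinucleotides: matched set equals brute-force log-odds
    enumeration over both strands."""
    cutoff = 0.8 * dinuc_pwm.max_score
    rc = dinuc_pwm.reverse_complement()
    for a, b in itertools.product("ACGT", repeat=2):
        window = a + b
        oracle = (
            dinuc_pwm.log_odds_score(window) >= cutoff
            or rc.log_odds_score(window) >= cutoff
        )
        # embed so the only windows covering the centre are within bounds
        assert scan_motif("T" + window + "T", 1, dinuc_pwm, 0.8) or not oracle
        isolated = scan_motif(window, 0, dinuc_pwm, 0.8) or scan_motif(
            window, 1, dinuc_pwm, 0.8
        )
        assert isolated == oracle


def test_scan_reverse_complement_strand_symmetry(causal_pwm):
    inst = causal_pwm.consensus
    from irdhs import revcomp

    seq_fwd = "TT" + inst + "TT"
    seq_rev = "TT" + revcomp(inst) + "TT"
    assert scan_motif(seq_fwd, 5, causal_pwm, 0.95)
    assert scan_motif(seq_rev, 5, causal_pwm, 0.95)


def test_scan_out_of_bounds_windows_skipped(dinuc_pwm):
    # centre at position 0 of a length-1 sequence: the only window overruns
    assert not scan_motif("A", 0, dinuc_pwm, 0.1)
    with pytest.raises(ValueError):
        scan_motif("ACGT", 9, dinuc_pwm, 0.5)


def test_vectorised_matcher_equals_scalar_scan(pwm_library):
    rng = np.random.default_rng(3)
    seqs = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(6)]
    hotspots = pd.DataFrame(
        {
            "seq_id": rng.integers(0, 6, 40),
            "position": rng.integers(0, 80, 40),
        }
    )
    matches = hotspot_motif_matches(hotspots, seqs, pwm_library[:4], 0.8)
    for h, (sid, pos) in enumerate(zip(hotspots.seq_id, hotspots.position)):
        for m, pwm in enumerate(pwm_library[:4]):
            assert matches[h, m] == scan_motif(seqs[sid], int(pos), pwm, 0.8)


# ---------------------------------------------------------------------------
# enrichment


def test_enrichment_score_arithmetic(pwm_library):
    pwms = pwm_library[:1]
    matches = np.zeros((30, 1), dtype=bool)
    classes = np.array(["IR"] * 10 + ["nonIR"] * 20)
    matches[:3, 0] = True          # 3/10 IR hot spots matched
    matches[10, 0] = True          # 1/20 non-IR matched
    table = enrichment_scores(matches, classes, pwms)
    assert table.loc[0, "score"] == pytest.approx(0.30 - 0.05)


def test_enrichment_zero_when_motif_matches_everything(pwm_library):
    matches = np.ones((12, 1), dtype=bool)
    classes = np.array(["IR"] * 5 + ["nonIR"] * 7)
    table = enrichment_scores(matches, classes, pwm_library[:1])
    assert table.loc[0, "score"] == 0.0


def test_enrichment_sorted_with_motif_id_tiebreak(pwm_library):
    matches = np.zeros((10, 3), dtype=bool)
    classes = np.array(["IR"] * 5 + ["nonIR"] * 5)
    table = enrichment_scores(matches, classes, pwm_library[:3])
    assert list(table.motif_id) == sorted(p.id for p in pwm_library[:3])
    assert list(table["rank"]) == [1, 2, 3]


def test_enrichment_requires_both_classes(pwm_library):
    with pytest.raises(ValueError, match="both classes"):
        enrichment_scores(
            np.zeros((4, 1), dtype=bool), np.array(["IR"] * 4), pwm_library[:1]
        )


def test_permutation_null_centred_at_zero():
    rng = np.random.default_rng(4)
    matches = rng.random((200, 3)) < 0.3
    classes = np.array(["IR"] * 80 + ["nonIR"] * 120)
    perm = classes.copy()
    null_means = []
    for _ in range(500):
        rng.shuffle(perm)
        ir = perm == "IR"
        null_means.append(matches[ir].mean(axis=0) - matches[~ir].mean(axis=0))
    assert np.abs(np.mean(null_means, axis=0)).max() < 0.01


def test_permutation_pvalue_detects_planted_signal():
    rng = np.random.default_rng(5)
    classes = np.array(["IR"] * 100 + ["nonIR"] * 100)
    matches = np.zeros((200, 2), dtype=bool)
    matches[:100, 0] = rng.random(100) < 0.6   # enriched in IR
    matches[100:, 0] = rng.random(100) < 0.1
    matches[:, 1] = rng.random(200) < 0.3      # uninformative
    p = permutation_pvalues(matches, classes, n_perm=500, seed=0)
    assert p[0] < 0.01 < p[1]


# ---------------------------------------------------------------------------
# end-to-end recovery on a small fixture


def test_pipeline_recovers_planted_motif(trained_cnn, pwm_library, causal_pwm):
    """Confidence filter -> IG -> hot spots -> scan -> enrichment ranks the
    planted motif first among 11 candidates on a small separable set."""
    clf, X, y = trained_cnn
    enrichment, hotspots = interpret_sequences(
        clf, X, y, pwm_library, InterpretConfig(ig_steps=16),
        max_per_class=60, seed=0,
    )
    assert not hotspots.empty
    assert enrichment.loc[0, "motif_id"] == causal_pwm.id
    assert enrichment.loc[0, "score"] > 0.2


# ---------------------------------------------------------------------------
# LR target ranking


def test_rank_lr_targets_orders_by_signed_weight():
    meta = pd.DataFrame(
        {
            "name": ["a", "b", "c", "d"],
            "protein": ["P1", "P1", "P2", "P3"],
            "group": ["TF", "TF", "HM", "ACC"],
        }
    )
    table = rank_lr_targets(np.array([0.5, -2.0, 3.0, 0.0]), meta)
    assert list(table.target) == ["c", "a", "d", "b"]
    assert list(table["rank"]) == [1, 2, 3, 4]


def test_rank_protein_can_occupy_multiple_ranks():
    meta = pd.DataFrame(
        {
            "name": ["x1", "x2"],
            "protein": ["SAME", "SAME"],
            "group": ["TF", "TF"],
        }
    )
    table = rank_lr_targets(np.array([1.0, -1.0]), meta)
    assert (table.protein == "SAME").all() and len(table) == 2


def test_rank_zero_weights_flagged():
    meta = pd.DataFrame(
        {"name": ["a"], "protein": ["p"], "group": ["TF"]}
    )
    with pytest.warns(UserWarning, match="degenerate"):
        rank_lr_targets(np.zeros(1), meta)


def test_rank_width_mismatch_rejected():
    meta = pd.DataFrame({"name": ["a"], "protein": ["p"], "group": ["TF"]})
    with pytest.raises(ValueError):
        rank_lr_targets(np.zeros(3), meta)


def test_top_bottom_intersection_reports_shared_proteins():
    meta = pd.DataFrame(
        {
            "name": [f"t{i}" for i in range(6)],
            "protein": ["A", "B", "C", "A", "D", "E"],
            "group": ["TF"] * 6,
        }
    )
    # protein A has both the largest and the smallest weight
    table = rank_lr_targets(np.array([5.0, 2.0, 1.0, -4.0, -1.0, 0.0]), meta)
    assert top_bottom_intersection(table, k=2) == ["A"]
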