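"""Dataset construction: overlap labeling, RNA-seq relabeling, augmentation,
one-hot encoding, redundancy clustering, and cluster-aware splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irdhs import (
    DatasetSummary,
    GenomicInterval,
    LabeledDHS,
    SplitConfig,
    augment_reverse_complement,
    label_dhs,
    one_hot,
    reduce_redundancy,
    relabel_with_rnaseq,
    revcomp,
    sequence_identity,
    split_dataset,
)

dna = st.text(alphabet="ACGTN", min_size=1, max_size=60)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def make_dhs(start, label, source="annotation", length=600):
    return LabeledDHS(iv(start, start + length), "A" * length, label, source)


# ---------------------------------------------------------------------------
# labeling


@pytest.mark.parametrize(
    "dhs, retained, min_overlap, expected",
    [
        (iv(1000, 1600), [iv(900, 2000)], 500, "IR"),      # overlap 600
        (iv(0, 600), [iv(600, 1200)], 1, "nonIR"),          # touching, half-open
        (iv(0, 600), [iv(101, 700)], 500, "nonIR"),         # overlap 499
        (iv(0, 600), [iv(100, 700)], 500, "IR"),            # overlap 500
        (iv(0, 600), [], 1, "nonIR"),                       # no introns
        (iv(0, 600), [iv(599, 700)], 1, "IR"),              # 1 bp suffices
    ],
)
def test_label_dhs_overlap_rule(dhs, retained, min_overlap, expected):
    assert label_dhs(dhs, retained, min_overlap) == expected


def test_overlap_matches_brute_force_position_count():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a0, b0 = sorted(rng.integers(0, 50, 2).tolist())
        c0, d0 = sorted(rng.integers(0, 50, 2).tolist())
        if a0 == b0 or c0 == d0:
            continue
        shared = len(set(range(a0, b0)) & set(range(c0, d0)))
        assert iv(a0, b0).overlap(iv(c0, d0)) == shared


def test_labeling_is_idempotent_and_order_independent():
    retained = [iv(0, 1000), iv(5000, 9000)]
    d = iv(800, 1400)
    assert label_dhs(d, retained, 200) == label_dhs(d, retained[::-1], 200) == "IR"


def test_malformed_interval_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)


# ---------------------------------------------------------------------------
# RNA-seq relabeling


def test_relabel_flips_qualifying_negatives_only():
    data = [make_dhs(0, "nonIR"), make_dhs(10_000, "nonIR"), make_dhs(20_000, "IR")]
    rnaseq = [iv(0, 550)]  # overlaps first DHS by 550
    out, summary = relabel_with_rnaseq(data, rnaseq)
    assert [s.label for s in out] == ["IR", "nonIR", "IR"]
    assert out[0].source == "rnaseq_relabel"
    assert (summary.relabeled, summary.rnaseq_new) == (1, 0)
    assert summary.total_ir == 2 and summary.total_nonir == 1


def test_relabel_boundary_at_499_not_500():
    data = [make_dhs(0, "nonIR")]
    out499, s499 = relabel_with_rnaseq(data, [iv(101, 700)])  # overlap 499
    out500, s500 = relabel_with_rnaseq(data, [iv(100, 700)])  # overlap 500
    assert out499[0].label == "nonIR" and s499.relabeled == 0
    assert out500[0].label == "IR" and s500.relabeled == 1


def test_relabel_empty_rnaseq_is_identity():
    data = [make_dhs(0, "nonIR"), make_dhs(10_000, "IR")]
    out, summary = relabel_with_rnaseq(data, [])
    assert [s.label for s in out] == ["nonIR", "IR"]
    assert (summary.relabeled, summary.rnaseq_new) == (0, 0)


def test_relabel_appends_new_dhs_passing_rule():
    data = [make_dhs(0, "nonIR")]
    new = [make_dhs(30_000, "nonIR"), make_dhs(50_000, "nonIR")]
    rnaseq = [iv(30_000, 30_600)]
    out, summary = relabel_with_rnaseq(data, rnaseq, new_dhs=new)
    assert len(out) == 2
    assert out[-1].source == "rnaseq_new" and out[-1].label == "IR"
    assert summary.rnaseq_new == 1


def test_relabel_rejects_duplicate_intervals():
    data = [make_dhs(0, "nonIR")]
    with pytest.raises(ValueError, match="duplicate"):
        relabel_with_rnaseq(data, [], new_dhs=[make_dhs(0, "nonIR")])


def test_relabel_never_flips_ir_to_nonir():
    data = [make_dhs(0, "IR"), make_dhs(10_000, "nonIR")]
    out, summary = relabel_with_rnaseq(data, [iv(40_000, 41_000)])
    assert sum(s.label == "IR" for s in out) >= 1
    assert summary.total_ir >= 1


# ---------------------------------------------------------------------------
# reverse complement and augmentation


@pytest.mark.parametrize("seq, expected", [("AACG", "CGTT"), ("ACGT", "ACGT"),
                                           ("ANT", "ANT"), ("A", "T")])
def test_revcomp_examples(seq, expected):
    assert revcomp(seq) == expected


@settings(max_examples=60, deadline=None, derandomize=True)
@given(dna)
def test_revcomp_is_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_revcomp_rejects_non_dna():
    with pytest.raises(ValueError):
        revcomp("ACGU")


def test_augment_doubles_and_preserves_label_counts():
    samples = [
        LabeledDHS(iv(0, 4), "AACG", "IR"),
        LabeledDHS(iv(10, 14), "TTTT", "nonIR"),
        LabeledDHS(iv(20, 24), "ACGT", "nonIR"),
    ]
    out = augment_reverse_complement(samples)
    assert len(out) == 6
    labels = [s.label for s in out]
    assert labels.count("IR") == 2 and labels.count("nonIR") == 4
    # original block first, complements after
    assert out[3].seq == "CGTT" and out[0].seq == "AACG"
    assert augment_reverse_complement([]) == []


def test_table_arithmetic_holds_on_any_dataset():
    """Totals: annotation events + RNA-seq additions; relabels conserve the
    total; augmentation doubles everything."""
    s = DatasetSummary(annotation_ir=7, annotation_nonir=20, relabeled=2, rnaseq_new=4)
    assert s.total_ir == 13 and s.total_nonir == 18
    assert s.total == 7 + 20 + 4
    assert s.augmented_total == 2 * s.total
    assert s.rnaseq_ir_events == 6


# ---------------------------------------------------------------------------
# one-hot


def test_one_hot_single_bases():
    assert one_hot("A")[:, 0].tolist() == [1, 0, 0, 0]
    assert one_hot("T")[:, 0].tolist() == [0, 0, 0, 1]


def test_one_hot_shape_and_n_column():
    mat = one_hot("ACGN")
    assert mat.shape == (4, 4)
    assert mat.sum(axis=0).tolist() == [1, 1, 1, 0]
    assert one_hot("A" * 600).shape == (4, 600)


def test_one_hot_rejects_unknown_characters():
    with pytest.raises(ValueError):
        one_hot("ACGX")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(dna)
def test_one_hot_revcomp_is_double_flip(seq):
    """one_hot(revcomp(s)) equals one_hot(s) flipped on both axes."""
    assert np.array_equal(one_hot(revcomp(seq)), one_hot(seq)[::-1, ::-1])


# ---------------------------------------------------------------------------
# redundancy clustering


def test_identical_sequences_form_one_cluster():
    assert reduce_redundancy(["ACGTACGT", "ACGTACGT"]).tolist() == [0, 0]


def test_identity_threshold_boundary():
    seqs = ["AAAAAAAAAA", "AAAAAAAATT"]  # 8/10 identity
    assert sequence_identity(*seqs) == pytest.approx(0.8)
    assert len(set(reduce_redundancy(seqs, 0.80))) == 1
    assert len(set(reduce_redundancy(seqs, 0.81))) == 2


def test_identity_considers_offsets_and_strands():
    # contained substring: identity 1 at the right offset
    assert sequence_identity("ACGTT", "GGACGTTGG") == 1.0
    # reverse complement match
    assert sequence_identity("ACGTT", revcomp("ACGTT")) == 1.0


def _greedy_oracle(seqs, threshold):
    """Independent O(n^2) greedy clustering oracle (plain string ops)."""

    def ident(a, b):
        short, long_ = (a, b) if len(a) <= len(b) else (b, a)
        best = 0
        rc = revcomp(short)
        for cand in (short, rc):
            for off in range(len(long_) - len(cand) + 1):
                m = sum(x == y for x, y in zip(cand, long_[off : off + len(cand)]))
                best = max(best, m)
        return best / len(short)

    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
    reps, assign = [], {}
    for i in order:
        for cid, rep in enumerate(reps):
            if ident(seqs[i], rep) >= threshold:
                assign[i] = cid
                break
        else:
            assign[i] = len(reps)
            reps.append(seqs[i])
    return [assign[i] for i in range(len(seqs))]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_clustering_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(8)]
    assert reduce_redundancy(seqs, 0.6).tolist() == _greedy_oracle(seqs, 0.6)


def test_clustering_empty_input():
    assert reduce_redundancy([]).size == 0


# ---------------------------------------------------------------------------
# splitting


def test_split_singleton_clusters_hit_exact_fractions():
    samples = list(range(10))
    clusters = np.arange(10)
    parts = split_dataset(samples, clusters, SplitConfig(seed=4))
    assert (len(parts["train"]), len(parts["val"]), len(parts["test"])) == (8, 1, 1)
    assert sorted(parts["train"] + parts["val"] + parts["test"]) == samples


def test_split_indivisible_cluster_stays_whole():
    samples = list(range(12))
    clusters = np.zeros(12, dtype=int)
    parts = split_dataset(samples, clusters, SplitConfig(seed=0))
    sizes = sorted(len(v) for v in parts.values())
    assert sizes == [0, 0, 12]


def test_split_partitions_are_disjoint_and_cover():
    rng = np.random.default_rng(2)
    clusters = rng.integers(0, 12, 40)
    parts = split_dataset(list(range(40)), clusters, SplitConfig(seed=9))
    everything = parts["train"] + parts["val"] + parts["test"]
    assert sorted(everything) == list(range(40))
    for name, idxs in parts.items():
        cl = set(clusters[idxs].tolist())
        for other, odx in parts.items():
            if other != name:
                assert cl.isdisjoint(set(clusters[odx].tolist()))


def test_split_cross_partition_identity_below_threshold():
    """No test sequence is >= 80% identical to any train/val sequence,
    verified by brute force."""
    rng = np.random.default_rng(5)
    base = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(12)]
    seqs = []
    for b in base:
        seqs.append(b)
        mutated = list(b)
        j = int(rng.integers(0, 30))
        mutated[j] = "ACGT"[(("ACGT".index(mutated[j])) + 1) % 4]
        seqs.append("".join(mutated))  # ~97% identical partner
    cfg = SplitConfig(seed=1)
    clusters = reduce_redundancy(seqs, cfg.redundancy_threshold)
    parts = split_dataset(seqs, clusters, cfg)
    for t in parts["test"]:
        for other in parts["train"] + parts["val"]:
            assert sequence_identity(seqs[t], seqs[other]) < cfg.redundancy_threshold


def test_split_config_validates_fractions():
    with pytest.raises(ValueError):
        SplitConfig(fractions=(0.5, 0.3, 0.1))
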