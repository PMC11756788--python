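"""Dataset construction for intron-retention prediction from DHS sequences.

DNase hypersensitive sites (DHSs, fixed-length 600 bp windows of open
chromatin) are labeled IR when they overlap a retained intron, non-IR
otherwise.  A second, RNA-seq-derived set of retained introns can relabel
negatives and contribute new positives when the overlap reaches 500 bp.
Redundancy between data splits is controlled by greedy sequence clustering
at 80% ungapped identity, whole clusters are assigned to one split, and the
dataset is doubled by reverse-complement augmentation.

Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

IR = "IR"
NONIR = "nonIR"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALPHABET = set("ACGTN")

BASE_ORDER = "ACGT"
_ONEHOT_ROW = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Shared positions between two half-open intervals (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class LabeledDHS:
    """One sample: a DHS interval, its sequence, IR label, and provenance."""

    interval: GenomicInterval
    seq: str
    label: str
    source: str = "annotation"

    def __post_init__(self) -> None:
        if self.label not in (IR, NONIR):
            raise ValueError(f"label must be {IR!r} or {NONIR!r}")
        if self.source not in ("annotation", "rnaseq_relabel", "rnaseq_new"):
            raise ValueError(f"unknown source {self.source!r}")
        if len(self.seq) != self.interval.length:
            raise ValueError("sequence length must equal interval length")
        bad = set(self.seq.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"sequence contains non-DNA characters {bad}")


@dataclass
class SplitConfig:
    fractions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    seed: int = 0
    redundancy_threshold: float = 0.80
    min_rnaseq_overlap: int = 500

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0 < self.redundancy_threshold <= 1):
            raise ValueError("redundancy_threshold must be in (0, 1]")


@dataclass
class DatasetSummary:
    """Event bookkeeping: per-(source, label) counts and augmentation totals.

    ``relabeled`` negatives move from non-IR to IR without changing the
    event total; ``rnaseq_new`` events add to it.  Reverse-complement
    augmentation doubles every count.
    """

    annotation_ir: int = 0
    annotation_nonir: int = 0
    relabeled: int = 0
    rnaseq_new: int = 0
    augmented: bool = False

    @property
    def total_ir(self) -> int:
        return self.annotation_ir + self.relabeled + self.rnaseq_new

    @property
    def total_nonir(self) -> int:
        return self.annotation_nonir - self.relabeled

    @property
    def rnaseq_ir_events(self) -> int:
        """IR gained from RNA-seq: relabeled negatives plus new DHSs."""
        return self.relabeled + self.rnaseq_new

    @property
    def total(self) -> int:
        return self.total_ir + self.total_nonir

    @property
    def augmented_ir(self) -> int:
        return 2 * self.total_ir

    @property
    def augmented_nonir(self) -> int:
        return 2 * self.total_nonir

    @property
    def augmented_total(self) -> int:
        return self.augmented_ir + self.augmented_nonir

    @classmethod
    def from_samples(cls, samples: Sequence[LabeledDHS]) -> "DatasetSummary":
        ann_ir = sum(1 for s in samples if s.source == "annotation" and s.label == IR)
        ann_non = sum(
            1 for s in samples if s.source == "annotation" and s.label == NONIR
        )
        relab = sum(1 for s in samples if s.source == "rnaseq_relabel")
        new = sum(1 for s in samples if s.source == "rnaseq_new")
        # relabeled samples started life as annotation negatives
        return cls(
            annotation_ir=ann_ir,
            annotation_nonir=ann_non + relab,
            relabeled=relab,
            rnaseq_new=new,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "IR": [self.annotation_ir, self.rnaseq_ir_events, self.total_ir,
                       self.augmented_ir],
                "nonIR": [self.annotation_nonir, -self.relabeled, self.total_nonir,
                          self.augmented_nonir],
            },
            index=["annotation_events", "rnaseq_events", "total_events",
                   "after_reverse_complement"],
        )


# ---------------------------------------------------------------------------
# labeling


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    return a.overlap(b)


def label_dhs(
    dhs: GenomicInterval,
    retained: Iterable[GenomicInterval],
    min_overlap: int = 1,
) -> str:
    """IR iff the best overlap with any retained intron is >= min_overlap.

    The annotation phase uses min_overlap=1 (any overlap); the RNA-seq phase
    uses 500 bp.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    best = max((dhs.overlap(r) for r in retained), default=0)
    return IR if best >= min_overlap else NONIR


def relabel_with_rnaseq(
    dataset: Sequence[LabeledDHS],
    rnaseq_retained: Sequence[GenomicInterval],
    new_dhs: Sequence[LabeledDHS] = (),
    min_overlap: int = 500,
) -> tuple[list[LabeledDHS], DatasetSummary]:
    """Apply RNA-seq-derived retained introns to an annotation-labeled set.

    Negatives overlapping an RNA-seq retained intron by >= min_overlap flip
    to IR (source ``rnaseq_relabel``); candidate new DHSs passing the same
    rule are appended (source ``rnaseq_new``).  IR labels never flip back.
    """
    existing = {s.interval for s in dataset}
    dupes = [s for s in new_dhs if s.interval in existing]
    if dupes:
        raise ValueError(
            f"{len(dupes)} new DHS intervals duplicate existing samples; "
            "deduplicate upstream"
        )
    out: list[LabeledDHS] = []
    for s in dataset:
        if s.label == NONIR and label_dhs(s.interval, rnaseq_retained, min_overlap) == IR:
            out.append(replace(s, label=IR, source="rnaseq_relabel"))
        else:
            out.append(s)
    for s in new_dhs:
        if label_dhs(s.interval, rnaseq_retained, min_overlap) == IR:
            out.append(replace(s, label=IR, source="rnaseq_new"))
    return out, DatasetSummary.from_samples(out)


# ---------------------------------------------------------------------------
# sequence transforms


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (case-preserving)."""
    bad = set(seq.upper()) - _ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def augment_reverse_complement(samples: Sequence[LabeledDHS]) -> list[LabeledDHS]:
    """Double the dataset: originals first, then their reverse complements.

    Each complement keeps its origin's label and source; the interval strand
    is flipped to record orientation.
    """
    flipped = {"+": "-", "-": "+", ".": "-"}
    out = list(samples)
    for s in samples:
        iv = replace(s.interval, strand=flipped[s.interval.strand])
        out.append(LabeledDHS(iv, revcomp(s.seq), s.label, s.source))
    return out


def one_hot(seq: str) -> np.ndarray:
    """4 x N binary encoding, rows A, C, G, T; N gives an all-zero column."""
    n = len(seq)
    mat = np.zeros((4, n))
    for j, base in enumerate(seq.upper()):
        if base == "N":
            continue
        row = _ONEHOT_ROW.get(base)
        if row is None:
            raise ValueError(f"cannot one-hot encode character {base!r}")
        mat[row, j] = 1.0
    return mat


def one_hot_batch(seqs: Sequence[str]) -> np.ndarray:
    """(n, 4, N) stack of one-hot encodings; sequences must share a length."""
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("all sequences must have equal length")
    return np.stack([one_hot(s) for s in seqs]) if seqs else np.empty((0, 4, 0))


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of one_hot: all-zero columns decode to N."""
    mat = np.asarray(mat)
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        out.append("N" if col.sum() == 0 else BASE_ORDER[int(col.argmax())])
    return "".join(out)


# ---------------------------------------------------------------------------
# redundancy clustering and split


def sequence_identity(a: str, b: str) -> float:
    """Best ungapped identity between two sequences, both strands.

    The shorter sequence is slid over the longer at every full-containment
    offset; identity = matches / len(shorter), maximised over offsets and
    over the reverse-complement of the shorter.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    long_arr = np.frombuffer(long_.upper().encode(), dtype=np.uint8)
    best = 0
    k = len(short)
    for cand in (short.upper(), revcomp(short.upper())):
        s_arr = np.frombuffer(cand.encode(), dtype=np.uint8)
        for off in range(len(long_) - k + 1):
            matches = int((long_arr[off : off + k] == s_arr).sum())
            if matches > best:
                best = matches
    return best / k


def reduce_redundancy(seqs: Sequence[str], threshold: float = 0.80) -> np.ndarray:
    """Greedy incremental clustering at an identity threshold.

    Sequences are visited longest-first (ties broken lexicographically); each
    joins the first existing cluster whose representative (founder) it matches
    at >= threshold identity, else founds a new cluster.  Deterministic.
    Returns the cluster id of each input sequence, in input order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    n = len(seqs)
    assignment = np.full(n, -1, dtype=int)
    order = sorted(range(n), key=lambda i: (-len(seqs[i]), seqs[i]))
    reps: list[tuple[int, str]] = []  # (cluster_id, representative)
    for i in order:
        for cid, rep in reps:
            if sequence_identity(seqs[i], rep) >= threshold:
                assignment[i] = cid
                break
        else:
            cid = len(reps)
            reps.append((cid, seqs[i]))
            assignment[i] = cid
    return assignment


def split_dataset(
    samples: Sequence,
    clusters: np.ndarray,
    cfg: SplitConfig,
) -> dict[str, list[int]]:
    """Cluster-aware 80/10/10 split; returns index lists per partition.

    Whole clusters go to a single partition so that no sequence at or above
    the redundancy threshold identity with a test sequence ends up in train
    or validation.  Clusters are shuffled with the config seed, then each is
    assigned to the partition with the largest remaining deficit relative to
    its target size (ties resolved train > val > test).
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(samples):
        raise ValueError("every sample needs a cluster assignment")
    n = len(samples)
    names = ("train", "val", "test")
    targets = {p: f * n for p, f in zip(names, cfg.fractions)}
    members: dict[int, list[int]] = {}
    for idx, cid in enumerate(clusters):
        members.setdefault(int(cid), []).append(idx)
    cluster_ids = sorted(members)
    rng = np.random.default_rng(cfg.seed)
    rng.shuffle(cluster_ids)
    out: dict[str, list[int]] = {p: [] for p in names}
    for cid in cluster_ids:
        deficits = {p: targets[p] - len(out[p]) for p in names}
        dest = max(names, key=lambda p: (deficits[p], -names.index(p)))
        out[dest].extend(members[cid])
    for p in names:
        out[p].sort()
    return out
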