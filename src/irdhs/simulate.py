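"""Synthetic ground-truth generators for the IR pipeline.

Three generators stand in for the study's raw inputs, each with known ground
truth so downstream stages are testable:

* ``simulate_annotation`` — a small genome with intronic intervals, a subset
  marked as retained, and fixed-length DHS windows placed inside introns;
  exercises the overlap-labeling rules and file formats.
* ``plant_motif_sequences`` — two classes of background sequences into which
  PWM motif instances are planted with class-conditional probabilities; the
  plant log is the ground truth for attribution/hot-spot recovery.
* ``simulate_targets`` — a chromatin-targets matrix with labels drawn from a
  known sparse logistic model; ground truth for weight-recovery tests.

Randomness: every generator builds its own stream from the config seed via
``SeedSequence(seed, spawn_key=(k,))`` with a fixed k per generator
(0 = annotation, 1 = sequences, 2 = targets), so partial re-runs reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import GenomicInterval, revcomp
from .io import write_bed, write_fasta
from .models import TargetsMatrix, TARGET_GROUPS
from .motifs import BASES, PWM

_STREAM = {"annotation": 0, "sequences": 1, "targets": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM[stream],)))


@dataclass
class SimulationConfig:
    """Conditions for sequence simulation.

    ``plant_prob_ir`` / ``plant_prob_nonir`` may be a single probability
    applied to every motif or a mapping motif-id -> probability.
    ``gc_background`` defaults to 0.41, the genome-wide human GC content.
    """

    n_ir: int
    n_nonir: int
    seq_len: int = 600
    motif_library: tuple[str, ...] = ()
    plant_prob_ir: float | Mapping[str, float] = 0.0
    plant_prob_nonir: float | Mapping[str, float] = 0.0
    gc_background: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ir < 0 or self.n_nonir < 0:
            raise ValueError("sample counts must be non-negative")
        if self.seq_len < 1:
            raise ValueError("seq_len must be positive")
        if not (0 <= self.gc_background <= 1):
            raise ValueError("gc_background must be a probability")
        for probs in (self.plant_prob_ir, self.plant_prob_nonir):
            vals = probs.values() if isinstance(probs, Mapping) else [probs]
            if any(not (0 <= p <= 1) for p in vals):
                raise ValueError("plant probabilities must be in [0, 1]")

    def plant_prob(self, motif_id: str, label: int) -> float:
        probs = self.plant_prob_ir if label == 1 else self.plant_prob_nonir
        if isinstance(probs, Mapping):
            return float(probs.get(motif_id, 0.0))
        return float(probs)


@dataclass
class SyntheticAnnotation:
    """A simulated genome with retained-intron and DHS interval structure."""

    genome: dict[str, str]
    retained_introns: list[GenomicInterval]
    non_ir_introns: list[GenomicInterval]
    dhs_intervals: list[GenomicInterval]
    dhs_labels: list[str]  # "IR" / "nonIR" ground truth by construction
    ir_fraction: float

    def dhs_sequences(self) -> list[str]:
        return [
            self.genome[iv.chrom][iv.start : iv.end] for iv in self.dhs_intervals
        ]

    def to_files(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa, retained_introns.bed, dhs.bed; byte-deterministic."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "retained": outdir / "retained_introns.bed",
            "dhs": outdir / "dhs.bed",
        }
        write_fasta(self.genome, paths["genome"])
        write_bed(
            self.retained_introns,
            paths["retained"],
            names=[f"ri{i}" for i in range(len(self.retained_introns))],
        )
        write_bed(
            self.dhs_intervals,
            paths["dhs"],
            names=[f"dhs{i}_{lab}" for i, lab in enumerate(self.dhs_labels)],
        )
        return paths


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=probs))


def simulate_annotation(
    cfg: SimulationConfig,
    intron_len: int | None = None,
    spacer_len: int = 200,
) -> SyntheticAnnotation:
    """Simulate one chromosome of intronic intervals with embedded DHSs.

    Each DHS (length ``cfg.seq_len``) sits fully inside its own intron;
    introns hosting the first ``n_ir`` DHSs (in shuffled genomic order) are
    marked retained, so IR DHSs overlap a retained intron over their full
    length and non-IR DHSs overlap none.
    """
    intron_len = intron_len or 3 * cfg.seq_len
    if cfg.seq_len > intron_len:
        raise ValueError(
            f"seq_len {cfg.seq_len} exceeds simulated intron length {intron_len}"
        )
    rng = _rng(cfg.seed, "annotation")
    n = cfg.n_ir + cfg.n_nonir
    is_ir = np.zeros(n, dtype=bool)
    is_ir[: cfg.n_ir] = True
    rng.shuffle(is_ir)

    chrom = "chr1"
    genome_len = n * (intron_len + spacer_len) + spacer_len
    genome = {chrom: _random_seq(rng, genome_len, cfg.gc_background)}

    retained, non_ir, dhs, labels = [], [], [], []
    pos = spacer_len
    for ir_flag in is_ir:
        intron = GenomicInterval(chrom, pos, pos + intron_len)
        off = int(rng.integers(0, intron_len - cfg.seq_len + 1))
        dhs.append(GenomicInterval(chrom, pos + off, pos + off + cfg.seq_len))
        if ir_flag:
            retained.append(intron)
            labels.append("IR")
        else:
            non_ir.append(intron)
            labels.append("nonIR")
        pos += intron_len + spacer_len

    return SyntheticAnnotation(
        genome=genome,
        retained_introns=retained,
        non_ir_introns=non_ir,
        dhs_intervals=dhs,
        dhs_labels=labels,
        ir_fraction=cfg.n_ir / n if n else 0.0,
    )


def _free_starts(occupied: list[tuple[int, int]], k: int, length: int) -> list[int]:
    """Start positions where a k-mer fits without touching occupied spans."""
    starts = []
    spans = sorted(occupied)
    for s in range(length - k + 1):
        if all(s + k <= a or s >= b for a, b in spans):
            starts.append(s)
    return starts


def plant_motif_sequences(
    cfg: SimulationConfig,
    pwms: Sequence[PWM],
) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """Generate labeled sequences with class-conditionally planted motifs.

    For each sequence and each motif, a Bernoulli draw at the motif's
    class-conditional probability decides planting; instances are sampled
    from the PWM, placed at a uniformly random non-overlapping offset, on a
    random strand.  Returns (sequences, labels with 1 = IR, plant log).
    """
    if cfg.motif_library:
        pwms = [p for p in pwms if p.id in cfg.motif_library]
    for pwm in pwms:
        if pwm.length > cfg.seq_len:
            raise ValueError(f"motif {pwm.id} longer than seq_len {cfg.seq_len}")
    rng = _rng(cfg.seed, "sequences")
    labels = np.concatenate(
        [np.ones(cfg.n_ir, dtype=int), np.zeros(cfg.n_nonir, dtype=int)]
    )
    seqs: list[str] = []
    log_rows = []
    for i, label in enumerate(labels):
        chars = list(_random_seq(rng, cfg.seq_len, cfg.gc_background))
        to_plant = [p for p in pwms if rng.random() < cfg.plant_prob(p.id, label)]
        if sum(p.length for p in to_plant) > cfg.seq_len:
            raise ValueError(
                f"sequence {i}: total motif length exceeds seq_len "
                f"{cfg.seq_len}; motifs cannot be placed without overlap"
            )
        occupied: list[tuple[int, int]] = []
        for pwm in to_plant:
            starts = _free_starts(occupied, pwm.length, cfg.seq_len)
            if not starts:
                raise ValueError(
                    f"sequence {i}: no non-overlapping offset for motif {pwm.id}"
                )
            off = int(starts[rng.integers(0, len(starts))])
            strand = "+" if rng.random() < 0.5 else "-"
            instance = pwm.sample(rng)
            planted = instance if strand == "+" else revcomp(instance)
            chars[off : off + pwm.length] = planted
            occupied.append((off, off + pwm.length))
            log_rows.append(
                {
                    "seq_id": i,
                    "label": int(label),
                    "motif_id": pwm.id,
                    "offset": off,
                    "strand": strand,
                    "instance": instance,
                }
            )
        seqs.append("".join(chars))
    plant_log = pd.DataFrame(
        log_rows, columns=["seq_id", "label", "motif_id", "offset", "strand", "instance"]
    )
    return seqs, labels, plant_log


@dataclass
class TargetSimConfig:
    """Conditions for the sparse-logistic chromatin-targets simulation."""

    n_samples: int
    n_targets: int
    n_active: int
    weight_scale: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active > self.n_targets:
            raise ValueError("n_active must not exceed n_targets")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.n_samples, self.n_targets) < 1 or self.n_active < 0:
            raise ValueError("counts must be positive (n_active >= 0)")


# Canonical group mix of the real chromatin-target compendium this emulates:
# 9,471 TF-binding, 10,064 histone-mark, 2,372 accessibility profiles.
_GROUP_MIX = {"TF": 9471, "HM": 10064, "ACC": 2372}


def _group_metadata(n_targets: int) -> pd.DataFrame:
    """Per-target metadata with groups in the canonical TF/HM/ACC mix.

    Proteins repeat across pairs of targets, mirroring the same factor being
    assayed in multiple cell lines.
    """
    total = sum(_GROUP_MIX.values())
    counts = {g: int(round(n_targets * c / total)) for g, c in _GROUP_MIX.items()}
    counts["TF"] += n_targets - sum(counts.values())
    groups = [g for g in TARGET_GROUPS for _ in range(counts[g])]
    rows = []
    for i, g in enumerate(groups):
        rows.append(
            {"name": f"t{i:04d}", "protein": f"{g}_prot{i // 2}", "group": g}
        )
    return pd.DataFrame(rows, columns=["name", "protein", "group"])


def simulate_targets(
    cfg: TargetSimConfig,
) -> tuple[TargetsMatrix, np.ndarray, np.ndarray]:
    """Targets in [0,1] with labels from a known sparse logistic model.

    ``n_active`` weights are nonzero with magnitude ``weight_scale`` and
    alternating signs; the intercept centers the logits so neither class is
    degenerate.  Labels ~ Bernoulli(sigmoid(w.x + b + noise)).  Returns
    (TargetsMatrix, labels, true weight vector).
    """
    rng = _rng(cfg.seed, "targets")
    X = rng.uniform(0.0, 1.0, size=(cfg.n_samples, cfg.n_targets))
    w = np.zeros(cfg.n_targets)
    active = rng.choice(cfg.n_targets, size=cfg.n_active, replace=False)
    signs = np.where(np.arange(cfg.n_active) % 2 == 0, 1.0, -1.0)
    w[active] = signs * cfg.weight_scale
    b = -0.5 * w.sum()  # E[x] = 0.5 -> logits centered at 0
    logits = X @ w + b
    if cfg.noise_sd > 0:
        logits = logits + rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
    probs = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.random(cfg.n_samples) < probs).astype(int)
    tm = TargetsMatrix(values=X, meta=_group_metadata(cfg.n_targets))
    return tm, y, w
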