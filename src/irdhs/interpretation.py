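"""Model interpretation: Integrated Gradients, hot spots, motif enrichment,
and logistic-weight target ranking.

The sequence-level pipeline mirrors how a trained IR classifier is mined for
transcription-factor signal:

1. keep sequences the model predicts correctly with probability above a
   confidence threshold (0.7 for either class);
2. attribute each kept sequence with Integrated Gradients against an
   all-zeros baseline;
3. call *hot spots*: positions whose attribution at the observed base
   exceeds 70% of the per-sequence maximum;
4. scan every motif window covering a hot spot (both strands) against a PWM
   library, a match requiring a log-odds score of at least 80% of the
   motif's maximum;
5. score each motif's enrichment as (fraction of IR hot spots matched) -
   (fraction of non-IR hot spots matched), with a permutation null obtained
   by shuffling hot-spot class labels.

Attributions keep their sign by default (the observed-base gradient value
is used as-is); magnitude mode is available via ``use_abs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .dataset import decode_one_hot
from .motifs import PWM, encode_bases


class DifferentiableModel(Protocol):
    def value_and_input_grad(
        self, X: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass
class InterpretConfig:
    confidence_threshold: float = 0.7
    hotspot_frac: float = 0.7
    motif_score_frac: float = 0.8
    ig_steps: int = 50
    use_abs: bool = False

    def __post_init__(self) -> None:
        for name in ("confidence_threshold", "hotspot_frac", "motif_score_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.ig_steps < 1:
            raise ValueError("ig_steps must be >= 1")


@dataclass
class AttributionMap:
    """Integrated-gradients attributions for one sequence (4 x N)."""

    values: np.ndarray
    seq_id: int | str | None = None
    model_prob: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attributions must be finite")


def integrated_gradients(
    model: DifferentiableModel,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
    seq_id: int | str | None = None,
) -> AttributionMap:
    """Right-Riemann Integrated Gradients for a single input.

    IG_i = (x_i - baseline_i) * (1/steps) * sum_{m=1..steps}
           df/dx_i at baseline + (m/steps)(x - baseline).

    The baseline defaults to all zeros (the "no sequence" reference for
    one-hot inputs).  All ``steps`` interpolation points are evaluated in
    one batched forward/backward pass.
    """
    x = np.asarray(x, dtype=float)
    baseline = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)
    if baseline.shape != x.shape:
        raise ValueError("x and baseline must share a shape")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    alphas = np.arange(1, steps + 1) / steps
    batch = baseline[None] + alphas[:, None, None] * (x - baseline)[None]
    f, grads = model.value_and_input_grad(batch)
    values = (x - baseline) * grads.mean(axis=0)
    return AttributionMap(values=values, seq_id=seq_id, model_prob=float(f[-1]))


def completeness_error(
    model: DifferentiableModel,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
) -> float:
    """|sum(IG) - (f(x) - f(baseline))| — the IG completeness residual."""
    x = np.asarray(x, dtype=float)
    baseline = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)
    attr = integrated_gradients(model, x, baseline, steps)
    f_base, _ = model.value_and_input_grad(baseline[None])
    return float(abs(attr.values.sum() - (attr.model_prob - f_base[0])))


def select_confident(
    model, X: np.ndarray, y: np.ndarray, threshold: float = 0.7
) -> tuple[np.ndarray, dict[str, int]]:
    """Mask of samples correctly predicted above the confidence threshold.

    The rule is symmetric in the true class: an IR sample is kept when
    p > threshold, a non-IR sample when 1 - p > threshold.
    """
    y = np.asarray(y)
    p = model.predict_proba(X)[:, 1]
    mask = np.where(y == 1, p > threshold, (1.0 - p) > threshold)
    counts = {
        "IR": int(mask[y == 1].sum()),
        "nonIR": int(mask[y == 0].sum()),
    }
    return mask, counts


def extract_hot_spots(
    attr: AttributionMap | np.ndarray,
    onehot: np.ndarray,
    frac: float = 0.7,
    use_abs: bool = False,
) -> np.ndarray:
    """Positions whose observed-base attribution exceeds frac x the maximum.

    The per-position scalar is the attribution at the base actually present
    (the nonzero one-hot channel); positions with an all-zero column (N
    bases) are never hot spots.  Signs are preserved unless ``use_abs``.
    Returns the 0-based positions, ascending.
    """
    values = attr.values if isinstance(attr, AttributionMap) else np.asarray(attr)
    onehot = np.asarray(onehot, dtype=float)
    if values.shape != onehot.shape:
        raise ValueError("attribution and one-hot shapes differ")
    observed = onehot.sum(axis=0) > 0
    if not observed.any():
        return np.empty(0, dtype=int)
    scalars = (values * onehot).sum(axis=0)
    if use_abs:
        scalars = np.abs(scalars)
    max_val = scalars[observed].max()
    keep = observed & (scalars > frac * max_val)
    return np.flatnonzero(keep)


def scan_motif(
    seq: str, center: int, pwm: PWM, score_frac: float = 0.8
) -> bool:
    """Does any motif window covering `center` match at >= score_frac of max?

    Every window of the motif's length that contains the position is scored
    on both strands with log-odds against the PWM background; windows
    extending beyond the sequence are skipped.
    """
    if not (0 <= center < len(seq)):
        raise ValueError(f"center {center} outside sequence of length {len(seq)}")
    k = pwm.length
    cutoff = score_frac * pwm.max_score
    rc = pwm.reverse_complement()
    for start in range(center - k + 1, center + 1):
        if start < 0 or start + k > len(seq):
            continue
        window = seq[start : start + k]
        if pwm.log_odds_score(window) >= cutoff:
            return True
        if rc.log_odds_score(window) >= cutoff:
            return True
    return False


def hotspot_motif_matches(
    hotspots: pd.DataFrame,
    seqs: Sequence[str],
    pwms: Sequence[PWM],
    score_frac: float = 0.8,
) -> np.ndarray:
    """Vectorised hot-spot x motif match matrix.

    ``hotspots`` needs columns ``seq_id`` (index into ``seqs``) and
    ``position``.  Equivalent to calling :func:`scan_motif` per cell.
    """
    n_h = len(hotspots)
    out = np.zeros((n_h, len(pwms)), dtype=bool)
    if n_h == 0:
        return out
    seq_ids = hotspots["seq_id"].to_numpy()
    centers = hotspots["position"].to_numpy()
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must share a length for vectorised scanning")
    encoded = {sid: encode_bases(seqs[sid]) for sid in np.unique(seq_ids)}
    seq_mat = np.stack([encoded[sid] for sid in seq_ids])  # (n_h, L)

    for mi, pwm in enumerate(pwms):
        k = pwm.length
        cutoff = score_frac * pwm.max_score
        starts = centers[:, None] - (k - 1) + np.arange(k)[None, :]  # (n_h, k)
        valid = (starts >= 0) & (starts <= length - k)
        pos = np.clip(starts, 0, length - k)[:, :, None] + np.arange(k)[None, None, :]
        bases = np.take_along_axis(
            seq_mat[:, None, :].repeat(k, axis=1).reshape(n_h, k, length),
            pos,
            axis=2,
        )  # (n_h, windows, k)
        for strand_pwm in (pwm, pwm.reverse_complement()):
            lo = np.vstack([strand_pwm.log_odds, np.full((1, k), -np.inf)])  # row 4 = N
            scores = lo[bases, np.arange(k)[None, None, :]].sum(axis=2)
            scores[~valid] = -np.inf
            out[:, mi] |= (scores >= cutoff).any(axis=1)
    return out


def enrichment_scores(
    matches: np.ndarray,
    classes: np.ndarray,
    pwms: Sequence[PWM],
) -> pd.DataFrame:
    """Per-motif IR enrichment: f_IR - f_nonIR over hot-spot match fractions.

    ``classes`` holds 'IR'/'nonIR' per hot spot.  Records are sorted by
    score descending, ties broken by motif id; ``rank`` is 1-based.
    Raises if either class has no hot spots.
    """
    classes = np.asarray(classes)
    ir_mask = classes == "IR"
    n_ir, n_nonir = int(ir_mask.sum()), int((~ir_mask).sum())
    if n_ir == 0 or n_nonir == 0:
        raise ValueError(
            f"need hot spots in both classes (IR: {n_ir}, nonIR: {n_nonir})"
        )
    f_ir = matches[ir_mask].mean(axis=0)
    f_nonir = matches[~ir_mask].mean(axis=0)
    frame = pd.DataFrame(
        {
            "motif_id": [p.id for p in pwms],
            "name": [p.name for p in pwms],
            "f_ir": f_ir,
            "f_nonir": f_nonir,
            "score": f_ir - f_nonir,
        }
    )
    frame = frame.sort_values(
        ["score", "motif_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def permutation_pvalues(
    matches: np.ndarray,
    classes: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """One-sided permutation p-values for positive IR enrichment.

    The null shuffles hot-spot class labels; p = (1 + #{null >= observed})
    / (n_perm + 1) per motif.
    """
    classes = np.asarray(classes)
    ir_mask = classes == "IR"
    obs = matches[ir_mask].mean(axis=0) - matches[~ir_mask].mean(axis=0)
    rng = np.random.default_rng(seed)
    count = np.zeros(matches.shape[1])
    perm = ir_mask.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        null = matches[perm].mean(axis=0) - matches[~perm].mean(axis=0)
        count += null >= obs
    return (1.0 + count) / (n_perm + 1.0)


def interpret_sequences(
    model,
    X: np.ndarray,
    y: np.ndarray,
    pwms: Sequence[PWM],
    cfg: InterpretConfig | None = None,
    max_per_class: int | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confidence filter -> IG -> hot spots -> motif scan -> enrichment.

    Returns (enrichment table, hot-spot table).  ``max_per_class`` caps the
    number of attributed sequences per class (seeded subsample) to bound
    compute; ``n_perm`` > 0 adds a permutation p-value column.
    """
    cfg = cfg or InterpretConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mask, _ = select_confident(model, X, y, cfg.confidence_threshold)
    kept = np.flatnonzero(mask)
    if max_per_class is not None:
        rng = np.random.default_rng(seed)
        chosen = []
        for cls in (0, 1):
            cls_idx = kept[y[kept] == cls]
            if len(cls_idx) > max_per_class:
                cls_idx = rng.choice(cls_idx, size=max_per_class, replace=False)
            chosen.append(cls_idx)
        kept = np.sort(np.concatenate(chosen))

    rows = []
    for i in kept:
        attr = integrated_gradients(model, X[i], steps=cfg.ig_steps, seq_id=int(i))
        positions = extract_hot_spots(attr, X[i], cfg.hotspot_frac, cfg.use_abs)
        scalars = (attr.values * X[i]).sum(axis=0)
        for pos in positions:
            rows.append(
                {
                    "seq_id": int(i),
                    "position": int(pos),
                    "attribution": float(scalars[pos]),
                    "class_label": "IR" if y[i] == 1 else "nonIR",
                }
            )
    hotspots = pd.DataFrame(
        rows, columns=["seq_id", "position", "attribution", "class_label"]
    )
    seqs = [decode_one_hot(x) for x in X]
    matches = hotspot_motif_matches(hotspots, seqs, pwms, cfg.motif_score_frac)
    enrichment = enrichment_scores(matches, hotspots["class_label"].to_numpy(), pwms)
    if n_perm > 0:
        pvals = permutation_pvalues(
            matches, hotspots["class_label"].to_numpy(), n_perm=n_perm, seed=seed
        )
        by_id = pd.Series(pvals, index=[p.id for p in pwms])
        enrichment["p_perm"] = by_id.loc[enrichment["motif_id"]].to_numpy()
    return enrichment, hotspots


# ---------------------------------------------------------------------------
# targets-model ranking


def rank_lr_targets(model, target_meta: pd.DataFrame) -> pd.DataFrame:
    """Rank chromatin targets by signed logistic-regression weight.

    ``model`` is a fitted estimator with ``coef_`` (or a raw weight vector).
    Rank 1 is the most positive (most IR-promoting) weight.  A protein
    assayed as several targets appears at several ranks.
    """
    weights = np.asarray(getattr(model, "coef_", model), dtype=float).ravel()
    if len(weights) != len(target_meta):
        raise ValueError(
            f"{len(weights)} weights vs {len(target_meta)} metadata rows"
        )
    if np.all(weights == 0):
        warnings.warn("all weights are zero; ranking is degenerate", stacklevel=2)
    table = pd.DataFrame(
        {
            "target": target_meta["name"].to_numpy(),
            "protein": target_meta["protein"].to_numpy(),
            "group": target_meta["group"].to_numpy(),
            "weight": weights,
        }
    )
    table = table.sort_values(
        ["weight", "target"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def top_bottom_intersection(ranked: pd.DataFrame, k: int = 100) -> list[str]:
    """Proteins present among both the top-k and bottom-k ranked targets.

    A non-empty intersection means the same factor carries both strongly
    positive and strongly negative weights across assay contexts.
    """
    top = set(ranked.nsmallest(k, "rank")["protein"])
    bottom = set(ranked.nlargest(k, "rank")["protein"])
    return sorted(top & bottom)
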