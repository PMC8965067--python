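"""Repeated-segmentation voting: turn attention weights into tiered motif calls.

A fragment is re-segmented and classified ``R`` times (default 20). Whenever a
run calls it a dimer, every residue of that run's highest-attention window
gains one vote. Residues are then tiered: blue with at least one vote, orange
with more than five, red with more than ten.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dataio import DIMER, NON_DIMER, Fragment
from .model import GLTMModel
from .windows import segment_windows, encode_windowset_array

TIER_NONE = "none"
TIER_BLUE = "blue"
TIER_ORANGE = "orange"
TIER_RED = "red"

#: vote thresholds (out of R runs): blue >= 1, orange > 5, red > 10
ORANGE_THRESHOLD = 5
RED_THRESHOLD = 10


def tier_for_votes(votes: int) -> str:
    if votes > RED_THRESHOLD:
        return TIER_RED
    if votes > ORANGE_THRESHOLD:
        return TIER_ORANGE
    if votes >= 1:
        return TIER_BLUE
    return TIER_NONE


@dataclass
class LocalizationResult:
    """Per-residue vote counts over repeated runs with tier labels.

    ``selected_centers`` records the argmax-attention window center of every
    run (regardless of the dimer call) for position-distribution diagnostics;
    it is not serialized and excluded from equality.
    """

    fragment_id: str
    predicted_label: str
    true_times: Optional[int]
    dimer_votes: Optional[int]
    residue_votes: Sequence[int]
    tiers: Sequence[str]
    selected_centers: Optional[list[float]] = field(default=None, compare=False)
    selected_boundary: Optional[list[bool]] = field(default=None, compare=False)
    selected_call: Optional[list[bool]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.residue_votes = list(int(v) for v in self.residue_votes)
        self.tiers = list(self.tiers)

    def tier_region(self, tier: str) -> list[int]:
        """Residue indices whose tier is at least *tier* (red ⊂ orange ⊂ blue)."""
        rank = {TIER_NONE: 0, TIER_BLUE: 1, TIER_ORANGE: 2, TIER_RED: 3}
        want = rank[tier]
        return [i for i, t in enumerate(self.tiers) if rank[t] >= want]


def locate(
    model: GLTMModel,
    fragment: Fragment,
    runs: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> LocalizationResult:
    """Run the R-fold voting procedure on one fragment."""
    return locate_batch(model, [fragment], runs=runs, rng=rng)[0]


def locate_batch(
    model: GLTMModel,
    fragments: Sequence[Fragment],
    runs: int = 20,
    rng: Optional[np.random.Generator] = None,
    batch_size: int = 256,
) -> list[LocalizationResult]:
    """Vectorized :func:`locate` over many fragments (one forward pass batches
    many (fragment, run) views)."""
    if not model.trained:
        raise RuntimeError("model is untrained; call train() or load a checkpoint")
    if rng is None:
        rng = np.random.default_rng()
    cfg = model.config
    n, k = cfg.n, cfg.k
    jobs = [(fi, r) for fi in range(len(fragments)) for r in range(runs)]
    L = {fi: len(fragments[fi].sequence) for fi in range(len(fragments))}
    votes = {fi: np.zeros(L[fi], dtype=int) for fi in L}
    dimer_votes = {fi: 0 for fi in L}
    centers: dict[int, list[float]] = {fi: [] for fi in L}
    boundary: dict[int, list[bool]] = {fi: [] for fi in L}
    calls: dict[int, list[bool]] = {fi: [] for fi in L}

    for lo in range(0, len(jobs), batch_size):
        chunk = jobs[lo : lo + batch_size]
        views = np.empty((len(chunk), n, k + 2, 22))
        window_sets = []
        for row, (fi, _r) in enumerate(chunk):
            ws = segment_windows(fragments[fi], n, k, rng)
            views[row] = encode_windowset_array(fragments[fi], ws)
            window_sets.append(ws)
        prob, A, _ = model.forward(views)
        probs, attn = prob.data, A.data
        for row, (fi, _r) in enumerate(chunk):
            ws = window_sets[row]
            best = int(np.argmax(attn[row]))  # ties -> lowest window index
            centers[fi].append(float(ws.centers[best]))
            boundary[fi].append(best == 0 or best == n - 1)
            calls[fi].append(bool(probs[row] > 0.5))
            if probs[row] > 0.5:
                dimer_votes[fi] += 1
                a, b = ws.intervals[best]
                votes[fi][a:b] += 1

    results = []
    for fi, fragment in enumerate(fragments):
        dv = dimer_votes[fi]
        predicted = DIMER if dv > runs / 2 else NON_DIMER
        if fragment.label == DIMER:
            true_times: Optional[int] = dv
        elif fragment.label == NON_DIMER:
            true_times = runs - dv
        else:
            true_times = None
        results.append(
            LocalizationResult(
                fragment_id=fragment.id,
                predicted_label=predicted,
                true_times=true_times,
                dimer_votes=dv,
                residue_votes=votes[fi].tolist(),
                tiers=[tier_for_votes(v) for v in votes[fi]],
                selected_centers=centers[fi],
                selected_boundary=boundary[fi],
                selected_call=calls[fi],
            )
        )
    return results


def evaluate_localization(
    results: Sequence[LocalizationResult],
    truth: dict[str, tuple[int, int]],
    labels: Optional[dict[str, str]] = None,
) -> dict:
    """Localization metrics against known motif intervals.

    Returns per-tier recovery rates (fraction of true-positive fragments whose
    tier region intersects the true interval), the mean offset between the
    vote-weighted located center and the true motif center, and located-center
    lists for dimer vs non-dimer fragments. ``located_centers`` holds the
    argmax-window centers of dimer-calling runs only (a located subsequence
    exists only when a run predicts dimer); ``*_all_runs`` lists the argmax
    centers of every run.
    """
    recovered = {TIER_BLUE: 0, TIER_ORANGE: 0, TIER_RED: 0}
    n_true_pos = 0
    offsets = []
    located: dict[str, list[float]] = {DIMER: [], NON_DIMER: []}
    all_runs: dict[str, list[float]] = {DIMER: [], NON_DIMER: []}
    for res in results:
        label = labels.get(res.fragment_id) if labels else (
            DIMER if res.fragment_id in truth else NON_DIMER
        )
        if res.selected_centers and label in located:
            all_runs[label].extend(res.selected_centers)
            located[label].extend(
                c
                for c, call in zip(res.selected_centers, res.selected_call or [])
                if call
            )
        if label != DIMER or res.fragment_id not in truth:
            continue
        if res.predicted_label != DIMER:
            continue
        n_true_pos += 1
        start, end = truth[res.fragment_id]
        interval = set(range(start, end))
        for tier in (TIER_BLUE, TIER_ORANGE, TIER_RED):
            if interval & set(res.tier_region(tier)):
                recovered[tier] += 1
        votes = np.asarray(res.residue_votes, dtype=float)
        if votes.sum() > 0:
            # residue i occupies [i, i+1); its center is i + 0.5
            vote_center = float(
                (votes * (np.arange(votes.size) + 0.5)).sum() / votes.sum()
            )
            offsets.append(abs(vote_center - (start + end) / 2.0))
    rates = {
        tier: (recovered[tier] / n_true_pos if n_true_pos else float("nan"))
        for tier in recovered
    }
    return {
        "n_true_positive": n_true_pos,
        "recovery_rate": rates,
        "mean_center_offset": float(np.mean(offsets)) if offsets else float("nan"),
        "located_centers": {
            "dimer": located[DIMER],
            "non-dimer": located[NON_DIMER],
            "dimer_all_runs": all_runs[DIMER],
            "non-dimer_all_runs": all_runs[NON_DIMER],
        },
    }


def uniformity_test(
    centers: Sequence[float],
    low: float,
    high: float,
    bins: int = 8,
) -> tuple[float, float]:
    """Chi-square test of the located-center sample against a uniform histogram.

    Returns ``(statistic, p_value)``.
    """
    counts, _ = np.histogram(np.asarray(centers, dtype=float), bins=bins, range=(low, high))
    return tuple(map(float, stats.chisquare(counts)))


def chance_recovery_rate(
    fragments: Sequence[Fragment],
    k: int,
    n: int,
    runs: int,
    rng: np.random.Generator,
    tier: str = TIER_RED,
    n_sim: int = 200,
) -> float:
    """Monte-Carlo recovery rate of a model that calls every view a dimer and
    selects a uniformly random window — the chance baseline for localization."""
    positives = [f for f in fragments if f.motif_interval is not None]
    hits = 0
    total = 0
    for _ in range(n_sim):
        frag = positives[int(rng.integers(len(positives)))]
        votes = np.zeros(len(frag.sequence), dtype=int)
        for _run in range(runs):
            ws = segment_windows(frag, n, k, rng)
            a, b = ws.intervals[int(rng.integers(n))]
            votes[a:b] += 1
        start, end = frag.motif_interval
        region = {
            TIER_BLUE: votes >= 1,
            TIER_ORANGE: votes > ORANGE_THRESHOLD,
            TIER_RED: votes > RED_THRESHOLD,
        }[tier]
        hits += bool(region[start:end].any())
        total += 1
    return hits / total


def evaluate_classification(
    predictions: Sequence[str], labels: Sequence[str]
) -> dict[str, float]:
    """Accuracy, precision, recall with dimer as the positive class.

    Precision (or recall) with an empty denominator is reported as 0.0 with a
    warning.
    """
    if len(predictions) == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    preds = np.asarray([p == DIMER for p in predictions])
    truth = np.asarray([l == DIMER for l in labels])
    tp = int((preds & truth).sum())
    fp = int((preds & ~truth).sum())
    fn = int((~preds & truth).sum())
    accuracy = float((preds == truth).mean())
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive labels; recall reported as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    return {"accuracy": accuracy, "precision": precision, "recall": recall}
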