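"""Random-step window segmentation, improved one-hot encoding, and window position scores.

A fragment of length ``L`` is segmented into ``n`` windows of ``k`` residues:
the first window is pinned at the N-terminus, the last at the C-terminus, and
the ``n - 2`` interior starts are drawn uniformly without replacement, so each
call yields a fresh stochastic view of the same fragment.

Each window is encoded as a ``(k + 2) x 22`` matrix: ``k`` residue rows holding
a 20-channel one-hot plus two overlap-flag channels, followed by two
window-state rows carrying the normalized overlap counts with the neighbouring
windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .dataio import AA_INDEX, Fragment

N_CHANNELS = 22
CH_OVERLAP_PREV = 20
CH_OVERLAP_NEXT = 21


@dataclass(frozen=True)
class WindowSet:
    """An ordered set of ``n`` subsequence windows over one fragment."""

    fragment_id: str
    starts: tuple[int, ...]
    k: int

    @property
    def n(self) -> int:
        return len(self.starts)

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return [(s, s + self.k) for s in self.starts]

    @property
    def centers(self) -> np.ndarray:
        """Window centers ``start + (k - 1) / 2`` (half-integral for even k)."""
        return np.asarray(self.starts, dtype=float) + (self.k - 1) / 2.0


def segment_windows(
    fragment: Fragment, n: int, k: int, rng: np.random.Generator
) -> WindowSet:
    """Draw a random-step segmentation of *fragment* into *n* windows of length *k*.

    The first window starts at 0, the last ends at ``L``; interior starts are
    uniform without replacement over ``(0, L - k)``, then sorted.

    Raises ``ValueError`` when no strictly increasing assignment of *n* starts
    exists (requires ``L - k >= n - 1``).
    """
    L = len(fragment.sequence)
    if n < 2:
        raise ValueError(f"window count n={n} must be at least 2")
    if k < 1:
        raise ValueError(f"window length k={k} must be positive")
    if L - k < n - 1:
        raise ValueError(
            f"infeasible segmentation: need L - k >= n - 1 for strictly increasing "
            f"starts, got L={L}, k={k}, n={n}"
        )
    interior = rng.choice(np.arange(1, L - k), size=n - 2, replace=False) if n > 2 else []
    starts = tuple(sorted([0, *map(int, interior), L - k]))
    return WindowSet(fragment_id=fragment.id, starts=starts, k=k)


def encode_window(
    window_seq: str,
    overlap_prev: Iterable[int] = (),
    overlap_next: Iterable[int] = (),
) -> np.ndarray:
    """Encode one k-residue window as a ``(k + 2) x 22`` matrix.

    Residue row ``j``: one-hot amino acid on channels 0-19; channel 20 flags
    membership in the preceding window's interval, channel 21 in the following
    window's. Window-state row ``k`` carries ``|overlap_prev| / k`` on channel
    20, row ``k + 1`` carries ``|overlap_next| / k`` on channel 21.
    """
    k = len(window_seq)
    if k < 1:
        raise ValueError("window sequence must be non-empty")
    prev = set(overlap_prev)
    nxt = set(overlap_next)
    for name, positions in (("overlap_prev", prev), ("overlap_next", nxt)):
        if not positions <= set(range(k)):
            raise ValueError(f"{name} contains indices outside the window (k={k})")
    matrix = np.zeros((k + 2, N_CHANNELS))
    for j, letter in enumerate(window_seq):
        try:
            matrix[j, AA_INDEX[letter]] = 1.0
        except KeyError:
            raise ValueError(f"non-standard residue {letter!r} at window position {j}")
        if j in prev:
            matrix[j, CH_OVERLAP_PREV] = 1.0
        if j in nxt:
            matrix[j, CH_OVERLAP_NEXT] = 1.0
    matrix[k, CH_OVERLAP_PREV] = len(prev) / k
    matrix[k + 1, CH_OVERLAP_NEXT] = len(nxt) / k
    return matrix


def window_overlaps(ws: WindowSet) -> list[tuple[set[int], set[int]]]:
    """Per-window local-index sets shared with the previous / next window."""
    out = []
    for i, (a, b) in enumerate(ws.intervals):
        prev: set[int] = set()
        nxt: set[int] = set()
        if i > 0:
            pa, pb = ws.intervals[i - 1]
            prev = {p - a for p in range(max(a, pa), min(b, pb))}
        if i < ws.n - 1:
            na, nb = ws.intervals[i + 1]
            nxt = {p - a for p in range(max(a, na), min(b, nb))}
        out.append((prev, nxt))
    return out


def encode_windowset(fragment: Fragment, ws: WindowSet) -> list[np.ndarray]:
    """Encode every window of *ws*, wiring overlap information between neighbours."""
    if ws.fragment_id != fragment.id:
        raise ValueError(
            f"window set belongs to {ws.fragment_id!r}, not {fragment.id!r}"
        )
    encoded = []
    for (a, b), (prev, nxt) in zip(ws.intervals, window_overlaps(ws)):
        encoded.append(encode_window(fragment.sequence[a:b], prev, nxt))
    return encoded


def encode_windowset_array(fragment: Fragment, ws: WindowSet) -> np.ndarray:
    """Vectorized equivalent of :func:`encode_windowset`, returning ``(n, k+2, 22)``.

    Used on the training hot path; agreement with the reference encoder is
    enforced by the test suite.
    """
    k, n = ws.k, ws.n
    idx = np.array([AA_INDEX[c] for c in fragment.sequence], dtype=np.intp)
    starts = np.asarray(ws.starts, dtype=np.intp)
    rows = idx[starts[:, None] + np.arange(k)[None, :]]  # (n, k)
    M = np.zeros((n, k + 2, N_CHANNELS))
    M[np.arange(n)[:, None], np.arange(k)[None, :], rows] = 1.0
    ends = starts + k
    local = np.arange(k)[None, :]
    # overlap with previous window: local indices < prev_end - start
    prev_cnt = np.zeros(n, dtype=np.intp)
    prev_cnt[1:] = np.maximum(0, ends[:-1] - starts[1:])
    M[:, :k, CH_OVERLAP_PREV] = (local < prev_cnt[:, None]).astype(float)
    # overlap with next window: local indices >= next_start - start
    nxt_cnt = np.zeros(n, dtype=np.intp)
    nxt_cnt[:-1] = np.maximum(0, ends[:-1] - starts[1:])
    M[:, :k, CH_OVERLAP_NEXT] = (local >= (k - nxt_cnt)[:, None]).astype(float)
    M[:, k, CH_OVERLAP_PREV] = prev_cnt / k
    M[:, k + 1, CH_OVERLAP_NEXT] = nxt_cnt / k
    return M


def position_scores(
    ws: WindowSet, motif_center: Optional[float], c: float = 0.0
) -> np.ndarray:
    """Softmax position-score vector over windows given a known motif center.

    ``s_i = exp(c - |cen_i - l|) / sum_j exp(c - |cen_j - l|)``; the constant
    ``c`` cancels analytically and is kept only for fidelity to the published
    form.

    Raises ``ValueError`` when *motif_center* is ``None``.
    """
    if motif_center is None:
        raise ValueError("position score undefined for unannotated fragment")
    logits = c - np.abs(ws.centers - float(motif_center))
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()
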