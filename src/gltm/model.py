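"""The global-local attention Bi-LSTM network, its penalized objective, and training.

Architecture
------------
Each fragment view is ``n`` encoded windows of shape ``(k + 2) x 22``. A local
bidirectional LSTM sweeps each window's rows — taking the window-state rows
first in each direction so the overlap bookkeeping is read before the residues
— and emits a ``2u`` summary per window. A global bidirectional LSTM runs over
the ``n`` summaries in window order, producing the hidden-state matrix ``H``
(``n x 2u``). Attention ``A = softmax(Ws2 tanh(Ws1 H^T))`` weighs the windows;
the context vector ``A H`` feeds a sigmoid output head.

The training objective sums squared classification error and a weighted
penalty per view: the position term ``||S - A||^2`` when the view's fragment
has a known motif (``S`` is its window position-score vector), otherwise the
self-focus term ``||A A^T - I||^2 = (sum_i A_i^2 - 1)^2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Adam, Tensor
from .dataio import DIMER, NON_DIMER, UNKNOWN, Fragment
from .windows import encode_windowset_array, position_scores, segment_windows

_GATES = "ifgo"


@dataclass
class ModelConfig:
    """Hyperparameters of the network."""

    k: int = 5        # window length (residues)
    n: int = 12       # windows per fragment view
    u: int = 32       # recurrent units per direction
    d_a: int = 16     # attention hidden size
    alpha: float = 0.1  # penalty weight; 0 disables both penalty terms
    c: float = 0.0    # position-score constant (cancels analytically)
    seed: int = 0
    state_rows_first: bool = True  # sweep window-state rows before residues

    def __post_init__(self) -> None:
        for name in ("k", "n", "u", "d_a"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class TrainConfig:
    """Optimization settings (the published work leaves these unspecified)."""

    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 2e-3
    lr_decay: float = 0.985  # multiplicative per-epoch decay
    oversample_minority: bool = True
    minority_repeat: Optional[int] = 2  # None -> auto (class-balance ratio)
    val_fraction: float = 0.1
    seed: int = 0


class GLTMModel:
    """Global-local attention Bi-LSTM classifier/localizer."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        u, d_a = config.u, config.d_a
        self.params: dict[str, Tensor] = {}
        self._init_lstm(rng, "local_f", 22, u)
        self._init_lstm(rng, "local_b", 22, u)
        self._init_lstm(rng, "global_f", 2 * u, u)
        self._init_lstm(rng, "global_b", 2 * u, u)
        self.params["Ws1"] = self._glorot(rng, (2 * u, d_a))
        self.params["Ws2"] = self._glorot(rng, (d_a, 1))
        self.params["w_out"] = self._glorot(rng, (2 * u, 1))
        self.params["b_out"] = Tensor(np.zeros((1, 1)), requires_grad=True)
        self.trained = False

    # -- parameters --------------------------------------------------------

    @staticmethod
    def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> Tensor:
        bound = math.sqrt(6.0 / sum(shape))
        return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)

    def _init_lstm(self, rng: np.random.Generator, prefix: str, n_in: int, u: int) -> None:
        # gate order along the last axis: input, forget, cell, output
        def blocks(fan_in):
            return np.hstack(
                [self._glorot(rng, (fan_in, u)).data for _ in _GATES]
            )

        self.params[f"{prefix}_Wx"] = Tensor(blocks(n_in), requires_grad=True)
        self.params[f"{prefix}_Wh"] = Tensor(blocks(u), requires_grad=True)
        bias = np.zeros((1, 4 * u))
        bias[:, u : 2 * u] = 1.0  # standard forget-gate bias init
        self.params[f"{prefix}_b"] = Tensor(bias, requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward -----------------------------------------------------------

    def _lstm(self, xs: Tensor, prefix: str) -> Tensor:
        """One LSTM direction over a step-major (T, B, n_in) sequence."""
        p = self.params
        return ag.lstm(xs, p[f"{prefix}_Wx"], p[f"{prefix}_Wh"], p[f"{prefix}_b"])

    def _local_sweep_order(self) -> list[int]:
        k = self.config.k
        if self.config.state_rows_first:
            return [k, *range(k), k + 1]
        return [*range(k), k, k + 1]

    def forward(self, views: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        """Forward one batch of encoded views.

        Parameters
        ----------
        views : ndarray, shape (B, n, k + 2, 22)

        Returns
        -------
        (prob, A, H) : prob (B,), attention A (B, n), global hidden state H (B, n, 2u)
        """
        cfg = self.config
        B, n, rows, ch = views.shape
        if n != cfg.n or rows != cfg.k + 2 or ch != 22:
            raise ValueError(
                f"expected views of shape (B, {cfg.n}, {cfg.k + 2}, 22), got {views.shape}"
            )
        order = self._local_sweep_order()
        # step-major local inputs: (k+2, B*n, 22)
        xs = np.ascontiguousarray(
            views.reshape(B * n, rows, ch)[:, order, :].transpose(1, 0, 2)
        )
        hf = self._lstm(Tensor(xs), "local_f")[rows - 1]           # (B*n, u)
        hb = self._lstm(Tensor(xs[::-1].copy()), "local_b")[rows - 1]
        summaries = ag.concat([hf, hb], axis=1)                    # (B*n, 2u)
        steps = ag.transpose(
            ag.reshape(summaries, (B, n, 2 * cfg.u)), (1, 0, 2)
        )                                                          # (n, B, 2u)
        gf = self._lstm(steps, "global_f")                         # (n, B, u)
        gb = ag.flip(self._lstm(ag.flip(steps, 0), "global_b"), 0)
        H = ag.transpose(ag.concat([gf, gb], axis=2), (1, 0, 2))   # (B, n, 2u)
        scores = ag.reshape(ag.tanh(H @ self.params["Ws1"]) @ self.params["Ws2"], (B, n))
        A = ag.softmax(scores, axis=1)
        m = ag.reshape(ag.reshape(A, (B, 1, n)) @ H, (B, 2 * cfg.u))
        logit = m @ self.params["w_out"] + self.params["b_out"]
        prob = ag.reshape(ag.sigmoid(logit), (B,))
        return prob, A, H

    # -- spec-level single-view operations ---------------------------------

    def local_encode(self, encoded_windows: Sequence[np.ndarray]) -> np.ndarray:
        """Summaries (n, 2u) of a list of (k+2, 22) encoded windows."""
        flat = np.stack(encoded_windows)
        n, rows, ch = flat.shape
        if rows != self.config.k + 2 or ch != 22:
            raise ValueError(f"expected windows of shape ({self.config.k + 2}, 22)")
        order = self._local_sweep_order()
        xs = np.ascontiguousarray(flat[:, order, :].transpose(1, 0, 2))
        hf = self._lstm(Tensor(xs), "local_f").data[-1]
        hb = self._lstm(Tensor(xs[::-1].copy()), "local_b").data[-1]
        return np.concatenate([hf, hb], axis=1)

    def global_encode(self, window_summaries: np.ndarray) -> np.ndarray:
        """Global hidden-state matrix H (n, 2u) from window summaries (n, 2u)."""
        summaries = np.asarray(window_summaries, dtype=float)
        if summaries.ndim != 2 or summaries.shape[1] != 2 * self.config.u:
            raise ValueError(f"expected summaries of shape (n, {2 * self.config.u})")
        n = summaries.shape[0]
        steps = summaries[:, None, :]  # (n, B=1, 2u)
        gf = self._lstm(Tensor(steps), "global_f").data[:, 0, :]
        gb = self._lstm(Tensor(steps[::-1].copy()), "global_b").data[::-1, 0, :]
        return np.concatenate([gf, gb], axis=1)

    def attend(self, H: np.ndarray) -> np.ndarray:
        """Annotation vector A (1, n): softmax(Ws2 tanh(Ws1 H^T))."""
        H = np.asarray(H, dtype=float)
        if H.ndim != 2 or H.shape[1] != 2 * self.config.u:
            raise ValueError(
                f"H must be (n, {2 * self.config.u}) to match Ws1, got {H.shape}"
            )
        scores = np.tanh(H @ self.params["Ws1"].data) @ self.params["Ws2"].data
        scores = scores.ravel() - scores.max()
        e = np.exp(scores)
        return (e / e.sum())[None, :]

    def classify(self, A: np.ndarray, H: np.ndarray) -> float:
        """Dimer probability sigmoid((A H) w + b) for one view."""
        A = np.asarray(A, dtype=float).reshape(1, -1)
        H = np.asarray(H, dtype=float)
        if A.shape[1] != H.shape[0]:
            raise ValueError(f"A has {A.shape[1]} windows but H has {H.shape[0]} rows")
        m = A @ H
        logit = (m @ self.params["w_out"].data + self.params["b_out"].data).item()
        return 1.0 / (1.0 + np.exp(-logit))

    def predict_view(self, encoded_windows: Sequence[np.ndarray]) -> tuple[float, np.ndarray]:
        """(probability, attention vector) for one encoded fragment view."""
        prob, A, _ = self.forward(np.stack(encoded_windows)[None, ...])
        return float(prob.data[0]), A.data[0]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint all weight matrices plus the full config in one archive."""
        arrays = {name: t.data for name, t in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GLTMModel":
        with np.load(path) as archive:
            cfg = ModelConfig(**json.loads(bytes(archive["__config__"]).decode()))
            model = cls(cfg)
            for name in model.params:
                model.params[name].data = archive[name].astype(np.float64)
        model.trained = True
        return model


def penalty(A: np.ndarray, S: Optional[np.ndarray] = None) -> float:
    """Penalty P for one view: self-focus ``||A A^T - I||^2`` when no position
    scores are given, else position ``||S - A||^2``."""
    A = np.asarray(A, dtype=float).ravel()
    if S is None:
        # A is 1 x n, so A A^T is the 1x1 matrix [sum A_i^2]
        return float((A @ A - 1.0) ** 2)
    S = np.asarray(S, dtype=float).ravel()
    if S.shape != A.shape:
        raise ValueError(f"S has length {S.size} but A has length {A.size}")
    return float(((S - A) ** 2).sum())


def loss_graph(
    model: GLTMModel,
    views: np.ndarray,
    y: np.ndarray,
    S: np.ndarray,
    has_motif: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """Build the batched objective: sum of squared error plus alpha * penalty.

    Views of fragments with a known motif (``has_motif`` mask) contribute the
    position term against their rows of ``S``; all others the self-focus term.
    Returns ``(loss, prob)``.
    """
    alpha = model.config.alpha
    prob, A, _ = model.forward(views)
    err = ag.square(Tensor(y) + (-1.0) * prob).sum()
    loss = err
    if alpha > 0:
        self_focus = ag.square(ag.tensor_sum(A * A, axis=1) + (-1.0))
        position = ag.tensor_sum(ag.square(Tensor(S) + (-1.0) * A), axis=1)
        mask = Tensor(has_motif.astype(float))
        P = mask * position + (Tensor(1.0 - has_motif.astype(float))) * self_focus
        loss = loss + alpha * P.sum()
    return loss, prob


def batch_loss(
    model: GLTMModel,
    views: np.ndarray,
    y: np.ndarray,
    S: np.ndarray,
    has_motif: np.ndarray,
) -> float:
    """Objective value for one batch (no gradient bookkeeping kept)."""
    loss, _ = loss_graph(model, views, y, S, has_motif)
    return loss.item()


def make_views(
    fragments: Sequence[Fragment],
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fresh random views for a list of fragments.

    Returns ``(views (B,n,k+2,22), y (B,), S (B,n), has_motif (B,))``; rows of
    ``S`` are zero for fragments without a known motif interval.
    """
    B, n = len(fragments), config.n
    views = np.empty((B, n, config.k + 2, 22))
    y = np.empty(B)
    S = np.zeros((B, n))
    has_motif = np.zeros(B, dtype=bool)
    for i, frag in enumerate(fragments):
        ws = segment_windows(frag, n, config.k, rng)
        views[i] = encode_windowset_array(frag, ws)
        y[i] = 1.0 if frag.label == DIMER else 0.0
        if frag.motif_interval is not None:
            S[i] = position_scores(ws, frag.motif_center, config.c)
            has_motif[i] = True
    return views, y, S, has_motif


def train(
    dataset: Sequence[Fragment],
    model_config: ModelConfig,
    train_config: TrainConfig,
    val_set: Optional[Sequence[Fragment]] = None,
) -> tuple[GLTMModel, dict]:
    """Fit the model on labeled fragments, re-segmenting every fragment with
    fresh random windows each epoch.

    Minority-class fragments are oversampled (integer replication of views per
    epoch) when ``oversample_minority`` is set. When *val_set* is ``None`` and
    ``val_fraction > 0``, a seeded split is carved from *dataset*.

    Returns the trained model and a history dict with per-epoch ``loss`` and
    ``val_accuracy``. Raises on unlabeled fragments or non-finite loss.
    """
    for frag in dataset:
        if frag.label == UNKNOWN:
            raise ValueError(f"fragment {frag.id!r} has unknown label; training needs y")
    rng = np.random.default_rng(train_config.seed)
    dataset = list(dataset)
    if val_set is None and train_config.val_fraction > 0:
        idx = rng.permutation(len(dataset))
        n_val = max(1, int(round(train_config.val_fraction * len(dataset))))
        val_set = [dataset[i] for i in idx[:n_val]]
        dataset = [dataset[i] for i in idx[n_val:]]

    positives = [f for f in dataset if f.label == DIMER]
    negatives = [f for f in dataset if f.label == NON_DIMER]
    repeat = 1
    if train_config.oversample_minority and positives and negatives:
        if train_config.minority_repeat is not None:
            repeat = max(1, train_config.minority_repeat)
        else:
            minority, majority = sorted((positives, negatives), key=len)
            repeat = max(1, round(len(majority) / len(minority)))

    model = GLTMModel(model_config)
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    history: dict = {"loss": [], "val_accuracy": []}

    for epoch in range(train_config.epochs):
        pool = list(dataset)
        if repeat > 1:
            minority = positives if len(positives) < len(negatives) else negatives
            pool += [f for f in minority for _ in range(repeat - 1)]
        order = rng.permutation(len(pool))
        epoch_loss = 0.0
        for lo in range(0, len(pool), train_config.batch_size):
            batch = [pool[i] for i in order[lo : lo + train_config.batch_size]]
            views, y, S, has_motif = make_views(batch, model_config, rng)
            loss, _ = loss_graph(model, views, y, S, has_motif)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            epoch_loss += value
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        optimizer.lr *= train_config.lr_decay
        history["loss"].append(epoch_loss)
        if val_set:
            history["val_accuracy"].append(
                accuracy(model, val_set, rng)
            )
    model.trained = True
    return model, history


def accuracy(
    model: GLTMModel, fragments: Sequence[Fragment], rng: np.random.Generator
) -> float:
    """Single-view classification accuracy on labeled fragments."""
    views, y, _, _ = make_views(fragments, model.config, rng)
    prob, _, _ = model.forward(views)
    return float(((prob.data > 0.5) == (y > 0.5)).mean())
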