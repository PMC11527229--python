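"""Multitask pre-training: task roster, label quantization, balanced batches.

Every task is cast as multi-class classification over quantized labels and
optimized with a cross-entropy (KL) loss summed across tasks.  Mini-batches
are split evenly across the task roster so no task can starve the others,
and the whole loop runs on the NumPy encoder with a hand-rolled Adam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from .model import Encoder, HeadSpec, ModelConfig, softmax, _trunc_normal
from .simulate import NO_BLEACH, GroundTruth, Trace

__all__ = [
    "TaskDefinition",
    "QuantizedLabel",
    "quantize_label",
    "default_task_roster",
    "compute_task_labels",
    "multitask_loss",
    "build_balanced_minibatches",
    "pretrain",
    "PretrainResult",
    "evaluate_task_losses",
]

EPS = 1e-9


# ---------------------------------------------------------------------------
# task definitions and quantization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDefinition:
    """One training head: what it predicts and how its labels are binned.

    ``bin_edges`` is None for categorical tasks; otherwise labels are mapped
    by half-open bin membership [edge_i, edge_{i+1}).  ``label_fn`` maps a
    GroundTruth to a raw scalar (trace level) or length-T array (frame level).
    """

    name: str
    level: str                    # "trace" | "frame"
    attribute_group: str
    channel_mode: str             # "two-color" | "one-color"
    n_classes: int
    label_fn: Callable[[GroundTruth], np.ndarray]
    bin_edges: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.level not in ("trace", "frame"):
            raise ValueError(f"bad level {self.level!r}")
        if self.bin_edges is not None:
            edges = np.asarray(self.bin_edges, dtype=float)
            if np.any(np.diff(edges) <= 0):
                raise ValueError(f"bin edges must be strictly increasing: {self.name}")
            if len(edges) != self.n_classes + 1:
                raise ValueError(f"n_classes/edges mismatch in {self.name}")

    def applicable(self, gt: GroundTruth) -> bool:
        return gt.one_color == (self.channel_mode == "one-color")


@dataclass
class QuantizedLabel:
    task_name: str
    class_index: int
    p_hat: np.ndarray  # empirical distribution over classes (one-hot default)


def _digitize(values: np.ndarray, edges: np.ndarray, n_classes: int,
              task_name: str = "") -> np.ndarray:
    values = np.asarray(values, dtype=float)
    below = values < edges[0]
    above = values > edges[-1]
    if np.any(below) or np.any(above):
        warnings.warn(
            f"{task_name}: {int(below.sum() + above.sum())} value(s) outside "
            f"[{edges[0]}, {edges[-1]}]; clamped to end bins"
        )
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, n_classes - 1).astype(np.int64)


def quantize_label(value, task: TaskDefinition) -> QuantizedLabel:
    """Quantize one raw label value into its class with a one-hot p_hat."""
    if task.bin_edges is None:
        cls = int(value)
        if not (0 <= cls < task.n_classes):
            raise ValueError(f"categorical label {value} out of range for {task.name}")
    else:
        cls = int(_digitize(np.array([value]), task.bin_edges, task.n_classes,
                            task.name)[0])
    p = np.zeros(task.n_classes)
    p[cls] = 1.0
    return QuantizedLabel(task.name, cls, p)


# -- raw label extractors ----------------------------------------------------

def _observed_lifetime(bleach_frame: int, T: int) -> float:
    return float(T if bleach_frame == NO_BLEACH else max(bleach_frame, 1))


def _trace_fret(gt: GroundTruth) -> float:
    active = gt.active_mask
    if not np.any(active):
        return 0.0
    return float(np.mean(gt.ideal_fret[active]))


def _observed_states(gt: GroundTruth) -> int:
    """Distinct states actually visited before the first bleach event."""
    act = gt.active_mask
    path = gt.state_path[act] if np.any(act) else gt.state_path[:1]
    return int(np.unique(path).size)


def _frame_bleach_count(gt: GroundTruth) -> np.ndarray:
    T = gt.state_path.shape[0]
    count = np.zeros(T, dtype=np.int64)
    for b in gt.bleach_frame:
        if b != NO_BLEACH:
            count[b:] += 1
    return count


def _frame_channel_bleached(gt: GroundTruth, channel: int) -> np.ndarray:
    T = gt.state_path.shape[0]
    out = np.zeros(T, dtype=np.int64)
    b = gt.bleach_frame[channel]
    if b != NO_BLEACH:
        out[b:] = 1
    return out


def default_task_roster(max_pb_steps: int = 6) -> list[TaskDefinition]:
    """The 30-head roster: 10 attribute groups x 3 heads each.

    Per group: a coarse-bin and a fine-bin trace-level head plus either a
    frame-level head or (for SNR, where per-frame labels are not meaningful)
    a medium-bin trace-level head.
    """
    snr_fine = np.linspace(1.0, 8.0, 11)
    snr_coarse = np.array([1.0, 3.0, 5.0, 8.0])
    snr_mid = np.linspace(1.0, 8.0, 6)
    life_fine = np.geomspace(1.0, 2000.0, 11)
    life_coarse = np.geomspace(1.0, 2000.0, 4)
    rate_fine = np.linspace(0.0, 1.0, 11)
    rate_coarse = np.array([0.0, 0.05, 0.3, 1.0])
    fret_fine = np.linspace(0.0, 1.0, 11)
    fret_coarse = np.array([0.0, 0.35, 0.65, 1.0])

    T = lambda *a, **k: TaskDefinition(*a, **k)  # noqa: E731

    tasks: list[TaskDefinition] = []

    def trace_pair(group, mode, fn, fine, coarse, fine_n=None, coarse_n=None):
        tasks.append(T(f"{group}/coarse", "trace", group, mode,
                       coarse_n or len(coarse) - 1, fn,
                       None if coarse_n else coarse))
        tasks.append(T(f"{group}/fine", "trace", group, mode,
                       fine_n or len(fine) - 1, fn,
                       None if fine_n else fine))

    # -- two-color groups --------------------------------------------------
    trace_pair("k_rate", "two-color",
               lambda gt: gt.mean_transition_rate, rate_fine, rate_coarse)
    tasks.append(T("k_rate/frame_active", "frame", "k_rate", "two-color", 2,
                   lambda gt: gt.active_mask.astype(np.int64)))

    tasks.append(T("fret_states/coarse", "trace", "fret_states", "two-color", 2,
                   lambda gt: int(_observed_states(gt) > 1)))
    tasks.append(T("fret_states/fine", "trace", "fret_states", "two-color", 4,
                   lambda gt: _observed_states(gt) - 1))
    tasks.append(T("fret_states/frame_state", "frame", "fret_states",
                   "two-color", 4, lambda gt: gt.state_path.astype(np.int64)))

    trace_pair("fret_value", "two-color", _trace_fret, fret_fine, fret_coarse)
    tasks.append(T("fret_value/frame_ideal", "frame", "fret_value", "two-color",
                   10, lambda gt: gt.ideal_fret, bin_edges=fret_fine))

    trace_pair("a_lifetime", "two-color",
               lambda gt: _observed_lifetime(gt.bleach_frame[1],
                                             gt.state_path.shape[0]),
               life_fine, life_coarse)
    tasks.append(T("a_lifetime/frame_bleached", "frame", "a_lifetime",
                   "two-color", 2, lambda gt: _frame_channel_bleached(gt, 1)))

    trace_pair("d_lifetime", "two-color",
               lambda gt: _observed_lifetime(gt.bleach_frame[0],
                                             gt.state_path.shape[0]),
               life_fine, life_coarse)
    tasks.append(T("d_lifetime/frame_bleached", "frame", "d_lifetime",
                   "two-color", 2, lambda gt: _frame_channel_bleached(gt, 0)))

    tasks.append(T("pb_steps/coarse", "trace", "pb_steps", "two-color", 2,
                   lambda gt: int(sum(gt.n_bleach_steps) > 0)))
    tasks.append(T("pb_steps/fine", "trace", "pb_steps", "two-color", 3,
                   lambda gt: int(sum(gt.n_bleach_steps))))
    tasks.append(T("pb_steps/frame_count", "frame", "pb_steps", "two-color", 3,
                   _frame_bleach_count))

    trace_pair("snr", "two-color", lambda gt: gt.snr, snr_fine, snr_coarse)
    tasks.append(T("snr/mid", "trace", "snr", "two-color", 5,
                   lambda gt: gt.snr, bin_edges=snr_mid))

    # -- one-color groups --------------------------------------------------
    trace_pair("sgl_k_rate", "one-color",
               lambda gt: gt.mean_transition_rate, rate_fine, rate_coarse)
    tasks.append(T("sgl_k_rate/frame_active", "frame", "sgl_k_rate",
                   "one-color", 2, lambda gt: gt.active_mask.astype(np.int64)))

    tasks.append(T("sgl_pb_steps/coarse", "trace", "sgl_pb_steps", "one-color",
                   3, lambda gt: min(gt.n_bleach_steps[0], 2)))
    tasks.append(T("sgl_pb_steps/fine", "trace", "sgl_pb_steps", "one-color",
                   max_pb_steps + 1,
                   lambda gt: min(gt.n_bleach_steps[0], max_pb_steps)))
    tasks.append(T("sgl_pb_steps/frame_count", "frame", "sgl_pb_steps",
                   "one-color", max_pb_steps + 1,
                   lambda gt: np.minimum(
                       gt.bleach_steps_so_far
                       if gt.bleach_steps_so_far is not None
                       else np.zeros(gt.state_path.shape[0], dtype=np.int64),
                       max_pb_steps)))

    trace_pair("sgl_snr", "one-color", lambda gt: gt.snr, snr_fine, snr_coarse)
    tasks.append(T("sgl_snr/mid", "trace", "sgl_snr", "one-color", 5,
                   lambda gt: gt.snr, bin_edges=snr_mid))

    assert len(tasks) == 30
    return tasks


def compute_task_labels(
    traces: Sequence[Trace], tasks: Sequence[TaskDefinition]
) -> dict[str, np.ndarray]:
    """Quantized class labels for every task over a dataset.

    Trace-level tasks yield (N,) int arrays; frame-level tasks (N, T) int
    arrays.  Entries are -1 where a task does not apply to a trace.
    """
    N = len(traces)
    T = traces[0].n_frames
    out: dict[str, np.ndarray] = {}
    for task in tasks:
        if task.level == "trace":
            lab = np.full(N, -1, dtype=np.int64)
        else:
            lab = np.full((N, T), -1, dtype=np.int64)
        for i, tr in enumerate(traces):
            gt = tr.ground_truth
            if gt is None or not task.applicable(gt):
                continue
            raw = task.label_fn(gt)
            if task.bin_edges is not None:
                cls = _digitize(np.atleast_1d(raw), task.bin_edges,
                                task.n_classes, task.name)
                lab[i] = cls[0] if task.level == "trace" else cls
            else:
                lab[i] = raw
        out[task.name] = lab
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _cross_entropy(probs: np.ndarray, p_hat: np.ndarray) -> np.ndarray:
    """Per-example cross-entropy -sum p_hat log p; probs clipped at EPS."""
    clipped = np.clip(probs, EPS, None)
    return -(p_hat * np.log(clipped)).sum(axis=-1)


def _as_distribution(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim >= 1 and labels.shape[-1] == n_classes and labels.dtype != np.int64:
        return labels
    eye = np.eye(n_classes)
    return eye[labels.astype(np.int64)]


def multitask_loss(
    predictions: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
) -> tuple[float, dict[str, float]]:
    """Total multitask loss plus the per-task decomposition.

    The per-task term is the mean cross-entropy over that task's examples
    (frame-level examples contribute the mean over frames); the total is
    the sum over tasks, so the decomposition identity holds exactly.
    """
    per_task: dict[str, float] = {}
    for name, probs in predictions.items():
        n_classes = probs.shape[-1]
        p_hat = _as_distribution(labels[name], n_classes)
        ce = _cross_entropy(probs, p_hat)
        per_task[name] = float(np.mean(ce))
    total = float(sum(per_task.values()))
    return total, per_task


# ---------------------------------------------------------------------------
# balanced batching
# ---------------------------------------------------------------------------

def build_balanced_minibatches(
    task_pools: dict[str, np.ndarray],
    batch_size: int,
    rng: np.random.Generator,
) -> Iterator[list[tuple[str, np.ndarray]]]:
    """Infinite iterator of batches split evenly across tasks.

    ``task_pools`` maps task name to the indices of traces it applies to.
    Per batch, per-task counts differ by at most 1 and every task appears.
    """
    names = list(task_pools)
    k = len(names)
    if batch_size < k:
        raise ValueError(f"batch_size {batch_size} < number of tasks {k}")
    base, extra = divmod(batch_size, k)
    while True:
        bonus = set(rng.choice(k, size=extra, replace=False)) if extra else set()
        batch = []
        for j, name in enumerate(names):
            cnt = base + (1 if j in bonus else 0)
            pool = task_pools[name]
            batch.append((name, rng.choice(pool, size=cnt, replace=True)))
        yield batch


# ---------------------------------------------------------------------------
# pre-training loop
# ---------------------------------------------------------------------------

@dataclass
class PretrainResult:
    encoder: Encoder
    heads: dict[str, HeadSpec]
    history: list[dict]          # rows: step, task, split, loss
    tasks: list[TaskDefinition] = field(default_factory=list)

    def history_tsv(self) -> str:
        lines = ["step\ttask\tsplit\tloss"]
        for r in self.history:
            lines.append(f"{r['step']}\t{r['task']}\t{r['split']}\t{r['loss']:.6f}")
        return "\n".join(lines) + "\n"


def _init_heads(tasks: Sequence[TaskDefinition], D: int, seed: int) -> dict[str, HeadSpec]:
    rng = np.random.default_rng(seed)
    return {
        t.name: HeadSpec(t.name, t.level, t.n_classes,
                         _trunc_normal(rng, (D, t.n_classes)),
                         np.zeros(t.n_classes))
        for t in tasks
    }


def _task_pools(tasks, labels, indices, strict: bool = True) -> dict[str, np.ndarray]:
    pools = {}
    for t in tasks:
        lab = labels[t.name]
        mask = (lab >= 0) if t.level == "trace" else np.any(lab >= 0, axis=1)
        pool = indices[mask[indices]]
        if pool.size == 0:
            if strict:
                raise ValueError(f"no applicable traces for task {t.name}")
            warnings.warn(f"no applicable traces for task {t.name} in split; "
                          "skipping it there")
            continue
        pools[t.name] = pool
    return pools


def evaluate_task_losses(
    encoder: Encoder,
    heads: dict[str, HeadSpec],
    data: np.ndarray,
    labels: dict[str, np.ndarray],
    tasks: Sequence[TaskDefinition],
    pools: dict[str, np.ndarray],
    max_per_task: int = 64,
) -> dict[str, float]:
    """Per-task mean losses on a fixed subset (first max_per_task of each pool)."""
    by_task = {t.name: t for t in tasks}
    idx_union = sorted({int(i) for name in pools
                        for i in pools[name][:max_per_task]})
    pos = {i: j for j, i in enumerate(idx_union)}
    z0, frames = encoder.forward(data[idx_union])
    losses = {}
    for name, pool in pools.items():
        task = by_task[name]
        head = heads[name]
        rows = [pos[int(i)] for i in pool[:max_per_task]]
        if task.level == "trace":
            probs = softmax(z0[rows] @ head.W + head.b)
            y = labels[name][pool[:max_per_task]]
            ce = _cross_entropy(probs, _as_distribution(y, task.n_classes))
        else:
            probs = softmax(frames[rows] @ head.W + head.b)
            y = labels[name][pool[:max_per_task]]
            ce = _cross_entropy(probs, _as_distribution(y, task.n_classes)).mean(axis=1)
        losses[name] = float(ce.mean())
    return losses


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr_scale: float = 1.0) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            params[k] -= lr_scale * self.lr * mhat / (np.sqrt(vhat) + self.eps)


def pretrain(
    traces: Sequence[Trace],
    model_cfg: ModelConfig,
    tasks: Optional[Sequence[TaskDefinition]] = None,
    steps: int = 1000,
    batch_size: int = 60,
    learning_rate: float = 3e-4,
    warmup_steps: int = 100,
    seed: int = 0,
    val_fraction: float = 0.1,
    eval_every: int = 100,
    eval_max_per_task: int = 32,
    init_from: Optional[PretrainResult] = None,
) -> PretrainResult:
    """Pre-train the encoder and all task heads with Adam (b1=0.9, b2=0.999).

    Deterministic given ``seed``.  Loss histories (train batch losses and
    periodic validation losses, including step 0) are recorded per task.
    Raises RuntimeError naming the step if the loss goes non-finite.
    ``init_from`` resumes from an earlier result's encoder and heads
    (fresh optimizer state).
    """
    tasks = list(tasks) if tasks is not None else default_task_roster()
    labels = compute_task_labels(traces, tasks)
    data = np.stack([t.intensities for t in traces]).astype(np.float64)
    N = data.shape[0]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    n_val = max(1, int(round(val_fraction * N))) if val_fraction > 0 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train_pools = _task_pools(tasks, labels, train_idx)
    val_pools = (_task_pools(tasks, labels, val_idx, strict=False)
                 if n_val else {})

    if init_from is not None:
        encoder = Encoder(model_cfg,
                          weights={k: v.copy()
                                   for k, v in init_from.encoder.weights.items()})
        heads = {n: HeadSpec(h.task_name, h.level, h.n_classes,
                             h.W.copy(), h.b.copy())
                 for n, h in init_from.heads.items()}
    else:
        encoder = Encoder(model_cfg, seed=seed)
        heads = _init_heads(tasks, model_cfg.embed_dim, seed + 1)
    by_task = {t.name: t for t in tasks}

    params: dict[str, np.ndarray] = dict(encoder.weights)
    for name, h in heads.items():
        params[f"head/{name}/W"] = h.W
        params[f"head/{name}/b"] = h.b
    adam = _Adam(params, learning_rate)

    history: list[dict] = []

    def record_eval(step: int) -> None:
        for split, pools in (("train", train_pools), ("val", val_pools)):
            if not pools:
                continue
            losses = evaluate_task_losses(
                encoder, heads, data, labels, tasks, pools, eval_max_per_task
            )
            for name, v in losses.items():
                history.append({"step": step, "task": name, "split": split,
                                "loss": v})
            history.append({"step": step, "task": "__total__", "split": split,
                            "loss": float(sum(losses.values()))})

    record_eval(0)
    batches = build_balanced_minibatches(train_pools, batch_size, rng)
    D = model_cfg.embed_dim

    for step in range(1, steps + 1):
        batch = next(batches)
        flat_idx = np.concatenate([idx for _, idx in batch])
        uniq = np.unique(flat_idx)
        pos = {int(i): j for j, i in enumerate(uniq)}
        x = data[uniq]
        z0, frames, cache = encoder.forward(x, want_cache=True)
        B, T, _ = x.shape
        dz0 = np.zeros((B, D))
        dframes = np.zeros((B, T, D))
        grads = {f"head/{n}/W": np.zeros_like(h.W) for n, h in heads.items()}
        grads.update({f"head/{n}/b": np.zeros_like(h.b) for n, h in heads.items()})

        total_loss = 0.0
        for name, idx in batch:
            task, head = by_task[name], heads[name]
            rows = np.array([pos[int(i)] for i in idx])
            y = labels[name][idx]
            if task.level == "trace":
                z = z0[rows]
                probs = softmax(z @ head.W + head.b)
                onehot = _as_distribution(y, task.n_classes)
                total_loss += float(_cross_entropy(probs, onehot).mean())
                dlogits = (probs - onehot) / len(idx)
                grads[f"head/{name}/W"] += z.T @ dlogits
                grads[f"head/{name}/b"] += dlogits.sum(axis=0)
                np.add.at(dz0, rows, dlogits @ head.W.T)
            else:
                f = frames[rows]
                probs = softmax(f @ head.W + head.b)
                onehot = _as_distribution(y, task.n_classes)
                total_loss += float(
                    _cross_entropy(probs, onehot).mean(axis=1).mean()
                )
                dlogits = (probs - onehot) / (len(idx) * T)
                grads[f"head/{name}/W"] += np.einsum("btd,btk->dk", f, dlogits)
                grads[f"head/{name}/b"] += dlogits.sum(axis=(0, 1))
                np.add.at(dframes, rows, dlogits @ head.W.T)

        if not np.isfinite(total_loss):
            raise RuntimeError(f"training diverged (non-finite loss) at step {step}")
        history.append({"step": step, "task": "__batch_total__", "split": "train",
                        "loss": total_loss})

        enc_grads = encoder.backward(cache, dz0, dframes)
        grads.update(enc_grads)
        lr_scale = min(1.0, step / warmup_steps) if warmup_steps > 0 else 1.0
        adam.step(params, grads, lr_scale=lr_scale)

        if eval_every and step % eval_every == 0:
            record_eval(step)

    if eval_every and steps % eval_every != 0:
        record_eval(steps)
    return PretrainResult(encoder, heads, history, list(tasks))
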