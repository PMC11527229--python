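"""Frozen-encoder fine-tuning and the derived kinetic analyses.

Downstream heads are multinomial logistic regressions fitted on frozen
trace- or frame-level embeddings; the encoder itself is never touched.
Also provides the idealization -> dwell-time -> exponential-rate pipeline,
photobleach step counting and kinetic-fingerprint accept/reject decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .model import EmbeddingSet, HeadSpec, head_predict

__all__ = [
    "DownstreamHead",
    "DwellTimeSummary",
    "fit_logistic_head",
    "classify_and_segment",
    "idealize",
    "idealize_two_state",
    "extract_dwells",
    "extract_dwells_censored",
    "dwell_times_and_rates",
    "count_photobleach_steps",
    "kinetic_fingerprint_classify",
]


@dataclass
class DownstreamHead:
    head: HeadSpec
    n_labeled: int
    seed: int
    training_accuracy: float
    classes: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def task_name(self) -> str:
        return self.head.task_name


def _stack_trace_embeddings(embeddings: Sequence[EmbeddingSet]) -> np.ndarray:
    return np.stack([e.trace_embedding for e in embeddings])


def fit_logistic_head(
    embeddings: Sequence[EmbeddingSet] | np.ndarray,
    labels: np.ndarray,
    level: str = "trace",
    seed: int = 0,
    task_name: str = "downstream",
    C: float = 1.0,
    max_iter: int = 1000,
) -> DownstreamHead:
    """Fit a multinomial logistic-regression head on frozen embeddings.

    ``level="trace"`` uses the per-trace embedding; ``level="frame"`` expects
    per-frame embeddings and per-frame labels (label -1 = unlabeled frame).
    """
    if level == "trace":
        X = (np.asarray(embeddings) if isinstance(embeddings, np.ndarray)
             else _stack_trace_embeddings(embeddings))
        y = np.asarray(labels)
    elif level == "frame":
        Xs, ys = [], []
        for emb, lab in zip(embeddings, labels):
            F = emb.frame_embeddings if isinstance(emb, EmbeddingSet) else emb
            lab = np.asarray(lab)
            mask = lab >= 0
            Xs.append(F[mask])
            ys.append(lab[mask])
        X = np.concatenate(Xs)
        y = np.concatenate(ys)
    else:
        raise ValueError(f"level must be 'trace' or 'frame', got {level!r}")

    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"labels contain a single class ({classes[0]!r}); need >= 2"
        )
    clf = LogisticRegression(C=C, max_iter=max_iter, random_state=seed)
    clf.fit(X, y)
    acc = float(clf.score(X, y))

    D = X.shape[1]
    n_classes = classes.size
    W = np.zeros((D, n_classes))
    b = np.zeros(n_classes)
    if clf.coef_.shape[0] == 1:  # sklearn binary convention
        W[:, 1] = clf.coef_[0]
        b[1] = clf.intercept_[0]
    else:
        W[:] = clf.coef_.T
        b[:] = clf.intercept_
    spec = HeadSpec(task_name, level, n_classes, W, b)
    return DownstreamHead(spec, n_labeled=len(y), seed=seed,
                         training_accuracy=acc, classes=classes)


# ---------------------------------------------------------------------------
# classification and segmentation
# ---------------------------------------------------------------------------

def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open [start, end) runs of True."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def classify_and_segment(
    embeddings: Sequence[EmbeddingSet],
    trace_head: DownstreamHead,
    frame_head: Optional[DownstreamHead] = None,
    accept_class: int = 1,
    usable_class: int = 1,
    threshold: float = 0.5,
    frame_threshold: Optional[float] = None,
) -> list[dict]:
    """Accept/reject each trace; for accepted traces, usable-frame intervals.

    Returns one dict per trace with keys ``accepted``, ``p_accept`` and
    ``intervals`` (empty list for rejected traces).  ``frame_threshold``
    defaults to ``threshold``.
    """
    if frame_threshold is None:
        frame_threshold = threshold
    out = []
    for emb in embeddings:
        p = head_predict(emb.trace_embedding, trace_head.head)
        col = int(np.where(trace_head.classes == accept_class)[0][0]) \
            if trace_head.classes.size else accept_class
        accepted = bool(p[col] >= threshold)
        intervals: list[tuple[int, int]] = []
        if accepted:
            if frame_head is not None:
                fp = head_predict(emb.frame_embeddings, frame_head.head)
                fcol = int(np.where(frame_head.classes == usable_class)[0][0]) \
                    if frame_head.classes.size else usable_class
                usable = fp[:, fcol] >= frame_threshold
            else:
                usable = np.ones(emb.frame_embeddings.shape[0], dtype=bool)
            intervals = _mask_to_intervals(usable)
        out.append({"accepted": accepted, "p_accept": float(p[col]),
                    "intervals": intervals})
    return out


# ---------------------------------------------------------------------------
# idealization
# ---------------------------------------------------------------------------

def idealize(
    embeddings: Sequence[EmbeddingSet],
    frame_fret_head: HeadSpec | DownstreamHead,
    bin_edges: Optional[np.ndarray] = None,
    median_window: Optional[int] = None,
) -> list[dict]:
    """Per-frame FRET class and bin-center FRET value via the frame head.

    ``bin_edges`` describes the full label quantizer whose bin indices the
    head predicts; it defaults to 10 equal bins on [0, 1], matching the
    pre-training quantizer.  Heads fitted on a label subset (a
    ``DownstreamHead`` whose ``classes`` lists the original bin indices)
    are mapped back onto the full quantizer before taking bin centers.
    """
    head = frame_fret_head.head if isinstance(frame_fret_head, DownstreamHead) \
        else frame_fret_head
    classes = (frame_fret_head.classes
               if isinstance(frame_fret_head, DownstreamHead)
               and frame_fret_head.classes.size else None)
    if bin_edges is None:
        n_bins = 10 if classes is not None else head.n_classes
        bin_edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    out = []
    for emb in embeddings:
        probs = head_predict(emb.frame_embeddings, head)
        cls = np.argmax(probs, axis=-1)
        if classes is not None:
            cls = classes[cls].astype(int)
        if median_window is not None and median_window > 1:
            from scipy.ndimage import median_filter

            cls = median_filter(cls, size=median_window,
                                mode="nearest").astype(int)
        out.append({"classes": cls, "fret": centers[np.clip(cls, 0,
                                                            len(centers) - 1)]})
    return out


def _hysteresis(x: np.ndarray, low: float, high: float) -> np.ndarray:
    """Two-state Schmitt-trigger assignment of a continuous FRET estimate."""
    s = np.zeros(x.size, dtype=int)
    cur = 1 if x[0] > 0.5 * (low + high) else 0
    for i, v in enumerate(x):
        if cur == 0 and v > high:
            cur = 1
        elif cur == 1 and v < low:
            cur = 0
        s[i] = cur
    return s


def idealize_two_state(
    embeddings: Sequence[EmbeddingSet],
    frame_fret_head: HeadSpec | DownstreamHead,
    bin_edges: Optional[np.ndarray] = None,
    low_threshold: float = 0.3,
    high_threshold: float = 0.7,
) -> list[dict]:
    """Two-state idealization via probability-weighted FRET plus hysteresis.

    The head's class posteriors are collapsed to an expected FRET value per
    frame (probability-weighted bin centers); a hysteresis threshold pair
    then assigns low/high states, suppressing single-frame threshold
    chatter.  Output items carry ``classes`` (0 = low, 1 = high) and
    ``fret`` (the per-frame expected FRET), ready for
    :func:`dwell_times_and_rates`.
    """
    head = frame_fret_head.head if isinstance(frame_fret_head, DownstreamHead) \
        else frame_fret_head
    classes = (frame_fret_head.classes
               if isinstance(frame_fret_head, DownstreamHead)
               and frame_fret_head.classes.size else None)
    if bin_edges is None:
        n_bins = 10 if classes is not None else head.n_classes
        bin_edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    col_values = centers[classes.astype(int)] if classes is not None \
        else centers[: head.n_classes]
    out = []
    for emb in embeddings:
        probs = head_predict(emb.frame_embeddings, head)
        efret = probs @ col_values
        states = _hysteresis(efret, low_threshold, high_threshold)
        out.append({"classes": states, "fret": efret})
    return out


# ---------------------------------------------------------------------------
# dwell times and rates
# ---------------------------------------------------------------------------

@dataclass
class DwellTimeSummary:
    dwells: dict[int, np.ndarray]          # state -> dwell lengths (frames)
    rates: dict[str, float]                # "k12", "k21" in frame^-1
    rates_per_second: dict[str, float]
    fret_means: dict[int, float]
    low_confidence: dict[str, bool]
    frame_period: float = 1.0


def extract_dwells(states: np.ndarray, drop_censored: bool = True) -> dict[int, list[int]]:
    """Run-length dwell segments per state; censored first/last runs dropped."""
    states = np.asarray(states)
    out: dict[int, list[int]] = {}
    if states.size == 0:
        return out
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [states.size]])
    for r in range(len(bounds) - 1):
        if drop_censored and (r == 0 or r == len(bounds) - 2):
            continue
        s = int(states[bounds[r]])
        out.setdefault(s, []).append(int(bounds[r + 1] - bounds[r]))
    return out


def extract_dwells_censored(
    states: np.ndarray, fresh_start: bool = True
) -> list[tuple[int, int, bool]]:
    """All dwell runs as (state, length, event) triples.

    The final run is always right-censored (event=False).  With
    ``fresh_start`` the first run counts as a complete dwell — correct for
    simulated traces whose state clock starts at frame 0; pass False for
    experimental segments that begin at an arbitrary time (the partial
    first dwell then contributes exposure only, which is unbiased for an
    exponential by memorylessness).
    """
    states = np.asarray(states)
    out: list[tuple[int, int, bool]] = []
    if states.size == 0:
        return out
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [states.size]])
    n_runs = len(bounds) - 1
    for r in range(n_runs):
        s = int(states[bounds[r]])
        L = int(bounds[r + 1] - bounds[r])
        event = r < n_runs - 1 and (fresh_start or r > 0)
        out.append((s, L, event))
    return out


def _fit_exponential_rate(dwells: np.ndarray) -> float:
    """Least-squares fit of log survival (1 - CDF) vs dwell time.

    Fitted with an intercept, so missing short dwells (censored or removed
    by smoothing) shift the offset rather than biasing the rate.
    """
    t = np.sort(np.asarray(dwells, dtype=float))
    n = t.size
    surv = 1.0 - np.arange(1, n + 1) / n
    keep = surv > 0
    t, surv = t[keep], surv[keep]
    if t.size == 0 or np.all(t == t[0]):
        # degenerate: all mass at one dwell length; fall back to 1/mean
        return float(1.0 / np.mean(dwells)) if np.mean(dwells) > 0 else np.nan
    slope = np.polyfit(t, np.log(surv), 1)[0]
    return -float(slope)


def dwell_times_and_rates(
    idealized: Sequence[dict] | Sequence[np.ndarray],
    frame_period: float = 1.0,
    min_dwells: int = 5,
    n_states: int = 2,
    method: str = "mle",
    fresh_start: bool = True,
    fret_boundary_margin: int = 2,
) -> DwellTimeSummary:
    """Aggregate dwell times over traces and fit exponential rate constants.

    Input items are either ``idealize`` outputs or plain state sequences.
    For the two-state case the reported rates are ``k12`` (leaving the
    low-FRET state) and ``k21`` (leaving the high-FRET state).

    ``method="mle"`` (default) fits the exponential dwell distribution with
    censoring: boundary-truncated dwells contribute exposure time without a
    transition event, so rates stay unbiased even when dwells are
    comparable to the trace length.  ``method="ls"`` is the naive
    least-squares fit of log survival on censoring-excluded dwells (biased
    upward when dwells approach the trace length; kept for reference).
    """
    seqs, frets = [], []
    for item in idealized:
        if isinstance(item, dict):
            seqs.append(np.asarray(item["classes"]))
            frets.append(np.asarray(item.get("fret", item["classes"])))
        else:
            seqs.append(np.asarray(item))
            frets.append(np.asarray(item, dtype=float))

    # collapse observed class values into n_states discrete levels
    all_vals = np.concatenate(seqs)
    uniq = np.unique(all_vals)
    if uniq.size < 2:
        raise ValueError("need at least 2 observed states to fit rates")
    if uniq.size > n_states:
        # merge nearest class values into n_states clusters by 1-D k-means
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_states, n_init=10, random_state=0)
        km.fit(all_vals.reshape(-1, 1).astype(float))
        order = np.argsort(km.cluster_centers_.ravel())
        relabel = np.empty(n_states, dtype=int)
        relabel[order] = np.arange(n_states)
        mapping = {v: relabel[km.predict(np.array([[float(v)]]))[0]]
                   for v in uniq}
    else:
        mapping = {v: i for i, v in enumerate(np.sort(uniq))}

    dwells: dict[int, list[int]] = {}
    exposure: dict[int, float] = {}
    events: dict[int, int] = {}
    fret_acc: dict[int, list[float]] = {}
    for seq, fr in zip(seqs, frets):
        mapped = np.array([mapping[v] for v in seq])
        for s, lst in extract_dwells(mapped).items():
            dwells.setdefault(s, []).extend(lst)
        for s, L, event in extract_dwells_censored(mapped, fresh_start):
            exposure[s] = exposure.get(s, 0.0) + L
            events[s] = events.get(s, 0) + int(event)
        # state FRET levels from dwell interiors only: frames adjacent to a
        # transition are blurred mixtures of both levels
        change = np.flatnonzero(np.diff(mapped)) + 1
        bounds = np.concatenate([[0], change, [mapped.size]])
        m = fret_boundary_margin
        for r in range(len(bounds) - 1):
            lo, hi = bounds[r] + m, bounds[r + 1] - m
            if r == 0:
                lo = bounds[r]  # trace start is not a transition
            if r == len(bounds) - 2:
                hi = bounds[r + 1]
            if hi > lo:
                s = int(mapped[bounds[r]])
                fret_acc.setdefault(s, []).extend(fr[lo:hi].tolist())

    # fallback for states whose every dwell was shorter than the margin
    missing = {s for s in exposure if not fret_acc.get(s)}
    if missing:
        for seq, fr in zip(seqs, frets):
            mapped = np.array([mapping[v] for v in seq])
            for s in missing:
                sel = mapped == s
                if np.any(sel):
                    fret_acc.setdefault(s, []).extend(fr[sel].tolist())

    rates: dict[str, float] = {}
    low_conf: dict[str, bool] = {}
    for s, name in ((0, "k12"), (1, "k21")):
        if method == "mle":
            n_ev = events.get(s, 0)
            expo = exposure.get(s, 0.0)
            rates[name] = n_ev / expo if expo > 0 and n_ev > 0 else float("nan")
            low_conf[name] = n_ev < min_dwells
        elif method == "ls":
            d = np.asarray(dwells.get(s, []), dtype=float)
            if d.size == 0:
                rates[name] = float("nan")
                low_conf[name] = True
                continue
            rates[name] = _fit_exponential_rate(d)
            low_conf[name] = d.size < min_dwells
        else:
            raise ValueError(f"unknown method {method!r}")
    # median over dwell-interior frames: robust to transition-blur outliers
    fret_means = {s: float(np.median(v)) for s, v in fret_acc.items()}
    rates_s = {k: v / frame_period for k, v in rates.items()}
    return DwellTimeSummary(
        dwells={s: np.asarray(v) for s, v in dwells.items()},
        rates=rates,
        rates_per_second=rates_s,
        fret_means=fret_means,
        low_confidence=low_conf,
        frame_period=frame_period,
    )


# ---------------------------------------------------------------------------
# photobleach step counting and kinetic fingerprinting
# ---------------------------------------------------------------------------

def count_photobleach_steps(
    embeddings: Sequence[EmbeddingSet],
    pb_head: DownstreamHead | HeadSpec,
) -> dict:
    """Per-trace photobleach step counts from a trace-level counting head."""
    head = pb_head.head if isinstance(pb_head, DownstreamHead) else pb_head
    classes = (pb_head.classes if isinstance(pb_head, DownstreamHead)
               and pb_head.classes.size else np.arange(head.n_classes))
    counts = []
    for emb in embeddings:
        p = head_predict(emb.trace_embedding, head)
        counts.append(int(classes[int(np.argmax(p))]))
    counts = np.asarray(counts)
    return {
        "counts": counts,
        "mean": float(counts.mean()) if counts.size else float("nan"),
        "std": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
    }


def kinetic_fingerprint_classify(
    embeddings: Sequence[EmbeddingSet],
    head: DownstreamHead,
    positive_class: int = 1,
    threshold: float = 0.5,
    fields_of_view: Optional[Sequence[str]] = None,
) -> dict:
    """Accept/reject traces by posterior of the positive (e.g. mutant) class."""
    if not len(embeddings):
        return {"accepted": np.array([], dtype=bool),
                "p_positive": np.array([]),
                "per_fov": {}}
    Z = _stack_trace_embeddings(embeddings)
    probs = head_predict(Z, head.head)
    col = int(np.where(head.classes == positive_class)[0][0]) \
        if head.classes.size else positive_class
    p_pos = probs[:, col]
    accepted = p_pos >= threshold
    per_fov: dict[str, int] = {}
    if fields_of_view is not None:
        for fov, a in zip(fields_of_view, accepted):
            per_fov[fov] = per_fov.get(fov, 0) + int(a)
    return {"accepted": accepted, "p_positive": p_pos, "per_fov": per_fov}
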