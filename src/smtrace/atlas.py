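"""The smFRET Atlas: category nomenclature, corpus generation, a fitted
global 2-D reducer, and per-category Gaussian-mixture contour annotation.

Category labels follow the grammar "states-SNRclass-FRETlevels-rateclass"
(rate omitted for 1-state traces): states 1-3; SNR "c" (clean, SNR >= 4) or
"n" (noisy); FRET levels a set of distinct letters from {l, m, h} whose size
equals the state count, written in ascending order; rate "f" (fast, average
rate >= 0.05 per frame) or "s" (slow).
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import Encoder, embed_traces
from .simulate import (
    GroundTruth,
    KineticModel,
    SimulatorConfig,
    Trace,
    add_noise,
    apply_photophysics,
    mean_transition_rate,
    render_ideal_trace,
    simulate_state_path,
    NO_BLEACH,
    _first_bleach,
)

__all__ = [
    "AtlasCategory",
    "Atlas",
    "enumerate_categories",
    "categorize",
    "sample_category_trace",
    "generate_atlas_corpus",
    "build_atlas",
    "project_into_atlas",
]

_LEVELS = ("l", "m", "h")
_LEVEL_RANK = {"l": 0, "m": 1, "h": 2}

SNR_CLEAN_THRESHOLD = 4.0
FRET_LOW_MAX = 0.35    # value < 0.35 -> low
FRET_HIGH_MIN = 0.65   # value > 0.65 -> high; [0.35, 0.65] -> medium
FAST_RATE_THRESHOLD = 0.05  # per frame


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------

def enumerate_categories() -> list[str]:
    """All valid category labels in canonical order (22 of them)."""
    labels = []
    for n_states in (1, 2, 3):
        for snr in ("c", "n"):
            for combo in combinations(_LEVELS, n_states):
                levels = "".join(combo)  # already ascending l < m < h
                if n_states == 1:
                    labels.append(f"1-{snr}-{levels}")
                else:
                    for rate in ("s", "f"):
                        labels.append(f"{n_states}-{snr}-{levels}-{rate}")
    return labels


def _fret_level(value: float) -> str:
    if value > FRET_HIGH_MIN:
        return "h"
    if value < FRET_LOW_MAX:
        return "l"
    return "m"


def categorize(gt: GroundTruth) -> str:
    """Category label of a trace from its simulation ground truth.

    Raises ValueError for traces outside the grammar: more than 3 states,
    one-color traces, or two states falling in the same FRET-level bin.
    """
    if gt.one_color:
        raise ValueError("one-color traces are outside the atlas grammar")
    if gt.n_states > 3:
        raise ValueError(f"{gt.n_states}-state traces are outside the atlas grammar")
    snr_class = "c" if gt.snr >= SNR_CLEAN_THRESHOLD else "n"
    letters = [_fret_level(v) for v in gt.state_fret_values]
    if len(set(letters)) != len(letters):
        raise ValueError(
            f"two states share a FRET-level bin ({letters}); outside the grammar"
        )
    levels = "".join(sorted(letters, key=_LEVEL_RANK.__getitem__))
    if gt.n_states == 1:
        return f"1-{snr_class}-{levels}"
    rate_class = "f" if gt.mean_transition_rate >= FAST_RATE_THRESHOLD else "s"
    return f"{gt.n_states}-{snr_class}-{levels}-{rate_class}"


def parse_category(label: str) -> dict:
    parts = label.split("-")
    if len(parts) not in (3, 4):
        raise ValueError(f"malformed category label {label!r}")
    n_states = int(parts[0])
    out = {"n_states": n_states, "snr": parts[1], "levels": parts[2]}
    out["rate"] = parts[3] if len(parts) == 4 else None
    if (n_states == 1) != (out["rate"] is None):
        raise ValueError(f"malformed category label {label!r}")
    return out


# ---------------------------------------------------------------------------
# targeted per-category simulation
# ---------------------------------------------------------------------------

_LEVEL_RANGES = {"l": (0.05, 0.30), "m": (0.40, 0.60), "h": (0.70, 0.95)}
_SNR_RANGES = {"c": (4.0, 6.0), "n": (1.9, 3.9)}
_RATE_RANGES = {"f": (0.06, 0.30), "s": (0.005, 0.04)}


def sample_category_trace(
    label: str,
    cfg: SimulatorConfig,
    rng: np.random.Generator,
) -> Trace:
    """Simulate one two-color trace guaranteed to fall in the category.

    Parameters are drawn inside the category's threshold region (with a
    margin at the boundaries) and the resulting trace is verified against
    :func:`categorize`.
    """
    spec = parse_category(label)
    S = spec["n_states"]
    fret = np.array([rng.uniform(*_LEVEL_RANGES[c]) for c in spec["levels"]])
    p_init = rng.uniform(size=S)
    p_init /= p_init.sum()
    if S == 1:
        p_transfer = np.ones((1, 1))
    else:
        r = rng.uniform(*_RATE_RANGES[spec["rate"]])
        p_transfer = np.zeros((S, S))
        for i in range(S):
            off = rng.uniform(0.2, 1.0, size=S - 1)
            off = off / off.sum() * r
            p_transfer[i] = np.insert(off, i, 1.0 - r)
    i_max = float(rng.uniform(*cfg.i_max_range))
    model = KineticModel(S, p_init, p_transfer, fret, i_max)
    model.validate()

    path = simulate_state_path(model, cfg.n_frames, rng)
    ideal = render_ideal_trace(model, path)
    photo, info = apply_photophysics(ideal, cfg.photophysics, rng)
    lo, hi = _SNR_RANGES[spec["snr"]]
    snr = float(rng.uniform(lo, hi))
    sigma = i_max / snr
    offset = float(rng.uniform(*cfg.noise.offset_fraction_range)) * i_max
    noisy = photo + rng.normal(0.0, sigma, size=photo.shape) + offset

    first = _first_bleach(info["bleach_frame"])
    ideal_fret = model.state_fret[path].copy()
    active = np.ones(cfg.n_frames, dtype=bool)
    if first != NO_BLEACH:
        ideal_fret[first:] = 0.0
        active[first:] = False
    gt = GroundTruth(
        state_path=path,
        ideal_fret=ideal_fret,
        active_mask=active,
        n_states=S,
        snr=snr,
        mean_transition_rate=mean_transition_rate(model),
        bleach_frame=tuple(info["bleach_frame"]),
        n_bleach_steps=tuple(info["n_bleach_steps"]),
        blink_events=info["blink_events"],
        state_fret_values=fret.copy(),
        tau_bleach=tuple(info["tau_bleach"]),
        i_max=i_max,
        one_color=False,
    )
    assert categorize(gt) == label, "targeted sampler left its category"
    return Trace(noisy.astype(np.float32), cfg.frame_period, ground_truth=gt)


def _default_atlas_sim_config(n_frames: int) -> SimulatorConfig:
    from .simulate import PhotophysicsConfig

    # long bleach lifetimes so category-defining dynamics stay visible
    return SimulatorConfig(
        n_frames=n_frames,
        photophysics=PhotophysicsConfig(tau_bleach_range=(500.0, 5000.0)),
    )


def generate_atlas_corpus(
    n_per_category: int,
    cfg: Optional[SimulatorConfig] = None,
    seed: int = 0,
    n_frames: int = 2000,
) -> tuple[list[Trace], list[str]]:
    """A balanced corpus: exactly n_per_category traces per category."""
    cfg = cfg or _default_atlas_sim_config(n_frames)
    rng = np.random.default_rng(seed)
    traces, labels = [], []
    for label in enumerate_categories():
        for _ in range(n_per_category):
            traces.append(sample_category_trace(label, cfg, rng))
            labels.append(label)
    return traces, labels


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

@dataclass
class AtlasCategory:
    label: str
    gmm_weights: np.ndarray      # (4,)
    gmm_means: np.ndarray        # (4, 2)
    gmm_covariances: np.ndarray  # (4, 2, 2)
    contour_level: float = 1e-2
    contours: list = field(default_factory=list)  # list of (M, 2) polylines

    def density(self, points: np.ndarray) -> np.ndarray:
        from scipy.stats import multivariate_normal

        pts = np.atleast_2d(points)
        out = np.zeros(pts.shape[0])
        for w, mu, cov in zip(self.gmm_weights, self.gmm_means,
                              self.gmm_covariances):
            out += w * multivariate_normal.pdf(pts, mean=mu, cov=cov,
                                               allow_singular=True)
        return out


@dataclass
class Atlas:
    reducer: object
    reducer_name: str
    encoder_fingerprint: str
    categories: dict[str, AtlasCategory]
    seed: int
    train_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def transform(self, embeddings: np.ndarray) -> np.ndarray:
        return np.asarray(self.reducer.transform(embeddings))

    # -- persistence: JSON for GMMs, TSV for contours, pickle for reducer --

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "reducer_name": self.reducer_name,
            "encoder_fingerprint": self.encoder_fingerprint,
            "seed": self.seed,
            "categories": {
                lab: {
                    "weights": c.gmm_weights.tolist(),
                    "means": c.gmm_means.tolist(),
                    "covariances": c.gmm_covariances.tolist(),
                    "contour_level": c.contour_level,
                }
                for lab, c in self.categories.items()
            },
        }
        (out / "atlas.json").write_text(json.dumps(meta, indent=1))
        with open(out / "reducer.pkl", "wb") as f:
            pickle.dump(self.reducer, f)
        lines = ["category\tpolyline\tx\ty"]
        for lab, c in self.categories.items():
            for pi, poly in enumerate(c.contours):
                for x, y in poly:
                    lines.append(f"{lab}\t{pi}\t{x:.6g}\t{y:.6g}")
        (out / "contours.tsv").write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, out_dir: str | Path) -> "Atlas":
        out = Path(out_dir)
        meta = json.loads((out / "atlas.json").read_text())
        with open(out / "reducer.pkl", "rb") as f:
            reducer = pickle.load(f)
        cats = {}
        for lab, c in meta["categories"].items():
            cats[lab] = AtlasCategory(
                lab,
                np.asarray(c["weights"]),
                np.asarray(c["means"]),
                np.asarray(c["covariances"]),
                c["contour_level"],
            )
        return cls(reducer, meta["reducer_name"], meta["encoder_fingerprint"],
                   cats, meta["seed"])


def _fit_reducer(embeddings: np.ndarray, reducer: str, seed: int):
    if reducer == "umap":
        try:
            from umap import UMAP

            model = UMAP(n_components=2, random_state=seed)
            coords = model.fit_transform(embeddings)
            return model, coords, "umap"
        except ImportError:
            warnings.warn("umap-learn unavailable; falling back to PCA")
    from sklearn.decomposition import PCA

    model = PCA(n_components=2, random_state=seed)
    coords = model.fit_transform(embeddings)
    return model, coords, "pca"


def _contour_polylines(cat: AtlasCategory, coords: np.ndarray,
                       level: float, n_grid: int = 80) -> list:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pad = 0.1 * (coords.max(axis=0) - coords.min(axis=0) + 1e-9)
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    X, Y = np.meshgrid(xs, ys)
    Z = cat.density(np.column_stack([X.ravel(), Y.ravel()])).reshape(X.shape)
    fig, ax = plt.subplots()
    try:
        cs = ax.contour(X, Y, Z, levels=[level])
        polylines = []
        for path in cs.get_paths():
            for poly in path.to_polygons(closed_only=False):
                if len(poly) > 1:
                    polylines.append(np.asarray(poly))
    finally:
        plt.close(fig)
    return polylines


def build_atlas(
    encoder: Encoder,
    n_fit_per_category: int = 50,
    n_annotate_per_category: int = 50,
    cfg: Optional[SimulatorConfig] = None,
    seed: int = 0,
    reducer: str = "umap",
    contour_level: float = 1e-2,
    n_frames: int = 2000,
) -> Atlas:
    """Fit the global reducer and per-category GMM contours.

    The reducer is fitted unsupervised on a balanced corpus; a second
    balanced corpus (``n_annotate_per_category`` per category, the paper
    used 1,000 at full scale) is projected and fitted with a 4-component
    2-D Gaussian mixture per category; contours are drawn at density
    ``contour_level``.
    """
    from sklearn.mixture import GaussianMixture

    cfg = cfg or _default_atlas_sim_config(n_frames)
    fit_traces, _ = generate_atlas_corpus(n_fit_per_category, cfg, seed,
                                          n_frames)
    ann_traces, ann_labels = generate_atlas_corpus(
        n_annotate_per_category, cfg, seed + 1, n_frames
    )

    fit_emb = np.stack([e.trace_embedding
                        for e in embed_traces(fit_traces, encoder)])
    ann_emb = np.stack([e.trace_embedding
                        for e in embed_traces(ann_traces, encoder)])

    model, fit_coords, name = _fit_reducer(fit_emb, reducer, seed)
    ann_coords = np.asarray(model.transform(ann_emb))

    ann_labels_arr = np.asarray(ann_labels)
    categories: dict[str, AtlasCategory] = {}
    for label in enumerate_categories():
        pts = ann_coords[ann_labels_arr == label]
        if np.allclose(pts.var(axis=0), 0.0):
            raise RuntimeError(
                f"degenerate projection for category {label}: zero variance"
            )
        gmm = GaussianMixture(n_components=4, random_state=seed,
                              covariance_type="full", reg_covar=1e-4)
        gmm.fit(pts)
        cat = AtlasCategory(label, gmm.weights_.copy(), gmm.means_.copy(),
                            gmm.covariances_.copy(), contour_level)
        cat.contours = _contour_polylines(cat, ann_coords, contour_level)
        categories[label] = cat

    return Atlas(model, name, encoder.fingerprint(), categories, seed,
                 train_coords=np.asarray(fit_coords))


def project_into_atlas(
    traces: Sequence[Trace] | np.ndarray,
    atlas: Atlas,
    encoder: Encoder,
) -> dict:
    """Project new traces into atlas coordinates with category densities.

    ``traces`` may also be a pre-computed (N, D) embedding matrix.  Raises
    if the encoder fingerprint does not match the one the atlas was built
    with (embeddings would not be comparable).
    """
    if encoder.fingerprint() != atlas.encoder_fingerprint:
        raise ValueError(
            "encoder fingerprint does not match the atlas; embeddings are "
            "not comparable"
        )
    if isinstance(traces, np.ndarray) and traces.ndim == 2:
        emb = traces
    else:
        if len(traces) == 0:
            return {"coordinates": np.empty((0, 2)),
                    "densities": {}, "best_category": []}
        emb = np.stack([e.trace_embedding
                        for e in embed_traces(traces, encoder)])
    if emb.shape[0] == 0:
        return {"coordinates": np.empty((0, 2)), "densities": {},
                "best_category": []}
    coords = atlas.transform(emb)
    densities = {lab: cat.density(coords)
                 for lab, cat in atlas.categories.items()}
    labs = list(densities)
    stack = np.stack([densities[lab] for lab in labs])
    best = [labs[i] for i in np.argmax(stack, axis=0)]
    return {"coordinates": coords, "densities": densities,
            "best_category": best}
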