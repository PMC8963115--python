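"""Dense-motion features for cybersickness prediction.

A VR scene's rendered frames are reduced to six scalar features of its dense
motion field.  Writing ``m_{n,t}`` for the motion vector of pixel ``n`` in
frame ``t`` (N vectors per frame, T frames):

* ``f1`` — spatio-temporal mean of |m_{n,t}| over all T*N vectors,
* ``f2`` — population variance of |m_{n,t}| about f1,
* ``f3``/``f4`` — mean/variance over the per-frame upper p-th percentile
  sets (the k = floor(N*p) largest magnitudes of each frame),
* ``f5``/``f6`` — the same over the per-frame lower p-th percentile sets,

with p = 10% by default.  Percentile pooling emphasizes the strongest and
weakest motion stimuli, which dominate the perceived quality of experience.
Variances divide by the exact pooled counts (T*N and T*k), matching the
mean-pooling normalizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VisualFeatureVector",
    "FEATURE_NAMES",
    "magnitudes",
    "percentile_sets",
    "extract_features",
    "estimate_flow",
]

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6")


@dataclass(frozen=True)
class VisualFeatureVector:
    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    p: float = 0.10

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4, self.f5, self.f6])


def _as_field(field) -> np.ndarray:
    """Coerce one frame's motion field to an (N, 2) vector array."""
    arr = np.asarray(field, dtype=float)
    if arr.ndim < 2 or arr.shape[-1] != 2:
        raise ValueError("a motion field must have a trailing axis of size 2 (dx, dy)")
    return arr.reshape(-1, 2)


def magnitudes(field) -> np.ndarray:
    """Per-vector magnitudes |m_n| of one frame's motion field, flattened."""
    return np.linalg.norm(_as_field(field), axis=-1)


def percentile_sets(mags, p: float):
    """Index sets of the k = floor(N*p) largest and smallest magnitudes.

    Ties are broken by ascending pixel index, so for constant input both sets
    are the first k indices.  If N*p < 1, k is forced to 1 with a warning.
    """
    mags = np.asarray(mags, dtype=float).ravel()
    n = mags.size
    if not 0 < p < 1:
        raise ValueError("percentile fraction p must lie in (0, 1)")
    k = int(n * p)
    if k < 1:
        warnings.warn(
            f"N*p = {n * p:.3g} < 1; forcing percentile set size k=1", stacklevel=2
        )
        k = 1
    upper = np.argsort(-mags, kind="stable")[:k]
    lower = np.argsort(mags, kind="stable")[:k]
    return upper, lower


def extract_features(fields, p: float = 0.10) -> VisualFeatureVector:
    """Compute the six percentile-pooled motion features from T motion fields.

    ``fields`` is a sequence of per-frame vector arrays (any spatial shape
    with trailing (dx, dy)); all frames must hold the same number of vectors.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("need at least one motion field")
    per_frame = [magnitudes(f) for f in fields]
    n = per_frame[0].size
    if any(m.size != n for m in per_frame):
        raise ValueError("all frames must contain the same number of vectors")
    all_mags = np.concatenate(per_frame)
    f1 = float(all_mags.mean())
    f2 = float(np.mean((all_mags - f1) ** 2))

    upper_vals, lower_vals = [], []
    for m in per_frame:
        up, lo = percentile_sets(m, p)
        upper_vals.append(m[up])
        lower_vals.append(m[lo])
    upper_vals = np.concatenate(upper_vals)
    lower_vals = np.concatenate(lower_vals)
    f3 = float(upper_vals.mean())
    f4 = float(np.mean((upper_vals - f3) ** 2))
    f5 = float(lower_vals.mean())
    f6 = float(np.mean((lower_vals - f5) ** 2))
    return VisualFeatureVector(f1, f2, f3, f4, f5, f6, p=p)


def estimate_flow(frames, backend: str = "ilk", **kwargs):
    """Estimate dense motion fields from a frame sequence.

    Parameters
    ----------
    frames : sequence of 2-D arrays, or precomputed fields for "passthrough"
        T grayscale frames of equal shape (T >= 2).
    backend : {"ilk", "tvl1", "passthrough"}
        "ilk" (default) is an iterative Lucas-Kanade dense estimator; "tvl1"
        is a total-variation L1 estimator (slower, more accurate on large
        displacements).  "passthrough" returns the input unchanged so that
        feature computation can run on exact ground-truth fields.

    Returns
    -------
    list of (H, W, 2) arrays, one per consecutive frame pair (T-1 fields),
    with vectors ordered (dx, dy) in pixel units: the displacement of scene
    content from frame t to frame t+1.
    """
    if backend == "passthrough":
        return [np.asarray(f, dtype=float) for f in frames]
    if backend not in {"ilk", "tvl1"}:
        raise ValueError(f"unknown flow backend {backend!r}")
    from skimage import registration

    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share the same dimensions")
    if any(f.ndim != 2 for f in frames):
        raise ValueError("frames must be 2-D grayscale arrays")

    func = registration.optical_flow_ilk if backend == "ilk" else registration.optical_flow_tvl1
    fields = []
    for ref, moving in zip(frames[:-1], frames[1:]):
        # skimage returns (row, col) displacements that map `ref` coordinates
        # onto the matching content in `moving`, i.e. the forward motion of
        # the scene; reorder to (dx, dy).
        v = func(ref, moving, **kwargs)
        field = np.stack([v[1], v[0]], axis=-1)
        fields.append(field)
    return fields
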