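"""Spatial conditioning of depth-resolved immunofluorescence samples.

Each sampled region of interest (ROI) carries a tissue-layer index
(0 basal, 1 spinous/granular, 2 transitional) and its minimum distances to
the deep (d1) and superficial (d2) boundaries of that layer.  The
layer-normalized distance u = i_layer + d1/(d1+d2) places every sample on
a common [0, 3] ordinate that follows the keratinocyte differentiation
gradient while absorbing variation in absolute layer thickness.

Because the layers hold roughly 1 : 4 : 2 cells, u is further mapped to a
model depth d in [0, 7] (one unit per cell) and binned into 7 coarse or 28
fine spatial partitions.  Intensities are z-scored per patient (per target
and compartment, since each was a separate labeling experiment), smoothed
per layer with a local quadratic (loess) fit, and aggregated to
per-partition means for the association statistics and model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateGroupError,
    DegeneratePositionError,
    DomainError,
    EmptyInputError,
    InsufficientDataError,
)

__all__ = [
    "PartitionProfile",
    "SmoothedProfile",
    "layer_normalized_distance",
    "condition_samples",
    "to_model_depth",
    "assign_partition",
    "zscore_per_patient",
    "loess_fit",
    "loess_profile",
    "partition_aggregate",
]

ROI_COLUMNS = ["patient", "target", "compartment", "layer_index", "d1", "d2", "intensity"]

SCHEME_SIZES = {"coarse7": 7, "fine28": 28}

#: depth units spanned per tissue layer in the coarse scheme (1:4:2 cells)
_LAYER_SPANS = np.array([1.0, 4.0, 2.0])
_LAYER_OFFSETS = np.array([0.0, 1.0, 5.0])


@dataclass
class PartitionProfile:
    """Mean z-scored intensity per discrete spatial partition.

    ``values`` holds NaN where a partition received no samples; ``counts``
    records per-partition sample counts.  ``patient`` is ``"all"`` for
    profiles aggregated across patients.
    """

    scheme: str
    values: np.ndarray
    counts: np.ndarray
    target: str = ""
    compartment: str = ""
    patient: str = "all"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_SIZES:
            raise DomainError(f"unknown partition scheme {self.scheme!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        n = SCHEME_SIZES[self.scheme]
        if self.values.shape != (n,) or self.counts.shape != (n,):
            raise DomainError(
                f"profile length must be {n} for scheme {self.scheme!r}"
            )
        if np.any(self.counts < 0):
            raise DomainError("partition counts must be nonnegative")

    @property
    def n_partitions(self) -> int:
        return SCHEME_SIZES[self.scheme]

    @property
    def label(self) -> str:
        return f"{self.target}/{self.compartment}"


@dataclass
class SmoothedProfile:
    """Loess-fitted intensity curve on a strictly increasing u grid."""

    u: np.ndarray
    fitted: np.ndarray
    span: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.fitted = np.asarray(self.fitted, dtype=float)
        if np.any(np.diff(self.u) <= 0):
            raise DomainError("smoothed-profile grid must be strictly increasing")
        if not np.all(np.isfinite(self.fitted)):
            raise DomainError("smoothed-profile values must be finite")


def layer_normalized_distance(layer_index, d1, d2):
    """u = i_layer + d1 / (d1 + d2), the layer-normalized distance in [0, 3].

    ``d1`` is the distance to the deep boundary, ``d2`` to the superficial
    boundary of the sample's tissue layer; linear interpolation between the
    two places the sample fractionally within its layer.
    """
    layer_index = np.asarray(layer_index)
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(~np.isin(layer_index, (0, 1, 2))):
        raise DomainError("layer_index must be 0, 1 or 2")
    if np.any(d1 < 0) or np.any(d2 < 0):
        raise DomainError("boundary distances must be nonnegative")
    tot = d1 + d2
    if np.any(tot == 0):
        raise DegeneratePositionError("d1 + d2 == 0: position within layer undefined")
    u = layer_index + d1 / tot
    return u if u.ndim else float(u)


def to_model_depth(u):
    """Map layer-normalized distance u in [0,3] to model depth d in [0,7].

    Piecewise linear with slopes 1, 4, 2 over the basal, spinous/granular
    and transitional layers, so that each layer spans a number of depth
    units equal to its relative cell count (1:4:2).  Continuous and
    strictly increasing; u = 0,1,2,3 map to d = 0,1,5,7.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 3.0):
        raise DomainError(f"layer-normalized distance must lie in [0, 3], got {u}")
    layer = np.clip(np.floor(u).astype(int), 0, 2)
    d = _LAYER_OFFSETS[layer] + _LAYER_SPANS[layer] * (u - layer)
    return d if d.ndim else float(d)


def assign_partition(u, scheme: str = "coarse7"):
    """Bin a layer-normalized distance into a discrete spatial partition.

    Partitions are left-closed/right-open intervals [k-1, k) in model
    depth (fine: [(k-1)/4, k/4)); the superficial limit d = 7 belongs to
    the last partition.  coarse7 assigns basal samples to partition 1,
    spinous/granular to 2-5 and transitional to 6-7; fine28 is the same
    construction at 4x resolution (1-4 / 5-20 / 21-28).
    """
    if scheme not in SCHEME_SIZES:
        raise DomainError(f"unknown partition scheme {scheme!r}")
    n = SCHEME_SIZES[scheme]
    d = np.asarray(to_model_depth(u), dtype=float)
    part = np.minimum(np.floor(d * (n / 7.0)).astype(int) + 1, n)
    return part if part.ndim else int(part)


def condition_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Full conditioning: add the layer-normalized ordinate and z-scores.

    Takes a raw ROI table (columns ``patient, target, compartment,
    layer_index, d1, d2, intensity``) and returns it with ``u`` (layer-
    normalized distance) and ``z`` (per patient/target/compartment z-score)
    columns appended.
    """
    out = samples.copy()
    out["u"] = layer_normalized_distance(
        out["layer_index"].to_numpy(),
        out["d1"].to_numpy(dtype=float),
        out["d2"].to_numpy(dtype=float),
    )
    return zscore_per_patient(out)


def zscore_per_patient(samples: pd.DataFrame) -> pd.DataFrame:
    """Z-score intensities within each patient x target x compartment group.

    Each immunolabeling experiment (one patient, one target, one
    compartment) has its own arbitrary intensity scale, so groups are
    standardized independently: the returned ``z`` column has mean 0 and
    sample SD 1 (ddof=1) within every group.  Raises on groups with fewer
    than two samples or zero variance.
    """
    out = samples.copy()
    z = np.empty(len(out), dtype=float)
    for key, idx in out.groupby(["patient", "target", "compartment"]).indices.items():
        vals = out["intensity"].to_numpy()[idx]
        if len(vals) < 2:
            raise DegenerateGroupError(f"group {key} has fewer than 2 samples")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise DegenerateGroupError(f"group {key} has zero variance")
        z[idx] = (vals - vals.mean()) / sd
    out["z"] = z
    return out


def loess_fit(x, y, x_eval, span: float = 0.25, degree: int = 2):
    """Locally weighted polynomial regression (loess) at the given points.

    For each evaluation point the nearest ceil(span * n) samples receive
    tricube weights and a degree-``degree`` polynomial is fitted by
    weighted least squares; near the edges the neighborhood simply extends
    inward, which keeps the fit well-posed without extrapolation.  With
    span = 1 the fit reproduces any polynomial of the local degree exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    n = x.size
    k = max(degree + 2, int(np.ceil(span * n)))
    if n < k or n < degree + 2:
        raise InsufficientDataError(
            f"need at least {max(k, degree + 2)} points for span={span}, got {n}"
        )
    fitted = np.empty(x_eval.size)
    for j, x0 in enumerate(x_eval):
        dist = np.abs(x - x0)
        neighbors = np.argpartition(dist, k - 1)[:k]
        h = dist[neighbors].max()
        if h == 0:
            fitted[j] = y[neighbors].mean()
            continue
        w = (1.0 - np.minimum(dist[neighbors] / h, 1.0) ** 3) ** 3
        # guard: points exactly at distance h get zero weight; keep a floor
        if w.sum() == 0 or np.count_nonzero(w) <= degree:
            w = w + 1e-9
        t = x[neighbors] - x0  # center for conditioning
        design = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[neighbors] * sw, rcond=None)
        fitted[j] = coef[0]
    return fitted


def loess_profile(
    samples: pd.DataFrame,
    span: float = 0.25,
    degree: int = 2,
    points_per_layer: int = 40,
) -> SmoothedProfile:
    """Loess-smooth conditioned samples separately within each tissue layer.

    Expects ``u`` and ``z`` columns.  Each layer present in the data is
    fitted on its own grid spanning that layer's observed u range (never
    extrapolating beyond it); the per-layer curves are concatenated.
    """
    if not 0.0 < span <= 1.0:
        raise DomainError("span must lie in (0, 1]")
    u = samples["u"].to_numpy(dtype=float)
    z = samples["z"].to_numpy(dtype=float)
    layer = np.clip(np.floor(u).astype(int), 0, 2)
    grids, fits = [], []
    for li in sorted(np.unique(layer)):
        mask = layer == li
        ul, zl = u[mask], z[mask]
        if ul.size < max(5, int(np.ceil(span * ul.size))):
            raise InsufficientDataError(
                f"layer {li} has only {ul.size} samples; too few to smooth"
            )
        grid = np.linspace(ul.min(), ul.max(), points_per_layer)
        grids.append(grid)
        fits.append(loess_fit(ul, zl, grid, span=span, degree=degree))
    u_all = np.concatenate(grids)
    f_all = np.concatenate(fits)
    # layer grids may touch at shared boundaries; keep the grid strictly increasing
    order = np.argsort(u_all, kind="stable")
    u_all, f_all = u_all[order], f_all[order]
    keep = np.concatenate([[True], np.diff(u_all) > 0])
    return SmoothedProfile(u=u_all[keep], fitted=f_all[keep], span=span)


def partition_aggregate(
    samples: pd.DataFrame,
    scheme: str = "fine28",
    per_patient: bool = False,
) -> list[PartitionProfile]:
    """Aggregate conditioned samples to per-partition mean z profiles.

    Returns one :class:`PartitionProfile` per target/compartment (and per
    patient when ``per_patient``).  Empty partitions are flagged with
    count 0 and NaN value; they are never imputed.
    """
    if len(samples) == 0:
        raise EmptyInputError("no samples to aggregate")
    n = SCHEME_SIZES[scheme]
    df = samples.copy()
    df["partition"] = assign_partition(df["u"].to_numpy(dtype=float), scheme)
    keys = ["target", "compartment"] + (["patient"] if per_patient else [])
    profiles = []
    for key, grp in df.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        values = np.full(n, np.nan)
        counts = np.zeros(n, dtype=int)
        agg = grp.groupby("partition")["z"]
        means, sizes = agg.mean(), agg.size()
        values[means.index.to_numpy() - 1] = means.to_numpy()
        counts[sizes.index.to_numpy() - 1] = sizes.to_numpy()
        profiles.append(
            PartitionProfile(
                scheme=scheme,
                values=values,
                counts=counts,
                target=str(key[0]),
                compartment=str(key[1]),
                patient=str(key[2]) if per_patient else "all",
            )
        )
    return profiles
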