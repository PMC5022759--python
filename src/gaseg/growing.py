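"""Seeded region growing with incrementally updated region statistics.

A region starts from a single seed pixel: the region mean is the seed
intensity and the standard deviation is zero.  The frontier is explored
breadth-first; a candidate pixel ``p`` is accepted into the region when

    |I_p - mu_region| <= max(k_sigma * sigma_region, t_min)

where ``mu_region`` and ``sigma_region`` are the running mean and
standard deviation over the pixels accepted so far.  On every acceptance
the statistics are updated incrementally (Welford's recurrence, see
:func:`update_stats`).  The floor tolerance ``t_min`` breaks the
cold-start deadlock right after the seed, when sigma is still zero.

Growth terminates when the frontier is empty: the class is complete and
no further point can be added.  A full segmentation grows one region per
tissue class sequentially; each later class is restricted to pixels not
yet claimed by an earlier one.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, DataError, SeedError

Coord = Tuple[int, int]

#: Neighbor offsets per neighborhood system, in row-major order.
NEIGHBORHOOD_OFFSETS: Dict[str, Tuple[Coord, ...]] = {
    "four": ((-1, 0), (0, -1), (0, 1), (1, 0)),
    "diagonal-four": ((-1, -1), (-1, 1), (1, -1), (1, 1)),
    "eight": (
        (-1, -1), (-1, 0), (-1, 1),
        (0, -1), (0, 1),
        (1, -1), (1, 0), (1, 1),
    ),
}

_NEIGHBORHOOD_ALIASES = {
    "four": "four", "4": "four",
    "diagonal-four": "diagonal-four", "d4": "diagonal-four",
    "diag4": "diagonal-four",
    "eight": "eight", "8": "eight",
}


def canonical_neighborhood(name: str) -> str:
    try:
        return _NEIGHBORHOOD_ALIASES[str(name).lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown neighborhood {name!r}; choose from 4, d4, 8"
        ) from None


@dataclass(frozen=True)
class GrowConfig:
    """Parameters of the growing criterion.

    ``k_sigma`` scales the running standard deviation in the acceptance
    band; ``t_min`` is a floor tolerance in intensity units that keeps
    the band open while sigma is still zero.  ``class_order`` fixes the
    sequence in which classes are grown; earlier classes claim contested
    pixels first.
    """

    neighborhood: str = "eight"
    k_sigma: float = 2.5
    t_min: float = 10.0
    class_order: Tuple[int, ...] = (1, 2, 3)

    def validate(self) -> None:
        canonical_neighborhood(self.neighborhood)
        if self.k_sigma < 0 or self.t_min < 0:
            raise ConfigurationError(
                f"k_sigma and t_min must be >= 0, got {self.k_sigma}, {self.t_min}"
            )
        if len(self.class_order) == 0 or len(set(self.class_order)) != len(
                self.class_order) or 0 in self.class_order:
            raise ConfigurationError(
                f"class_order must be distinct non-zero labels, got {self.class_order}"
            )

    def to_dict(self) -> dict:
        return {
            "neighborhood": canonical_neighborhood(self.neighborhood),
            "k_sigma": float(self.k_sigma),
            "t_min": float(self.t_min),
            "class_order": list(self.class_order),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GrowConfig":
        return cls(
            neighborhood=str(d.get("neighborhood", "eight")),
            k_sigma=float(d.get("k_sigma", 2.5)),
            t_min=float(d.get("t_min", 10.0)),
            class_order=tuple(int(c) for c in d.get("class_order", (1, 2, 3))),
        )


@dataclass(frozen=True)
class RegionState:
    """Running statistics of one growing region.

    ``disp`` is the accumulated sum of squared deviations from the mean
    (Welford's M2), so ``variance = disp / n`` (population convention:
    the region *is* the population of accepted pixels).  A fresh region
    holds only its seed: ``n = 1``, ``mean`` equals the seed intensity
    and the standard deviation is zero.
    """

    label: int
    n: int
    mean: float
    disp: float

    @classmethod
    def from_seed(cls, label: int, intensity: float) -> "RegionState":
        if not np.isfinite(intensity):
            raise DataError(f"non-finite seed intensity {intensity!r}")
        return cls(label=label, n=1, mean=float(intensity), disp=0.0)

    @property
    def variance(self) -> float:
        return self.disp / self.n

    @property
    def std(self) -> float:
        return float(np.sqrt(self.variance))


def update_stats(state: RegionState, intensity: float,
                 scheme: str = "welford") -> RegionState:
    """Fold one accepted intensity into the region statistics.

    The default scheme is Welford's numerically stable recurrence::

        n       <- n + 1
        delta    = I - mean
        mean    <- mean + delta / n
        disp    <- disp + delta * (I - mean)

    which keeps ``mean`` equal to the arithmetic mean of all accepted
    intensities and ``disp / n`` equal to their population variance.

    ``scheme="printed"`` instead applies the raw recurrence
    ``V_n = ((n-2) V_{n-1} + I_n) / n`` to the ``disp`` field.  That
    recurrence mixes intensity and intensity-squared units and does not
    produce a variance; it is retained only for comparison and is never
    used by the grower.

    The input state is left unmodified; a new state is returned.
    """
    if not np.isfinite(intensity):
        raise DataError(f"non-finite intensity {intensity!r}")
    if state.n < 1:
        raise DataError("region state must contain at least the seed")
    n = state.n + 1
    if scheme == "welford":
        delta = intensity - state.mean
        mean = state.mean + delta / n
        disp = state.disp + delta * (intensity - mean)
    elif scheme == "printed":
        mean = ((n - 1) * state.mean + intensity) / n
        disp = ((n - 2) * state.disp + intensity) / n
    else:
        raise ConfigurationError(f"unknown update scheme {scheme!r}")
    return replace(state, n=n, mean=mean, disp=disp)


def neighbors(coord: Coord, neighborhood: str,
              shape: Tuple[int, int]) -> Tuple[Coord, ...]:
    """In-bounds neighbors of ``coord``, in row-major order.

    Never contains ``coord`` itself and never contains duplicates.  The
    four- and diagonal-four systems partition the eight-neighborhood.
    """
    r, c = coord
    rows, cols = shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise DataError(f"coordinate {coord} outside grid {shape}")
    offsets = NEIGHBORHOOD_OFFSETS[canonical_neighborhood(neighborhood)]
    return tuple(
        (r + dr, c + dc)
        for dr, dc in offsets
        if 0 <= r + dr < rows and 0 <= c + dc < cols
    )


def _as_float_image(image: np.ndarray) -> np.ndarray:
    arr = np.ascontiguousarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise DataError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise DataError("image contains non-finite values")
    return arr


def grow_region(image: np.ndarray, seed: Coord, config: GrowConfig,
                eligible: Optional[np.ndarray] = None,
                label: int = 1,
                frozen_stats: bool = False,
                ) -> Tuple[np.ndarray, RegionState]:
    """Grow one region from ``seed`` and return its mask and statistics.

    The frontier is a FIFO queue; when a pixel is accepted its in-bounds,
    eligible, not-yet-queued neighbors are enqueued in row-major offset
    order, which makes the traversal (and hence the result under live
    statistics) fully deterministic.  A pixel rejected once is not
    reconsidered for this region.

    With ``frozen_stats=True`` the acceptance band is evaluated against
    the seed statistics (mean = seed intensity, sigma = 0) for the whole
    growth, so the region is exactly the connected flood fill of
    ``|I - I_seed| <= t_min`` around the seed; the returned
    :class:`RegionState` still carries the live statistics of the
    accepted pixels.
    """
    config.validate()
    arr = _as_float_image(image)
    rows, cols = arr.shape
    r0, c0 = int(seed[0]), int(seed[1])
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise SeedError(f"seed {seed} outside image of shape {arr.shape}")
    if eligible is None:
        elig = np.ones(arr.shape, dtype=bool)
    else:
        elig = np.asarray(eligible, dtype=bool)
        if elig.shape != arr.shape:
            raise DataError("eligibility mask shape does not match image")
    if not elig[r0, c0]:
        raise SeedError(f"seed {seed} is not eligible")

    flat = arr.ravel()
    elig_flat = elig.ravel()
    offsets = NEIGHBORHOOD_OFFSETS[canonical_neighborhood(config.neighborhood)]

    mask = np.zeros(rows * cols, dtype=bool)
    queued = np.zeros(rows * cols, dtype=bool)
    idx0 = r0 * cols + c0
    mask[idx0] = True
    queued[idx0] = True

    # local scalars for the hot loop; packaged into RegionState at the end
    n = 1
    mean = flat[idx0]
    m2 = 0.0
    k_sigma = float(config.k_sigma)
    t_min = float(config.t_min)
    seed_mean = mean

    queue: deque = deque()
    for dr, dc in offsets:
        rr, cc = r0 + dr, c0 + dc
        if 0 <= rr < rows and 0 <= cc < cols:
            j = rr * cols + cc
            if elig_flat[j] and not queued[j]:
                queued[j] = True
                queue.append(j)

    while queue:
        j = queue.popleft()
        x = flat[j]
        if frozen_stats:
            tol = t_min
            ref_mean = seed_mean
        else:
            tol = max(k_sigma * np.sqrt(m2 / n), t_min)
            ref_mean = mean
        if abs(x - ref_mean) > tol:
            continue
        mask[j] = True
        n += 1
        delta = x - mean
        mean += delta / n
        m2 += delta * (x - mean)
        r, c = divmod(j, cols)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                jj = rr * cols + cc
                if elig_flat[jj] and not queued[jj]:
                    queued[jj] = True
                    queue.append(jj)

    state = RegionState(label=label, n=n, mean=float(mean), disp=float(m2))
    return mask.reshape(rows, cols), state


def _seed_items(seeds, class_order: Sequence[int]):
    """Normalize ``seeds`` to ``[(class, [coords...]), ...]`` in class order."""
    if hasattr(seeds, "coords_by_class"):
        mapping = seeds.coords_by_class()
    elif isinstance(seeds, Mapping):
        mapping = seeds
    else:
        raise ConfigurationError(
            "seeds must be a mapping class -> coordinate(s) or a SeedSet"
        )
    items = []
    for c in class_order:
        if c not in mapping:
            raise SeedError(f"no seed given for class {c}")
        value = mapping[c]
        if len(value) == 2 and np.isscalar(value[0]):
            coords = [tuple(int(v) for v in value)]
        else:
            coords = [tuple(int(v) for v in p) for p in value]
        items.append((c, coords))
    all_coords = [p for _, coords in items for p in coords]
    if len(set(all_coords)) != len(all_coords):
        raise SeedError(f"seed coordinates must be pairwise distinct: {all_coords}")
    return items


def segment(image: np.ndarray, seeds, config: GrowConfig) -> np.ndarray:
    """Sequential multi-class region growing.

    Classes are grown in ``config.class_order``; each class is restricted
    to pixels not claimed by an earlier class, so pixels are assigned at
    most once and contested pixels go to the class grown first.  Pixels
    never accepted by any class stay 0 (background).  A seed swallowed by
    an earlier class yields an empty region for its own class rather than
    an error, so supervised seed search remains well-defined on noisy
    images.

    ``seeds`` maps each class label to one coordinate or a list of
    coordinates (multiple seeds grow independent sub-regions that share
    the class label).
    """
    config.validate()
    arr = _as_float_image(image)
    labels = np.zeros(arr.shape, dtype=np.int32)
    for c, coords in _seed_items(seeds, config.class_order):
        for coord in coords:
            r, s = int(coord[0]), int(coord[1])
            if not (0 <= r < arr.shape[0] and 0 <= s < arr.shape[1]):
                raise SeedError(f"seed {coord} outside image of shape {arr.shape}")
            if labels[r, s] != 0:
                continue  # claimed by an earlier class: empty region
            mask, _ = grow_region(arr, coord, config,
                                  eligible=(labels == 0), label=c)
            labels[mask] = c
    return labels
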