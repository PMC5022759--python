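"""Synthetic brain phantoms with exact tissue ground truth.

Emulates the kind of simulated T1-weighted slices distributed by public
simulated-MRI databases: piecewise-constant tissue classes (cerebrospinal
fluid, gray matter, white matter over a dark background) with distinct
mean intensities, additive Gaussian noise, and an optional smooth
multiplicative intensity non-uniformity ("bias") field.  Every phantom
comes with the exact per-class label masks used to paint it, so
segmentation quality can be scored against a known truth.

Two geometries are provided:

``nested-ellipses``
    A CSF ring around a GM ring around a WM core, mimicking the
    coarse cortical topology of an axial slice.  Fully deterministic
    and analytically checkable (point-in-ellipse tests).

``voronoi-blobs``
    Tissue classes assigned to randomly-sited Voronoi cells, for
    irregular region shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from .errors import ConfigurationError, DataError

BACKGROUND = 0
CSF = 1
GM = 2
WM = 3

TISSUE_CLASSES: Tuple[int, int, int] = (CSF, GM, WM)

CLASS_NAMES: Dict[int, str] = {
    BACKGROUND: "background",
    CSF: "csf",
    GM: "gm",
    WM: "wm",
}

#: Default class mean intensities on a 0-255 scale.  The ordering
#: CSF < GM < WM matches T1-weighted appearance.
DEFAULT_CLASS_MEANS: Dict[int, float] = {
    BACKGROUND: 0.0,
    CSF: 60.0,
    GM: 120.0,
    WM: 200.0,
}

#: Semi-axis lengths of the nested ellipses as fractions of the image
#: side lengths: class -> (row fraction, column fraction).  The ellipse
#: for a class contains the ellipses of all brighter classes; the ring
#: between consecutive ellipses belongs to the dimmer class.
NESTED_ELLIPSE_FRACTIONS: Dict[int, Tuple[float, float]] = {
    CSF: (0.45, 0.42),
    GM: (0.36, 0.33),
    WM: (0.22, 0.20),
}

#: Number of Voronoi sites drawn per tissue class in voronoi-blobs mode.
VORONOI_SITES_PER_CLASS = 3

GEOMETRIES = ("nested-ellipses", "voronoi-blobs")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic phantom.

    Parameters
    ----------
    shape
        Image shape ``(rows, cols)``; both dimensions must be >= 8.
    class_means
        Mean intensity per class label (arbitrary units, default 0-255
        scale).  All means must be distinct.
    noise_sigma
        Standard deviation of the additive Gaussian noise, in intensity
        units (>= 0).
    bias_amplitude
        Relative amplitude of the smooth multiplicative intensity
        non-uniformity field; the field spans ``1 +/- bias_amplitude``.
    geometry
        ``"nested-ellipses"`` or ``"voronoi-blobs"``.
    rng_seed
        Seed for all randomness (noise, bias coefficients, Voronoi
        sites).  Identical specs produce bit-identical phantoms.
    """

    shape: Tuple[int, int] = (128, 128)
    class_means: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    geometry: str = "nested-ellipses"
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 2 or any(int(s) < 8 for s in self.shape):
            raise ConfigurationError(
                f"phantom shape must be 2-D with dims >= 8, got {self.shape!r}"
            )
        means = [float(self.class_means[c]) for c in (BACKGROUND, *TISSUE_CLASSES)]
        if len(set(means)) != len(means):
            raise ConfigurationError(
                f"class means must be pairwise distinct, got {means!r}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.bias_amplitude < 0:
            raise ConfigurationError(
                f"bias_amplitude must be >= 0, got {self.bias_amplitude}"
            )
        if self.geometry not in GEOMETRIES:
            raise ConfigurationError(
                f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}"
            )

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "class_means": {str(k): float(v) for k, v in self.class_means.items()},
            "noise_sigma": float(self.noise_sigma),
            "bias_amplitude": float(self.bias_amplitude),
            "geometry": self.geometry,
            "rng_seed": int(self.rng_seed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomSpec":
        return cls(
            shape=tuple(int(s) for s in d.get("shape", (128, 128))),
            class_means={int(k): float(v) for k, v in d.get(
                "class_means", DEFAULT_CLASS_MEANS).items()},
            noise_sigma=float(d.get("noise_sigma", 0.0)),
            bias_amplitude=float(d.get("bias_amplitude", 0.0)),
            geometry=str(d.get("geometry", "nested-ellipses")),
            rng_seed=int(d.get("rng_seed", 0)),
        )


@dataclass
class ReferenceSegmentation:
    """Per-class binary tissue masks sharing one image grid.

    ``masks`` maps class label -> boolean array.  Background is implicit:
    a pixel belonging to no mask is background.  Masks are pairwise
    disjoint.
    """

    masks: Dict[int, np.ndarray]

    def validate(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise DataError(f"reference masks disagree on shape: {shapes}")
        total = np.zeros(next(iter(shapes)), dtype=np.int64)
        for c, m in self.masks.items():
            if m.dtype != bool:
                raise DataError(f"mask for class {c} is not boolean")
            if not m.any():
                raise DataError(f"mask for class {c} is empty")
            total += m
        if total.max() > 1:
            raise DataError("reference class masks overlap")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def label_map(self) -> np.ndarray:
        """Collapse the masks into one integer label image (0 = background)."""
        labels = np.zeros(self.shape, dtype=np.int32)
        for c, m in self.masks.items():
            labels[m] = c
        return labels

    @classmethod
    def from_label_map(cls, labels: np.ndarray,
                       classes: Tuple[int, ...] = TISSUE_CLASSES
                       ) -> "ReferenceSegmentation":
        return cls(masks={c: np.asarray(labels) == c for c in classes})


def nested_ellipse_labels(shape: Tuple[int, int]) -> np.ndarray:
    """Label map for the nested-ellipses geometry.

    The ellipses share the grid center ``((rows-1)/2, (cols-1)/2)``; the
    semi-axes are ``NESTED_ELLIPSE_FRACTIONS[c] * (rows, cols)``.  A pixel
    gets the innermost class whose ellipse contains it.
    """
    rows, cols = shape
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc_grid = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    labels = np.zeros(shape, dtype=np.int32)
    # paint outermost first so inner classes overwrite
    for c in (CSF, GM, WM):
        fr, fc = NESTED_ELLIPSE_FRACTIONS[c]
        a, b = fr * rows, fc * cols
        inside = ((rr - cr) / a) ** 2 + ((cc_grid - cc) / b) ** 2 <= 1.0
        labels[inside] = c
    return labels


def voronoi_labels(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Label map from nearest-site assignment over random per-class sites."""
    rows, cols = shape
    sites = []
    site_class = []
    for c in TISSUE_CLASSES:
        pts = np.column_stack([
            rng.uniform(0, rows, VORONOI_SITES_PER_CLASS),
            rng.uniform(0, cols, VORONOI_SITES_PER_CLASS),
        ])
        sites.append(pts)
        site_class.extend([c] * VORONOI_SITES_PER_CLASS)
    sites = np.vstack(sites)
    site_class = np.asarray(site_class, dtype=np.int32)
    rr, cc_grid = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr.ravel(), cc_grid.ravel()], axis=1).astype(float)
    d2 = ((coords[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    labels = site_class[np.argmin(d2, axis=1)].reshape(shape)
    return labels


def bias_field(shape: Tuple[int, int], amplitude: float,
               rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative intensity non-uniformity field.

    A second-order polynomial surface in normalized coordinates, rescaled
    so the field spans exactly ``1 +/- amplitude``.  With ``amplitude``
    0 a field of ones is returned (and no random draws are consumed).
    """
    if amplitude == 0:
        return np.ones(shape)
    rows, cols = shape
    u = np.linspace(-1.0, 1.0, rows)[:, None]
    v = np.linspace(-1.0, 1.0, cols)[None, :]
    c = rng.uniform(-1.0, 1.0, size=5)
    p = c[0] * u + c[1] * v + c[2] * u * v + c[3] * u ** 2 + c[4] * v ** 2
    span = np.abs(p).max()
    if span > 0:
        p = p / span
    return 1.0 + amplitude * p


def generate_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, ReferenceSegmentation]:
    """Render a phantom image and its exact reference segmentation.

    The image is the class-mean raster, multiplied by the bias field,
    plus i.i.d. Gaussian noise of standard deviation ``noise_sigma``.
    With ``noise_sigma == 0`` and ``bias_amplitude == 0`` every pixel
    equals its class mean exactly.  Intensities are float64 and are not
    clipped; writers quantize as needed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    if spec.geometry == "nested-ellipses":
        labels = nested_ellipse_labels(spec.shape)
    else:
        labels = voronoi_labels(spec.shape, rng)
    means = np.zeros(max(spec.class_means) + 1)
    for c, m in spec.class_means.items():
        means[c] = m
    image = means[labels].astype(np.float64)
    image *= bias_field(spec.shape, spec.bias_amplitude, rng)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    ref = ReferenceSegmentation.from_label_map(labels)
    ref.validate()
    return image, ref
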