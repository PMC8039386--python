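"""Synthetic layered gastric-wall phantoms.

Real oral contrast-enhanced ultrasound shows the gastric wall as five
alternating echogenic bands (mucosa, muscularis mucosa, submucosa,
muscularis propria, serosa) embedded in the darker, contrast-filled
lumen.  This module renders that geometry as a piecewise-constant
template -- a horizontal, optionally bowed, five-band wall -- and
corrupts it with fully developed multiplicative speckle, so that wall
detection, SRAD filtering, stratification and screening can all be
exercised against a known ground truth.

The speckle model is unit-mean gamma noise parameterised by the number
of ``looks`` L: pixel intensity is template x Gamma(L, 1/L), giving
E[noise] = 1 and Var[noise] = 1/L.  L=1 is raw fully developed speckle
(coefficient of variation 1); larger L emulates spatial compounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GastrolayerError, LayerTooThinError

#: Cohort-average layer proportions of a normal wall (mucosa, muscularis
#: mucosa, submucosa, muscularis propria, serosa).  Used as the default
#: normal template; note the tabulated rounding makes it sum to 0.999.
NORMAL_PROPORTIONS = (0.278, 0.133, 0.154, 0.154, 0.280)

#: The same template renormalised to sum exactly to 1, as the phantom
#: geometry requires.
DEFAULT_WALL_PROPORTIONS = tuple(p / sum(NORMAL_PROPORTIONS) for p in NORMAL_PROPORTIONS)

#: Default mean echogenicities for the five bands, alternating
#: bright/dark/bright/dark/bright.  Which anatomical layers are
#: hyperechoic is scanner- and preparation-dependent, so this is a
#: parameter, not a fixed truth.
DEFAULT_LAYER_LEVELS = (200.0, 80.0, 180.0, 70.0, 190.0)

DEFAULT_BACKGROUND_LEVEL = 40.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, echogenicity and noise parameters of one phantom.

    ``curvature`` is the number of pixels of vertical bowing across the
    image width (0 gives a flat wall); the bow follows a half-period
    cosine bump, zero at both lateral edges and maximal at the centre.
    """

    height: int = 256
    width: int = 192
    wall_top_row: int = 60
    wall_thickness: int = 120
    proportions: tuple[float, ...] = DEFAULT_WALL_PROPORTIONS
    layer_levels: tuple[float, ...] = DEFAULT_LAYER_LEVELS
    background_level: float = DEFAULT_BACKGROUND_LEVEL
    speckle_looks: int | None = 4  # None disables noise entirely
    curvature: int = 0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (5,):
            raise GastrolayerError("proportions must have 5 components")
        if (p < 0).any():
            raise GastrolayerError("proportions must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise GastrolayerError(f"proportions must sum to 1, got {p.sum():.12f}")
        levels = np.asarray(self.layer_levels, dtype=float)
        if levels.shape != (5,):
            raise GastrolayerError("layer_levels must have 5 components")
        if (levels <= 0).any() or self.background_level <= 0:
            raise GastrolayerError("all echogenicity levels must be > 0")
        if self.wall_top_row + self.wall_thickness + max(self.curvature, 0) > self.height:
            raise GastrolayerError("wall (plus bowing) does not fit inside the image")
        if self.speckle_looks is not None and self.speckle_looks < 1:
            raise GastrolayerError("speckle_looks must be >= 1 (or None for no noise)")


@dataclass
class PhantomTruth:
    """A generated phantom with its full ground truth.

    ``boundary_rows`` has shape (4, width): for each column, the first
    row of layers 2..5 (half-open convention -- layer k occupies rows
    [b_{k-1}, b_k)).  ``wall_top``/``wall_bottom`` are per-column
    (width,) arrays delimiting the whole band, half-open.
    """

    image: np.ndarray
    wall_mask: np.ndarray
    boundary_rows: np.ndarray
    wall_top: np.ndarray
    wall_bottom: np.ndarray
    proportions: np.ndarray
    label: str = "normal"
    spec: PhantomSpec | None = None


def layer_thicknesses(proportions, wall_thickness: int) -> np.ndarray:
    """Integer per-layer thicknesses for a wall of ``wall_thickness`` rows.

    The first four layers are rounded half-up; the deepest layer absorbs
    the (possibly negative) remainder so the band totals exactly
    ``wall_thickness`` rows.
    """
    p = np.asarray(proportions, dtype=float)
    t = np.empty(5, dtype=int)
    t[:4] = np.floor(p[:4] * wall_thickness + 0.5).astype(int)
    t[4] = wall_thickness - t[:4].sum()
    if (t < 1).any():
        raise LayerTooThinError(f"layer too thin: thicknesses {t.tolist()}")
    return t


def _curvature_offsets(width: int, curvature: int) -> np.ndarray:
    """Per-column downward shift of the wall: a half-cosine bump."""
    if curvature == 0:
        return np.zeros(width, dtype=int)
    c = np.arange(width) / max(width - 1, 1)
    bump = 0.5 * (1.0 - np.cos(2.0 * math.pi * c))  # 0 at edges, 1 at centre
    return np.floor(curvature * bump + 0.5).astype(int)


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom: five-band template, optional bowing, speckle."""
    t = layer_thicknesses(spec.proportions, spec.wall_thickness)
    offsets = _curvature_offsets(spec.width, spec.curvature)

    template = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    rows = np.arange(spec.height)[:, None]  # (H, 1) broadcast against columns

    top = spec.wall_top_row + offsets  # (W,)
    edges = top[None, :] + np.concatenate(([0], np.cumsum(t)))[:, None]  # (6, W)
    for k in range(5):
        band = (rows >= edges[k]) & (rows < edges[k + 1])
        template[band] = spec.layer_levels[k]
        mask |= band

    image = apply_speckle(template, spec.speckle_looks, seed=spec.seed)
    return PhantomTruth(
        image=image,
        wall_mask=mask.astype(np.uint8),
        boundary_rows=edges[1:5].copy(),
        wall_top=edges[0].copy(),
        wall_bottom=edges[5].copy(),
        proportions=np.asarray(spec.proportions, dtype=float),
        spec=spec,
    )


def apply_speckle(image: np.ndarray, looks: int | None, seed=0) -> np.ndarray:
    """Multiply ``image`` by i.i.d. unit-mean gamma noise with variance 1/looks.

    ``looks=None`` is the no-noise (infinite-looks) limit and returns the
    input unchanged.  The input must be strictly positive, as required by
    downstream SRAD filtering.
    """
    image = np.asarray(image, dtype=float)
    if (image <= 0).any():
        raise GastrolayerError("apply_speckle requires strictly positive intensities")
    if looks is None:
        return image.copy()
    if looks < 1:
        raise GastrolayerError("looks must be >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.gamma(shape=looks, scale=1.0 / looks, size=image.shape)
    # gamma(looks, 1/looks) has mean 1 and variance 1/looks and is a.s. > 0
    return image * noise


def _largest_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Largest axis-aligned all-true rectangle, as (r0, r1, c0, c1) half-open.

    Classic histogram-stack scan, O(H*W).
    """
    h, w = mask.shape
    heights = np.zeros(w, dtype=int)
    best = (0, 0, 0, 0)
    best_area = 0
    for r in range(h):
        heights = np.where(mask[r], heights + 1, 0)
        stack: list[int] = []  # column indices with increasing heights
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            while stack and heights[stack[-1]] >= cur:
                top = stack.pop()
                ht = heights[top]
                left = stack[-1] + 1 if stack else 0
                area = ht * (c - left)
                if area > best_area:
                    best_area = area
                    best = (r + 1 - ht, r + 1, left, c)
            stack.append(c)
    return best


def make_labels(truth: PhantomTruth, mode: str) -> np.ndarray:
    """Emulate the three manual labelling styles used for wall ground truth.

    ``one_rect``: the largest axis-aligned rectangle that fits inside the
    wall band.  ``two_rect``: one such rectangle per lateral half of the
    image, covering more of a bowed wall.  ``full``: the exact wall mask.
    """
    wall = truth.wall_mask.astype(bool)
    if mode == "full":
        return truth.wall_mask.copy()
    label = np.zeros_like(wall)
    if mode == "one_rect":
        r0, r1, c0, c1 = _largest_rectangle(wall)
        label[r0:r1, c0:c1] = True
    elif mode == "two_rect":
        half = wall.shape[1] // 2
        for sl in (np.s_[:, :half], np.s_[:, half:]):
            r0, r1, c0, c1 = _largest_rectangle(wall[sl])
            sub = label[sl]
            sub[r0:r1, c0:c1] = True
    else:
        raise GastrolayerError(f"unknown labeling mode {mode!r}")
    return label.astype(np.uint8)


@dataclass(frozen=True)
class AbnormalEffect:
    """Proportion shift defining the diseased class.

    Each layer's fraction is multiplied by the corresponding factor and
    the vector renormalised -- e.g. factors (2,1,1,1,1) doubles the
    mucosal fraction before renormalisation, emulating mucosal
    thickening.
    """

    factors: tuple[float, ...] = (2.0, 1.0, 1.0, 1.0, 1.0)

    def apply(self, proportions) -> np.ndarray:
        p = np.asarray(proportions, dtype=float) * np.asarray(self.factors, dtype=float)
        if (p < 0).any():
            raise GastrolayerError("abnormal effect produced negative proportions")
        return p / p.sum()


def _jitter_proportions(p: np.ndarray, rng: np.random.Generator, scale: float) -> np.ndarray:
    """Dirichlet jitter around p with concentration p/scale (small scale = tight)."""
    alpha = np.maximum(p, 1e-6) / scale
    return rng.dirichlet(alpha)


def generate_cohort(
    n_normal: int,
    n_abnormal: int,
    abnormal_effect: AbnormalEffect | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    jitter_scale: float = 0.002,
) -> list[PhantomTruth]:
    """Generate a labelled cohort of phantoms.

    Normals jitter around ``base_spec.proportions``; abnormals jitter
    around the effect-shifted template.  Wall thickness and top row vary
    mildly between subjects.  Fully reproducible under ``seed``.
    """
    if abnormal_effect is None:
        abnormal_effect = AbnormalEffect()
    if base_spec is None:
        base_spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    base_p = np.asarray(base_spec.proportions, dtype=float)
    abn_p = abnormal_effect.apply(base_p)

    cohort: list[PhantomTruth] = []
    for label, template, n in (("normal", base_p, n_normal), ("abnormal", abn_p, n_abnormal)):
        for _ in range(n):
            p = _jitter_proportions(template, rng, jitter_scale)
            thickness = int(rng.integers(max(50, base_spec.wall_thickness - 20),
                                         base_spec.wall_thickness + 21))
            top = int(rng.integers(max(4, base_spec.wall_top_row - 10),
                                   base_spec.wall_top_row + 11))
            spec = replace(
                base_spec,
                proportions=tuple(p / p.sum()),
                wall_thickness=thickness,
                wall_top_row=top,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            truth = generate_phantom(spec)
            truth.label = label
            cohort.append(truth)
    return cohort
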