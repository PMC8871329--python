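"""Synthetic dermoscopy fixtures with exact ground-truth masks.

Real dermoscopic images come with a characteristic set of nuisance
properties: hair and blood vessels crossing the lesion, ruler marks and
color-calibration charts from the acquisition rig, marker ink, gel
bubbles, vignette darkening, low lesion/skin contrast, irregular
borders, and multi-shade pigmentation.  This module renders small
images that emulate those properties -- a darker elliptical lesion on a
skin-toned background, with artifacts drawn on top -- together with the
exact rasterized lesion support as ground truth.

The ground-truth mask is always the *pre-artifact* lesion support:
artifacts occlude the image but never alter the mask, matching how
expert ground truths for public dermoscopy datasets are drawn.

Everything is driven by a single pseudo-random generator seeded from
``FixtureSpec.seed``, so a spec fully determines its image and mask.

What the generator does **not** emulate: real skin texture (pores,
pigment network), specular highlights, lens distortion, and JPEG
artifacts.  Passing tests on these fixtures therefore demonstrates the
algorithmic contract (contrast-driven saliency, artifact robustness),
not clinical-grade performance on photographic data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import FixtureSpecError

__all__ = [
    "FixtureSpec",
    "TABLE3_CLASSES",
    "generate",
    "generate_suite",
    "class_spec",
    "random_spec",
]

ARTIFACT_KINDS = ("hair", "ruler", "ink", "vignette", "gel_bubble", "color_chart", "vessel")

#: The heterogeneous-property classes observed in dermoscopic images.
TABLE3_CLASSES = (
    "irregular_shape",
    "border_touching",
    "low_contrast",
    "color_chart",
    "hair",
    "ink",
    "ruler",
    "vessel",
    "gel_bubble",
    "vignette",
    "multiple_artifacts",
    "multi_shade",
    "small_lesion",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of one synthetic dermoscopy image.

    Geometry is in pixels with (row, col) centers; ``axes`` are the
    ellipse semi-axes.  ``contrast_gap`` is the intensity drop from
    skin to lesion used when ``lesion_rgb`` is not given explicitly.
    ``irregularity`` is the relative amplitude of the random radial
    border perturbation.  ``artifacts`` is a subset of
    ``ARTIFACT_KINDS``; ``tag`` is a free-form class label carried
    through suites.
    """

    width: int = 256
    height: int = 256
    center: tuple[float, float] | None = None  # (row, col); None = image center
    axes: tuple[float, float] = (60.0, 45.0)
    rotation_deg: float = 0.0
    irregularity: float = 0.0
    lesion_rgb: tuple[int, int, int] | None = None
    skin_rgb: tuple[int, int, int] = (224, 172, 150)
    contrast_gap: float = 70.0
    n_shades: int = 1
    artifacts: tuple[str, ...] = ()
    noise_sigma: float = 2.5
    border_touching: bool = False
    seed: int = 0
    tag: str = ""

    def __post_init__(self) -> None:
        if self.contrast_gap < 0:
            raise FixtureSpecError("contrast_gap must be >= 0")
        unknown = set(self.artifacts) - set(ARTIFACT_KINDS)
        if unknown:
            raise FixtureSpecError(f"unknown artifact kinds: {sorted(unknown)}")
        cy, cx = self.center if self.center is not None else (
            self.height / 2.0,
            self.width / 2.0,
        )
        reach = max(self.axes) * (1.0 + self.irregularity)
        inside = (
            cy - reach >= 0
            and cy + reach <= self.height
            and cx - reach >= 0
            and cx + reach <= self.width
        )
        if not inside and not self.border_touching:
            raise FixtureSpecError(
                "lesion does not fit inside the frame; set border_touching=True"
            )

    @property
    def center_rc(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (self.height / 2.0, self.width / 2.0)

    @property
    def lesion_color(self) -> np.ndarray:
        if self.lesion_rgb is not None:
            return np.array(self.lesion_rgb, dtype=np.float64)
        skin = np.array(self.skin_rgb, dtype=np.float64)
        # darken with a brown shift: green/blue drop faster than red
        drop = self.contrast_gap * np.array([1.0, 1.2, 1.3])
        return np.clip(skin - drop, 0, 255)

    def to_dict(self) -> dict:
        return asdict(self)


def _ellipse_mask(shape, center, axes, rotation_deg, irregularity=0.0, rng=None):
    """Rasterize a rotated ellipse, optionally with a wavy radial border."""
    m, n = shape
    cy, cx = center
    a, b = axes
    rr = np.arange(m)[:, None] - cy
    cc = np.arange(n)[None, :] - cx
    th = np.deg2rad(rotation_deg)
    u = rr * np.cos(th) + cc * np.sin(th)
    v = -rr * np.sin(th) + cc * np.cos(th)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if irregularity > 0 and rng is not None:
        harmonics = np.arange(2, 6)
        amp = rng.uniform(-1.0, 1.0, size=harmonics.size)
        amp *= irregularity / max(np.abs(amp).sum(), 1e-12)
        phase = rng.uniform(0, 2 * np.pi, size=harmonics.size)
        phi = np.arctan2(v, u)
        bound = 1.0 + (amp[:, None, None] * np.cos(
            harmonics[:, None, None] * phi[None] + phase[:, None, None]
        )).sum(axis=0)
    else:
        bound = 1.0
    return rho <= bound


def _draw_strokes(img, rng, n_strokes, color, alpha=0.75):
    """Curvilinear strands (hair / vessels) as finite quadratic Beziers.

    Each strand is a curved arc of 35-85% of the frame diagonal at a
    random position and orientation -- individual strands lying across
    the skin, as in real dermoscopy, rather than a frame-spanning grid.
    """
    m, n = img.shape[:2]
    color = np.asarray(color, dtype=np.float64)
    span = min(m, n)
    for _ in range(n_strokes):
        length = rng.uniform(0.35, 0.85) * span
        theta = rng.uniform(0, 2 * np.pi)
        p0 = np.array([rng.uniform(0, m - 1), rng.uniform(0, n - 1)])
        d = np.array([np.sin(theta), np.cos(theta)])
        p2 = p0 + length * d
        perp = np.array([-d[1], d[0]])
        p1 = (p0 + p2) / 2 + rng.uniform(-0.3, 0.3) * length * perp
        t = np.linspace(0, 1, 4 * (m + n))[:, None]
        curve = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        inside = (
            (curve[:, 0] >= 0) & (curve[:, 0] <= m - 1)
            & (curve[:, 1] >= 0) & (curve[:, 1] <= n - 1)
        )
        if not inside.any():
            continue
        r = np.round(curve[inside, 0]).astype(int)
        c = np.round(curve[inside, 1]).astype(int)
        stroke = np.zeros((m, n), dtype=bool)
        stroke[r, c] = True
        if rng.random() < 0.5:  # half the strands are 2 px wide
            stroke[np.clip(r + 1, 0, m - 1), c] = True
        img[stroke] = (1 - alpha) * img[stroke] + alpha * color


def _apply_artifacts(img, spec, rng):
    m, n = img.shape[:2]
    kinds = set(spec.artifacts)
    if "hair" in kinds:
        _draw_strokes(img, rng, n_strokes=8, color=(45, 32, 28))
    if "vessel" in kinds:
        _draw_strokes(img, rng, n_strokes=5, color=(152, 62, 70), alpha=0.7)
    if "ruler" in kinds:
        row = int(0.08 * m)
        for c in range(10, n - 10, 18):
            img[row : row + 10, c : c + 2] = (60, 60, 60)
    if "ink" in kinds:
        cy = rng.uniform(0.1, 0.25) * m
        cx = rng.uniform(0.6, 0.85) * n
        blob = _ellipse_mask((m, n), (cy, cx), (16, 11), rng.uniform(0, 180))
        img[blob] = (42, 30, 84)
    if "gel_bubble" in kinds:
        cy = rng.uniform(0.6, 0.8) * m
        cx = rng.uniform(0.15, 0.35) * n
        th = rng.uniform(0, 180)
        outer = _ellipse_mask((m, n), (cy, cx), (20, 15), th)
        inner = _ellipse_mask((m, n), (cy, cx), (17, 12.5), th)
        img[inner] = np.clip(img[inner] + 18, 0, 255)
        img[outer & ~inner] = np.clip(img[outer & ~inner] - 28, 0, 255)
    if "color_chart" in kinds:
        patches = [(200, 30, 30), (30, 160, 40), (30, 60, 200),
                   (220, 200, 40), (40, 190, 190), (190, 40, 190)]
        size, margin = 14, 4
        for k, col in enumerate(patches):
            i, j = divmod(k, 3)
            r0 = margin + i * (size + 2)
            c0 = margin + j * (size + 2)
            img[r0 : r0 + size, c0 : c0 + size] = col
    if "vignette" in kinds:
        cy, cx = (m - 1) / 2.0, (n - 1) / 2.0
        rr = np.arange(m)[:, None] - cy
        cc = np.arange(n)[None, :] - cx
        d2 = (rr**2 + cc**2) / (cy**2 + cx**2)
        img *= (1.0 - 0.35 * d2)[..., None]


def generate(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one fixture: (uint8 RGB image, boolean ground-truth mask)."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.height, spec.width
    mask = _ellipse_mask(
        (m, n), spec.center_rc, spec.axes, spec.rotation_deg, spec.irregularity, rng
    )
    img = np.empty((m, n, 3), dtype=np.float64)
    img[:] = np.array(spec.skin_rgb, dtype=np.float64)
    img[mask] = spec.lesion_color
    if spec.n_shades >= 2:
        core = _ellipse_mask(
            (m, n),
            spec.center_rc,
            (spec.axes[0] * 0.5, spec.axes[1] * 0.5),
            spec.rotation_deg,
        )
        img[core & mask] = np.clip(spec.lesion_color - 35, 0, 255)
    _apply_artifacts(img, spec, rng)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


def class_spec(cls: str, seed: int = 0, **overrides) -> FixtureSpec:
    """A representative fixture spec for one heterogeneous-property class."""
    presets: dict[str, dict] = {
        "irregular_shape": dict(irregularity=0.18),
        "border_touching": dict(axes=(150.0, 120.0), border_touching=True),
        "low_contrast": dict(contrast_gap=25.0),
        "color_chart": dict(artifacts=("color_chart",)),
        "hair": dict(artifacts=("hair",)),
        "ink": dict(artifacts=("ink",)),
        "ruler": dict(artifacts=("ruler",)),
        "vessel": dict(artifacts=("vessel",)),
        "gel_bubble": dict(artifacts=("gel_bubble",)),
        "vignette": dict(artifacts=("vignette",)),
        "multiple_artifacts": dict(artifacts=("hair", "ruler", "vignette")),
        "multi_shade": dict(n_shades=2),
        "small_lesion": dict(axes=(20.0, 15.0)),
    }
    if cls not in presets:
        raise FixtureSpecError(f"unknown property class {cls!r}")
    kwargs = {**presets[cls], **overrides}
    return FixtureSpec(seed=seed, tag=cls, **kwargs)


def random_spec(rng: np.random.Generator, artifacts=(), tag: str = "", **overrides) -> FixtureSpec:
    """A fixture spec with randomized lesion geometry and contrast.

    Geometry ranges emulate a typical mid-sized, roughly central lesion:
    center jitter within 12% of the frame, semi-axes 40-80 x 30-65 px
    (for the default 256 px frame), arbitrary rotation, mild border
    irregularity, and a skin/lesion contrast gap of 50-90 intensity
    levels.
    """
    height = overrides.pop("height", 256)
    width = overrides.pop("width", 256)
    jitter_r = rng.uniform(-0.12, 0.12) * height
    jitter_c = rng.uniform(-0.12, 0.12) * width
    scale = min(height, width) / 256.0
    spec = dict(
        height=height,
        width=width,
        center=(height / 2.0 + jitter_r, width / 2.0 + jitter_c),
        axes=(rng.uniform(40, 80) * scale, rng.uniform(30, 65) * scale),
        rotation_deg=rng.uniform(0, 180),
        irregularity=rng.uniform(0, 0.15),
        contrast_gap=rng.uniform(50, 90),
        artifacts=tuple(artifacts),
        seed=int(rng.integers(0, 2**31 - 1)),
        tag=tag,
        border_touching=True,  # jittered geometry may graze the frame edge
    )
    spec.update(overrides)
    return FixtureSpec(**spec)


def generate_suite(n_images: int, property_mix=None, seed: int = 0):
    """A reproducible batch of fixtures spanning the property classes.

    ``property_mix`` maps class names to weights (default: uniform over
    all classes).  Class counts are apportioned by largest remainder so
    realized fractions match the requested mix within 1/n.  Returns a
    list of ``(image, mask, spec)`` triples.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if property_mix is None:
        property_mix = {cls: 1.0 for cls in TABLE3_CLASSES}
    classes = list(property_mix)
    weights = np.array([property_mix[c] for c in classes], dtype=np.float64)
    weights /= weights.sum()
    ideal = weights * n_images
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder)[: n_images - counts.sum()]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    out = []
    for cls, cnt in zip(classes, counts):
        for _ in range(cnt):
            base = class_spec(cls, seed=int(rng.integers(0, 2**31 - 1)))
            img, mask = generate(base)
            out.append((img, mask, base))
    return out
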