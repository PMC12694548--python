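"""Procedural synthetic vineyard-leaf scenes.

The generator emulates the *statistical structure* of a field-collected
grape-leaf dataset — eleven classes separable by leaf morphology, cluttered
natural backgrounds composed of 2-4 element textures (soil, grass, trunk),
and a controlled occlusion profile (65% of images under 15% occlusion, 25%
at 15-30%, 10% at 30-40%) — not botanical realism.

Leaf geometry is a polar lobed curve,

    r(theta) = R * (1 - depth * sin^2(lobes * theta / 2))
               + serr_amp * R * sin(serr_freq * theta),

whose low-frequency term gives ``lobes`` lobes and whose high-frequency term
models margin serration; a vein skeleton radiates from the petiole point.
The eleven cultivar presets are pairwise distinct in at least two parameters
(all are unique in the (lobes, serr_freq) pair), so the benchmark is
separable by construction; :func:`shape_descriptors` recovers those factors
from a rendered mask and serves as the learnability oracle.

Occlusion is measured on the ground-truth leaf mask: the fraction of leaf
pixels covered by occluder strokes drawn over the composed scene.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .datapipe import MANIFEST_COLUMNS, DatasetManifest

CANVAS = 224
SPRITE = 160

_GRIDS: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    if size not in _GRIDS:
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
        _GRIDS[size] = (yy, xx)
    return _GRIDS[size]

OCCLUSION_BANDS = {"none": (0.0, 0.15), "slight": (0.15, 0.30),
                   "moderate": (0.30, 0.40)}
OCCLUSION_MIX = (0.65, 0.25, 0.10)       # none / slight / moderate

#: per-class image counts of the study dataset (total 6051)
PAPER_CLASS_COUNTS = {
    "Auxerrois": 528, "Cabernet_Franc": 360, "Cabernet_Sauvignon": 666,
    "Chardonnay": 623, "Merlot": 366, "Muller_Thurgau": 726,
    "Pinot_Noir": 353, "Riesling": 696, "Sauvignon_Blanc": 600,
    "Syrah": 713, "Tempranillo": 420,
}

TINY_PER_CLASS = 20


@dataclasses.dataclass(frozen=True)
class CultivarParams:
    name: str
    lobes: int                 # 3, 5 or 7
    lobe_depth: float          # sinus depth between lobes, in (0, 1)
    serr_freq: int             # serration cycles around the margin
    serr_amp: float            # serration amplitude, fraction of R
    vein_angle: float          # secondary-vein branching angle (degrees)
    hue: float                 # base hue in [0, 1] (green neighbourhood)
    saturation: float
    size_scale: float          # leaf radius relative to sprite


CULTIVARS: tuple[CultivarParams, ...] = (
    CultivarParams("Auxerrois",          3, 0.30, 18, 0.030, 35.0, 0.26, 0.55, 0.95),
    CultivarParams("Cabernet_Franc",     5, 0.45, 26, 0.045, 45.0, 0.30, 0.60, 0.90),
    CultivarParams("Cabernet_Sauvignon", 5, 0.55, 34, 0.050, 50.0, 0.33, 0.70, 0.92),
    CultivarParams("Chardonnay",         3, 0.25, 26, 0.035, 40.0, 0.22, 0.50, 1.00),
    CultivarParams("Merlot",             5, 0.40, 42, 0.055, 55.0, 0.28, 0.65, 0.88),
    CultivarParams("Muller_Thurgau",     3, 0.35, 34, 0.040, 30.0, 0.24, 0.45, 0.97),
    CultivarParams("Pinot_Noir",         3, 0.20, 42, 0.025, 48.0, 0.31, 0.55, 0.93),
    CultivarParams("Riesling",           5, 0.35, 18, 0.060, 38.0, 0.25, 0.75, 0.96),
    CultivarParams("Sauvignon_Blanc",    7, 0.40, 26, 0.035, 42.0, 0.27, 0.60, 0.91),
    CultivarParams("Syrah",              7, 0.50, 34, 0.045, 52.0, 0.32, 0.68, 0.94),
    CultivarParams("Tempranillo",        7, 0.30, 18, 0.055, 46.0, 0.29, 0.52, 0.98),
)

BACKGROUND_ELEMENTS = ("soil", "grass", "trunk")
_PALETTES = {
    "soil":  (np.array([0.45, 0.33, 0.22]), np.array([0.30, 0.22, 0.15])),
    "grass": (np.array([0.35, 0.50, 0.22]), np.array([0.20, 0.32, 0.12])),
    "trunk": (np.array([0.38, 0.30, 0.25]), np.array([0.22, 0.18, 0.15])),
}


@dataclasses.dataclass(frozen=True)
class SceneParams:
    elements: tuple[str, ...]            # 2-4 background element types
    occlusion_band: str                  # key of OCCLUSION_BANDS
    lighting: float = 1.0                # multiplicative lighting factor
    pose_angle: float = 0.0              # leaf rotation in the scene (deg)

    def __post_init__(self):
        if not 2 <= len(self.elements) <= 4:
            raise ValueError("scenes use 2-4 background elements")
        if self.occlusion_band not in OCCLUSION_BANDS:
            raise ValueError(f"unknown occlusion band {self.occlusion_band!r}")
        for e in self.elements:
            if e not in BACKGROUND_ELEMENTS:
                raise ValueError(f"unknown background element {e!r}")


def _hsv_to_rgb(h, s, v):
    h = (h % 1.0) * 6.0
    i = np.floor(h)
    f = h - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    i = i.astype(int) % 6
    choices = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)]
    r = np.choose(i, [c[0] for c in choices])
    g = np.choose(i, [c[1] for c in choices])
    b = np.choose(i, [c[2] for c in choices])
    return np.stack([r, g, b], axis=-1)


def leaf_radius(params: CultivarParams, theta: np.ndarray,
                radius: float) -> np.ndarray:
    """The polar boundary r(theta) of the leaf silhouette."""
    base = 1.0 - params.lobe_depth * np.sin(params.lobes * theta / 2.0) ** 2
    serr = params.serr_amp * np.sin(params.serr_freq * theta)
    return radius * (base + serr)


def render_leaf(params: CultivarParams, seed: int,
                size: int = SPRITE) -> tuple[np.ndarray, np.ndarray]:
    """Render one leaf sprite.

    Returns ``(rgba, mask)``: float RGBA (size, size, 4) in [0, 1] and the
    boolean silhouette mask.  Deterministic for a given (params, seed).
    """
    rng = np.random.default_rng(seed)
    yy, xx = _grid(size)
    cy = cx = (size - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    radius = 0.45 * size * params.size_scale * rng.uniform(0.92, 1.05)
    r_bound = leaf_radius(params, theta, radius)
    mask = dist <= r_bound

    # base color field with gentle radial shading and speckle
    hue = params.hue + rng.normal(0, 0.01)
    val = 0.55 + 0.25 * (1.0 - dist / (radius + 1e-6)).clip(0, 1)
    val += 0.05 * rng.standard_normal((size, size)).astype(np.float32)
    val = ndimage.gaussian_filter(val, 2.0)
    rgb = _hsv_to_rgb(np.full_like(val, hue),
                      np.full_like(val, params.saturation),
                      np.clip(val, 0.05, 1.0))

    # vein skeleton: primary veins toward each lobe apex, plus laterals at
    # the branching angle, drawn as bright ridges in angular distance
    apex_angles = np.arange(params.lobes) * 2 * np.pi / params.lobes \
        + rng.uniform(0, 2 * np.pi)
    vein = np.zeros_like(val)
    for a in apex_angles:
        for branch, fade in ((0.0, 1.0), (np.deg2rad(params.vein_angle), 0.6),
                             (-np.deg2rad(params.vein_angle), 0.6)):
            ang = np.abs((theta - a - branch + np.pi) % (2 * np.pi) - np.pi)
            ridge = np.exp(-(ang * dist / 2.5) ** 2) * fade
            vein = np.maximum(vein, ridge)
    rgb = rgb + 0.18 * vein[..., None] * np.array([0.9, 1.0, 0.7])
    rgb = np.clip(rgb, 0.0, 1.0)

    rgba = np.concatenate([rgb, mask[..., None].astype(np.float32)], axis=-1)
    rgba[~mask] = 0.0
    return rgba.astype(np.float32), mask


def shape_descriptors(mask: np.ndarray) -> np.ndarray:
    """Oracle descriptors from a silhouette: estimated lobe count,
    serration frequency, and normalized mean radius."""
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    theta = np.arctan2(ys - cy, xs - cx)
    dist = np.hypot(xs - cx, ys - cy)
    bins = 360
    idx = ((theta + np.pi) / (2 * np.pi) * bins).astype(int) % bins
    prof = np.zeros(bins)
    np.maximum.at(prof, idx, dist)   # boundary radius per angular bin
    prof = prof - prof.mean()
    spec = np.abs(np.fft.rfft(prof))
    lobe_est = float(np.argmax(spec[2:9]) + 2)       # lobes in 3,5,7
    serr_est = float(np.argmax(spec[12:50]) + 12)    # serration band
    return np.array([lobe_est, serr_est,
                     dist.mean() / np.sqrt(mask.sum())])


# ----------------------------------------------------------- backgrounds

def _value_noise(rng, size, scale):
    low = rng.random((scale, scale)).astype(np.float32)
    return np.asarray(Image.fromarray(low, mode="F").resize(
        (size, size), Image.BILINEAR))


def _background(elements: tuple[str, ...], rng,
                size: int = CANVAS) -> np.ndarray:
    """Tile the canvas into element regions (nearest-seed partition) and fill
    each with that element's value-noise texture."""
    seeds = rng.uniform(0, size, size=(len(elements), 2)).astype(np.float32)
    yy, xx = _grid(size)
    d = (yy[None] - seeds[:, 0, None, None]) ** 2 \
        + (xx[None] - seeds[:, 1, None, None]) ** 2
    region = d.argmin(axis=0)
    canvas = np.zeros((size, size, 3), dtype=np.float32)
    for i, el in enumerate(elements):
        hi, lo = _PALETTES[el]
        tex = _value_noise(rng, size, scale=6 if el == "trunk" else 10)
        patch = lo + (hi - lo) * tex[..., None]
        canvas[region == i] = patch[region == i]
    return canvas


def _draw_occluder(canvas, leaf_mask_canvas, rng, element):
    """One occluder stroke (a rotated capsule); returns its mask."""
    size = canvas.shape[0]
    length = rng.uniform(0.3, 1.0) * size
    width = rng.uniform(8, 26)
    x0, y0 = rng.uniform(0, size, 2)
    ang = rng.uniform(0, np.pi)
    yy, xx = _grid(size)
    u = (xx - x0) * np.cos(ang) + (yy - y0) * np.sin(ang)
    v = -(xx - x0) * np.sin(ang) + (yy - y0) * np.cos(ang)
    occ = (np.abs(u) < length / 2) & (np.abs(v) < width / 2)
    hi, lo = _PALETTES[element]
    shade = rng.uniform(0.2, 0.9)
    canvas[occ] = lo + (hi - lo) * shade
    return occ


def compose_scene(rgba: np.ndarray, mask: np.ndarray, scene: SceneParams,
                  seed: int, size: int = CANVAS,
                  max_attempts: int = 100) -> tuple[np.ndarray, float]:
    """Compose a 224x224 RGB scene; returns (image, achieved occlusion)."""
    lo, hi = OCCLUSION_BANDS[scene.occlusion_band]
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        canvas = _background(scene.elements, rng, size)

        sprite = rgba
        leaf_mask = mask.astype(np.float32)
        if scene.pose_angle:
            sprite = ndimage.rotate(rgba, scene.pose_angle, reshape=False,
                                    order=1, mode="constant")
            leaf_mask = ndimage.rotate(leaf_mask, scene.pose_angle,
                                       reshape=False, order=1,
                                       mode="constant")
        s = sprite.shape[0]
        oy = (size - s) // 2 + rng.integers(-12, 13)
        ox = (size - s) // 2 + rng.integers(-12, 13)
        alpha = np.zeros((size, size), dtype=np.float32)
        alpha[oy:oy + s, ox:ox + s] = sprite[..., 3] * (leaf_mask > 0.5)
        rgb_full = np.zeros((size, size, 3), dtype=np.float32)
        rgb_full[oy:oy + s, ox:ox + s] = sprite[..., :3]
        canvas = canvas * (1 - alpha[..., None]) + rgb_full * alpha[..., None]
        leaf = alpha > 0.5
        n_leaf = leaf.sum()

        occluded = np.zeros((size, size), dtype=bool)
        frac = 0.0
        # grow occlusion until the band is reached (band "none" may stay 0)
        target = rng.uniform(lo, hi) if lo > 0 else rng.uniform(0, hi * 0.8)
        for _ in range(60):
            if frac >= target:
                break
            el = scene.elements[rng.integers(len(scene.elements))]
            occ = _draw_occluder(canvas, leaf, rng, el)
            occluded |= occ
            frac = (occluded & leaf).sum() / n_leaf
            if frac >= hi:   # overshot the band; retry with fresh randomness
                break
        frac = (occluded & leaf).sum() / n_leaf
        if lo <= frac < hi:
            canvas = np.clip(canvas * scene.lighting, 0.0, 1.0)
            return canvas.astype(np.float32), float(frac)
    raise RuntimeError(
        f"could not reach occlusion band {scene.occlusion_band!r} "
        f"in {max_attempts} attempts")


# ------------------------------------------------------------- datasets

def apportion(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n into len(fractions) parts."""
    raw = [n * f for f in fractions]
    out = [int(x) for x in raw]
    rem = n - sum(out)
    order = np.argsort([i - r for i, r in zip(out, raw)])  # largest remainder
    for j in range(rem):
        out[order[j]] += 1
    return out


def _scene_seed(seed: int, label: int, i: int) -> int:
    return (seed * 1_000_003 + label * 10_007 + i) % (2 ** 31 - 1)


def _make_record(label: int, i: int, band: str, seed: int):
    params = CULTIVARS[label]
    s = _scene_seed(seed, label, i)
    rng = np.random.default_rng((s, 17))
    n_el = rng.integers(2, 5)
    elements = tuple(rng.choice(BACKGROUND_ELEMENTS, size=n_el, replace=True))
    scene = SceneParams(elements=elements, occlusion_band=band,
                        lighting=float(rng.uniform(0.8, 1.15)),
                        pose_angle=float(rng.uniform(0, 360)))
    rgba, mask = render_leaf(params, s)
    img, frac = compose_scene(rgba, mask, scene, s)
    return img, frac


def band_assignment(count: int, mix: tuple[float, float, float] = OCCLUSION_MIX
                    ) -> list[str]:
    names = list(OCCLUSION_BANDS)
    per = apportion(count, mix)
    bands: list[str] = []
    for name, c in zip(names, per):
        bands += [name] * c
    return bands


def generate_dataset(per_class_counts: dict[str, int] | None = None,
                     mix: tuple[float, float, float] = OCCLUSION_MIX,
                     seed: int = 0, out_dir: str | Path | None = None
                     ) -> DatasetManifest:
    """Generate a class-per-folder synthetic dataset and its manifest.

    With ``out_dir=None`` no PNG files are written; manifest paths are then
    synthetic identifiers and the images are discarded after statistics are
    recorded (useful for count/occlusion checks).
    """
    if per_class_counts is None:
        per_class_counts = PAPER_CLASS_COUNTS
    names = [c.name for c in CULTIVARS]
    for k in per_class_counts:
        if k not in names:
            raise ValueError(f"unknown cultivar {k!r}")
    root = Path(out_dir) if out_dir is not None else None
    rows = []
    for label, cname in enumerate(names):
        if cname not in per_class_counts:
            continue
        count = per_class_counts[cname]
        bands = band_assignment(count, mix)
        if root is not None:
            (root / cname).mkdir(parents=True, exist_ok=True)
        for i, band in enumerate(bands):
            img, frac = _make_record(label, i, band, seed)
            rel = f"{cname}/{cname}_{i:04d}.png"
            if root is not None:
                Image.fromarray((img * 255 + 0.5).astype(np.uint8)).save(
                    root / rel)
            rows.append({"path": str(root / rel) if root else rel,
                         "label": label, "class_name": cname, "split": "",
                         "fold": -1, "occlusion_band": band,
                         "occlusion_frac": frac})
    manifest = DatasetManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    if root is not None:
        manifest.save(root / "manifest.csv")
        with open(root / "provenance.json", "w") as fh:
            json.dump({"seed": seed, "mix": mix,
                       "per_class_counts": per_class_counts,
                       "cultivars": [dataclasses.asdict(c)
                                     for c in CULTIVARS]}, fh, indent=2)
    return manifest


def generate_arrays(per_class: int = TINY_PER_CLASS, num_classes: int = 11,
                    mix: tuple[float, float, float] = OCCLUSION_MIX,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray, DatasetManifest]:
    """In-memory dataset (images NHWC float in [0,1], labels, manifest)."""
    images, labels, rows = [], [], []
    for label in range(num_classes):
        cname = CULTIVARS[label].name
        bands = band_assignment(per_class, mix)
        for i, band in enumerate(bands):
            img, frac = _make_record(label, i, band, seed)
            images.append(img)
            labels.append(label)
            rows.append({"path": f"{cname}/{i:04d}", "label": label,
                         "class_name": cname, "split": "", "fold": -1,
                         "occlusion_band": band,
                         "occlusion_frac": frac})
    manifest = DatasetManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    return (np.stack(images), np.asarray(labels, dtype=np.int64), manifest)
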