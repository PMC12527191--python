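"""Synthetic brain-slice phantoms with pixel-exact tumor masks.

The generator emulates the structure of the public brain-MRI collections
the routing pipeline is designed for, without shipping any patient data:

* three geometrically distinct slice orientations —

  - **axial**: a wide ellipse with two symmetric dark interior "ventricle"
    lobes,
  - **coronal**: a tall ellipse with a dark vertical midline groove,
  - **sagittal**: an off-centre asymmetric profile with a posterior notch
    and an anterior-posterior intensity gradient;

* optional tumors as bright Gaussian blobs, with the ground-truth mask
  defined as the region at or above 50% of blob peak (a disc of the drawn
  half-max radius), guaranteed to lie strictly inside the brain tissue;

* tumor-free samples with all-zero ("all-black") masks;

* configurable per-view class imbalance and tumor prevalence.

All randomness flows from integer seeds; the same spec always produces a
bitwise-identical sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from viewseg.models import ViewLabel

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "split_dataset",
    "save_dataset",
    "load_dataset",
]

_HALF_MAX = np.sqrt(2.0 * np.log(2.0))  # half-max radius in units of sigma


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a single phantom slice."""

    image_size: int = 64
    view: ViewLabel = ViewLabel.AXIAL
    tumor_present: bool = True
    tumor_radius_range: tuple[float, float] = (0.05, 0.15)  # fraction of size
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        lo, hi = self.tumor_radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("tumor_radius_range must lie within (0, 0.5)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class PhantomSample:
    """Generated image, ground-truth mask and labels."""

    image: np.ndarray        # (H, W) float32 in [0, 1]
    mask: np.ndarray         # (H, W) uint8 in {0, 1}
    view: ViewLabel
    tumor_label: int
    sample_id: str = ""

    def image_rgb(self) -> np.ndarray:
        """Replicate the gray channel into a 3-channel (H, W, 3) array."""
        return np.repeat(self.image[..., None], 3, axis=2)


def _ellipse(u, v, cu, cv, a, b):
    return ((u - cu) / a) ** 2 + ((v - cv) / b) ** 2 <= 1.0


def _brain(view: ViewLabel, u, v, rng):
    """Returns (tissue intensity map, inside-brain mask, safe ellipse)."""
    j = lambda s: rng.uniform(-s, s)
    if view == ViewLabel.AXIAL:
        a, b = 0.42 + j(0.02), 0.30 + j(0.02)
        cu = cv = 0.0
        inside = _ellipse(u, v, cu, cv, a, b)
        r2 = ((u - cu) / a) ** 2 + ((v - cv) / b) ** 2
        tissue = 0.50 + 0.12 * (1.0 - r2)
        for s in (-1.0, 1.0):
            vent = _ellipse(u, v, s * 0.11, 0.0, 0.045, 0.13)
            tissue = np.where(vent, tissue * 0.35, tissue)
    elif view == ViewLabel.CORONAL:
        a, b = 0.30 + j(0.02), 0.42 + j(0.02)
        cu = cv = 0.0
        inside = _ellipse(u, v, cu, cv, a, b)
        r2 = ((u - cu) / a) ** 2 + ((v - cv) / b) ** 2
        tissue = 0.50 + 0.12 * (1.0 - r2)
        groove = (np.abs(u) < 0.025) & (v > -0.38) & (v < 0.15)
        tissue = np.where(groove, tissue * 0.35, tissue)
    elif view == ViewLabel.SAGITTAL:
        a, b = 0.40 + j(0.02), 0.33 + j(0.02)
        cu, cv = 0.04, 0.0
        inside = _ellipse(u, v, cu, cv, a, b)
        notch = _ellipse(u, v, -0.30, 0.26, 0.12, 0.12)
        inside = inside & ~notch
        r2 = ((u - cu) / a) ** 2 + ((v - cv) / b) ** 2
        tissue = (0.50 + 0.12 * (1.0 - r2)) * (1.0 + 0.30 * (u - cu) / a)
    else:  # pragma: no cover - IntEnum restricts the codes
        raise ValueError(f"unknown view {view}")
    return tissue, inside, (cu, cv, a, b)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one deterministic phantom slice from its spec."""
    S = spec.image_size
    rng = np.random.default_rng(spec.seed)
    # unit coordinates centred on the image, u rightward, v upward
    idx = (np.arange(S) + 0.5) / S - 0.5
    v, u = np.meshgrid(-idx, idx, indexing="ij")
    tissue, inside, (cu, cv, a, b) = _brain(spec.view, u, v, rng)

    image = np.where(inside, tissue, 0.0)
    mask = np.zeros((S, S), dtype=np.uint8)
    if spec.tumor_present:
        lo, hi = spec.tumor_radius_range
        r_frac = rng.uniform(lo, hi)
        margin = r_frac + 2.0 / S
        for _ in range(400):
            tu = rng.uniform(cu - a, cu + a)
            tv = rng.uniform(cv - b, cv + b)
            sa, sb = max(a - margin, 1e-3), max(b - margin, 1e-3)
            if ((tu - cu) / sa) ** 2 + ((tv - cv) / sb) ** 2 <= 1.0:
                if spec.view == ViewLabel.SAGITTAL:
                    # keep clear of the posterior notch
                    if np.hypot(tu + 0.30, tv - 0.26) < r_frac + 0.12 + 2.0 / S:
                        continue
                break
        else:  # extremely small brains: shrink until it fits
            r_frac *= 0.5
            tu, tv = cu, cv
        sigma = r_frac / _HALF_MAX
        d2 = (u - tu) ** 2 + (v - tv) ** 2
        blob = np.exp(-d2 / (2.0 * sigma ** 2))
        amp = 0.45
        image = image + amp * blob
        mask = (blob >= 0.5).astype(np.uint8)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(S, S))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return PhantomSample(image=image, mask=mask, view=spec.view,
                         tumor_label=int(mask.any()))


def _apportion(n: int, fractions) -> list[int]:
    """Floor-then-distribute largest-remainder rounding of n * fractions."""
    fr = np.asarray(fractions, dtype=np.float64)
    raw = n * fr
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(n - counts.sum()):
        counts[order[i % len(fr)]] += 1
    return counts.tolist()


def generate_dataset(n: int, view_mix=(1 / 3, 1 / 3, 1 / 3),
                     tumor_rate: float = 0.5,
                     template: PhantomSpec | None = None,
                     seed: int = 0) -> list[PhantomSample]:
    """Generate ``n`` phantoms with the requested view and tumor mix.

    Counts follow the proportions under largest-remainder rounding; each
    sample gets its own child seed, so the whole dataset is reproducible
    from ``seed`` alone.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = np.asarray(view_mix, dtype=np.float64)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("view_mix must be three non-negative proportions "
                         "summing to 1")
    if not 0.0 <= tumor_rate <= 1.0:
        raise ValueError("tumor_rate must lie in [0, 1]")
    template = template or PhantomSpec()
    rng = np.random.default_rng(seed)
    view_counts = _apportion(n, mix)
    assignments: list[tuple[ViewLabel, bool]] = []
    for view, count in zip(ViewLabel, view_counts):
        n_tum, _ = _apportion(count, (tumor_rate, 1.0 - tumor_rate)) if count \
            else (0, 0)
        assignments += [(view, True)] * n_tum + [(view, False)] * (count - n_tum)
    order = rng.permutation(len(assignments))
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=len(assignments))
    samples = []
    for pos, k in enumerate(order):
        view, tumor = assignments[k]
        spec = replace(template, view=view, tumor_present=tumor,
                       seed=int(child_seeds[pos]))
        sample = generate_phantom(spec)
        sample.sample_id = f"{view.name.lower()}_{pos:05d}"
        samples.append(sample)
    return samples


def split_dataset(samples, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Deterministic shuffled train/validation/test split.

    Sizes follow floor-then-distribute rounding of ``len(samples) * ratios``;
    the three parts are disjoint and exhaustive.
    """
    if len(samples) == 0:
        raise ValueError("cannot split an empty dataset")
    r = np.asarray(ratios, dtype=np.float64)
    if r.shape != (3,) or abs(r.sum() - 1.0) > 1e-9 or (r < 0).any():
        raise ValueError("ratios must be three non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    sizes = _apportion(len(samples), r)
    shuffled = [samples[i] for i in order]
    i1, i2 = sizes[0], sizes[0] + sizes[1]
    return shuffled[:i1], shuffled[i1:i2], shuffled[i2:]


# ---------------------------------------------------------------------------
# on-disk layout: <root>/<view>/{images,masks}/<id>.png + manifest.csv


def save_dataset(samples, root, split_names=None) -> Path:
    """Write samples as 8-bit PNGs in a per-view folder layout.

    Images are written as 3-channel RGB (replicated gray); masks as 0/255
    grayscale PNGs.  Returns the manifest path.
    """
    root = Path(root)
    split_names = split_names or {}
    rows = []
    for i, s in enumerate(samples):
        sid = s.sample_id or f"{s.view.name.lower()}_{i:05d}"
        vdir = root / s.view.name.lower()
        (vdir / "images").mkdir(parents=True, exist_ok=True)
        (vdir / "masks").mkdir(parents=True, exist_ok=True)
        img8 = (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(np.repeat(img8[..., None], 3, axis=2)).save(
            vdir / "images" / f"{sid}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            vdir / "masks" / f"{sid}.png")
        rows.append({"id": sid, "view": s.view.name.lower(),
                     "tumor_label": s.tumor_label,
                     "split": split_names.get(sid, "")})
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=["id", "view", "tumor_label",
                                            "split"])
        wr.writeheader()
        wr.writerows(rows)
    return manifest


def load_dataset(root) -> list[PhantomSample]:
    """Read a dataset written by :func:`save_dataset`."""
    root = Path(root)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {root}")
    samples = []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            view = ViewLabel[row["view"].upper()]
            vdir = root / row["view"]
            img = np.asarray(Image.open(vdir / "images" / f"{row['id']}.png")
                             .convert("L"), dtype=np.float32) / 255.0
            mask = (np.asarray(Image.open(vdir / "masks" / f"{row['id']}.png")
                               .convert("L")) > 127).astype(np.uint8)
            samples.append(PhantomSample(image=img, mask=mask, view=view,
                                         tumor_label=int(row["tumor_label"]),
                                         sample_id=row["id"]))
    return samples
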