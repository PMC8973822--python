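"""Synthetic multi-channel fluorescence scenes with ground truth.

Emulates fields of view of transfected HeLa-like cells in which a tagged
membrane protein distributes between two compartments: a plasma-membrane
ring (colocalizing with a WGA-like PM marker) and a reticular intracellular
component (colocalizing with a calreticulin-like ER marker).  The mixture
fraction ``alpha`` is the membrane fraction of the protein signal:
``alpha`` near 1 is a wild-type-like, membrane-dominant distribution;
``alpha`` near 0 is a mutant-like, ER-retained distribution.

Every scene is fully determined by its :class:`SceneSpec` (including the
seed), and ships with a :class:`GroundTruth` label mask so the downstream
segmentation and colocalization stages can be validated without any real
image data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "NoiseModel",
    "SceneSpec",
    "ImageStack",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "generate_dataset",
]

#: channel page order used on TIFF export
CHANNEL_ORDER = ("protein", "comarker", "nuclei")

#: fixed float -> 16-bit export scale (one global scale: acquisition
#: settings are held constant across images)
EXPORT_SCALE = 100.0

# template geometry constants (fractions of the respective peak intensity)
_MEMBRANE_PEDESTAL = 0.25  # uniform interior level of the PM template
_ER_BASELINE = 0.35        # uniform floor of the reticular ER template


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails after bounded retries."""


@dataclass(frozen=True)
class NoiseModel:
    """Fluorescence detector noise: Poisson shot noise then additive Gaussian.

    ``poisson_gain`` of 0 disables shot noise; ``gaussian_sd`` of 0 disables
    read noise. Intensities are clipped at zero afterwards.
    """

    poisson_gain: float = 1.0
    gaussian_sd: float = 5.0


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic field of view.

    Identical spec + seed yields bit-identical pixel data.
    """

    image_height: int = 512
    image_width: int = 512
    n_cells: int = 4
    cell_radius_range: tuple[float, float] = (30.0, 45.0)
    membrane_ring_width: float = 5.0
    er_texture_scale: float = 3.0
    alpha: float = 0.8
    alpha_jitter_sd: float = 0.03
    protein_amplitude: float = 300.0
    marker_amplitude: float = 300.0
    background_level: float = 20.0
    psf_sigma: float = 1.5
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    comarker: str = "PM"
    genotype_label: str = "WT"
    pixel_size: float = 0.16  # um/pixel, metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("protein_amplitude", "marker_amplitude", "background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.comarker not in ("PM", "ER"):
            raise ValueError(f"comarker must be 'PM' or 'ER', got {self.comarker!r}")
        lo, hi = self.cell_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("cell_radius_range must satisfy 0 < lo <= hi")

    def replace(self, **kwargs) -> "SceneSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_model"] = dataclasses.asdict(self.noise_model)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneSpec":
        d = dict(d)
        nm = d.get("noise_model")
        if isinstance(nm, Mapping):
            d["noise_model"] = NoiseModel(**nm)
        if "cell_radius_range" in d:
            d["cell_radius_range"] = tuple(d["cell_radius_range"])
        return cls(**d)


@dataclass
class ImageStack:
    """One multi-channel field of view.

    ``channels`` maps a role (``protein``, ``comarker``, ``nuclei``) to a 2D
    float array; all channels share the same shape and are non-negative.
    """

    channels: dict[str, np.ndarray]
    genotype_label: str
    comarker: str
    pixel_size: float = 0.16
    image_id: str = ""

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        missing = set(CHANNEL_ORDER) - set(self.channels)
        if missing:
            raise ValueError(f"missing channel roles: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["protein"].shape


@dataclass
class GroundTruth:
    """True per-pixel cell assignment and per-cell parameters of a scene."""

    true_mask: np.ndarray  # int labels, 0 = background
    per_cell_alpha: list[float]
    cell_centers: list[tuple[float, float]]  # (row, col)


# ---------------------------------------------------------------------------
# rendering

def _place_cells(spec: SceneSpec, rng: np.random.Generator,
                 max_tries_per_cell: int = 200):
    """Rejection-sample non-overlapping ellipses fully inside the image.

    Overlap test is circle-based on the major semi-axis plus an 8 px gap, so
    placed cells are guaranteed well separated.
    """
    gap = 8.0
    placed = []  # (cy, cx, a, b, theta)
    lo, hi = spec.cell_radius_range
    for _ in range(spec.n_cells):
        for attempt in range(max_tries_per_cell):
            a = rng.uniform(lo, hi)
            b = a / rng.uniform(1.0, 1.25)  # bounded eccentricity
            theta = rng.uniform(0, math.pi)
            margin = a + 2.0
            if (spec.image_height <= 2 * margin) or (spec.image_width <= 2 * margin):
                continue
            cy = rng.uniform(margin, spec.image_height - margin)
            cx = rng.uniform(margin, spec.image_width - margin)
            ok = all(
                math.hypot(cy - py, cx - px) > a + pa + gap
                for (py, px, pa, _, _) in placed
            )
            if ok:
                placed.append((cy, cx, a, b, theta))
                break
        else:
            raise PlacementError(
                f"could not place cell {len(placed) + 1}/{spec.n_cells} after "
                f"{max_tries_per_cell} tries; reduce n_cells or cell radius"
            )
    return placed


def _cell_masks(shape, cy, cx, a, b, theta, ring_frac):
    """Interior / ring boolean masks of one rotated ellipse."""
    rows = np.arange(shape[0])[:, None] - cy
    cols = np.arange(shape[1])[None, :] - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (rows * ct + cols * st) / a
    v = (-rows * st + cols * ct) / b
    rho2 = u * u + v * v
    cell = rho2 <= 1.0
    inner = rho2 < (1.0 - ring_frac) ** 2
    ring = cell & ~inner
    return cell, inner, ring


def _bandpass_noise(shape, scale, rng):
    """Difference-of-Gaussians filtered white noise: a reticular texture."""
    white = rng.standard_normal(shape)
    return gaussian_filter(white, scale) - gaussian_filter(white, 2.0 * scale)


def generate_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one scene from its spec.

    The protein channel of each cell is
    ``alpha * membrane_template + (1 - alpha) * er_template``; the comarker
    channel renders the pure template matching ``spec.comarker``; the nuclei
    channel renders one Gaussian blob per cell.  A constant background is
    added, the field is convolved with a Gaussian PSF, and detector noise
    applied last.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height, spec.image_width)

    placed = _place_cells(spec, rng)
    texture = _bandpass_noise(shape, spec.er_texture_scale, rng)

    protein = np.zeros(shape)
    pm_chan = np.zeros(shape)
    er_chan = np.zeros(shape)
    nuclei = np.zeros(shape)
    true_mask = np.zeros(shape, dtype=np.int32)

    per_cell_alpha: list[float] = []
    centers: list[tuple[float, float]] = []

    for k, (cy, cx, a, b, theta) in enumerate(placed, start=1):
        ring_frac = spec.membrane_ring_width / (0.5 * (a + b))
        cell, inner, ring = _cell_masks(shape, cy, cx, a, b, theta, ring_frac)

        if spec.alpha_jitter_sd > 0:
            alpha_k = float(np.clip(
                spec.alpha + rng.normal(0.0, spec.alpha_jitter_sd), 0.0, 1.0))
        else:
            alpha_k = spec.alpha

        mem_t = np.zeros(shape)
        mem_t[ring] = 1.0
        mem_t[inner] = _MEMBRANE_PEDESTAL

        er_t = np.zeros(shape)
        if inner.any():
            tex = texture[inner]
            span = tex.max() - tex.min()
            tex01 = (tex - tex.min()) / span if span > 0 else np.zeros_like(tex)
            er_t[inner] = _ER_BASELINE + (1.0 - _ER_BASELINE) * tex01

        protein += spec.protein_amplitude * (alpha_k * mem_t + (1 - alpha_k) * er_t)
        pm_chan += spec.marker_amplitude * mem_t
        er_chan += spec.marker_amplitude * er_t

        rows = np.arange(shape[0])[:, None] - cy
        cols = np.arange(shape[1])[None, :] - cx
        nuc_sigma = 0.35 * b
        nuclei += spec.marker_amplitude * np.exp(
            -(rows ** 2 + cols ** 2) / (2.0 * nuc_sigma ** 2))

        true_mask[cell] = k
        per_cell_alpha.append(alpha_k)
        centers.append((cy, cx))

    comarker = pm_chan if spec.comarker == "PM" else er_chan

    chans = {}
    for role, img in (("protein", protein), ("comarker", comarker),
                      ("nuclei", nuclei)):
        img = img + spec.background_level
        if spec.psf_sigma > 0:
            img = gaussian_filter(img, spec.psf_sigma)
        nm = spec.noise_model
        if nm.poisson_gain > 0:
            img = rng.poisson(np.maximum(img, 0.0) / nm.poisson_gain) * nm.poisson_gain
            img = img.astype(float)
        if nm.gaussian_sd > 0:
            img = img + rng.normal(0.0, nm.gaussian_sd, size=img.shape)
        chans[role] = np.maximum(img, 0.0)

    stack = ImageStack(channels=chans, genotype_label=spec.genotype_label,
                       comarker=spec.comarker, pixel_size=spec.pixel_size)
    truth = GroundTruth(true_mask=true_mask, per_cell_alpha=per_cell_alpha,
                        cell_centers=centers)
    return stack, truth


# ---------------------------------------------------------------------------
# dataset generation

def derive_seed(base_seed: int, genotype_index: int, image_index: int) -> int:
    """Deterministic per-scene seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), genotype_index, image_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(
    specs: Sequence[SceneSpec],
    images_per_genotype: int,
    base_seed: int = 0,
) -> Iterator[tuple[SceneSpec, ImageStack, GroundTruth]]:
    """Yield ``images_per_genotype`` scenes for every genotype spec.

    Scene seeds are derived deterministically from
    ``(base_seed, genotype index, image index)``; the per-spec ``seed`` field
    is overridden.  Duplicate genotype labels with conflicting specs raise.
    """
    if images_per_genotype < 1:
        raise ValueError("images_per_genotype must be >= 1")
    seen: dict[str, SceneSpec] = {}
    for spec in specs:
        prev = seen.get(spec.genotype_label)
        if prev is not None and prev != spec:
            raise ValueError(
                f"duplicate genotype_label {spec.genotype_label!r} with "
                f"conflicting specs")
        seen[spec.genotype_label] = spec

    for g_idx, spec in enumerate(seen.values()):
        for i_idx in range(images_per_genotype):
            scene_spec = spec.replace(seed=derive_seed(base_seed, g_idx, i_idx))
            stack, truth = generate_scene(scene_spec)
            stack.image_id = f"{spec.genotype_label}_{spec.comarker}_{i_idx:03d}"
            yield scene_spec, stack, truth


# ---------------------------------------------------------------------------
# export

def write_scene(stack: ImageStack, truth: GroundTruth | None,
                spec: SceneSpec, out_dir: Path) -> Path:
    """Write a scene as multi-page 16-bit TIFF + JSON sidecar (+ truth mask)."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pages = np.stack([
        np.clip(stack.channels[r] * EXPORT_SCALE, 0, 65535).astype(np.uint16)
        for r in CHANNEL_ORDER
    ])
    path = out_dir / f"{stack.image_id}.tif"
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {"spec": spec.to_dict(), "seed": spec.seed,
               "image_id": stack.image_id, "export_scale": EXPORT_SCALE,
               "channel_order": list(CHANNEL_ORDER)}
    (out_dir / f"{stack.image_id}.json").write_text(
        json.dumps(sidecar, indent=2))
    if truth is not None:
        tifffile.imwrite(out_dir / f"{stack.image_id}_truth.tif",
                         truth.true_mask.astype(np.uint16))
    return path


def read_scene(path: Path) -> tuple[ImageStack, SceneSpec | None]:
    """Read a multi-page TIFF scene (inverse of :func:`write_scene`)."""
    import tifffile

    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        raise ValueError(f"{path}: expected multi-page TIFF with 3 channels")
    sidecar_path = path.with_suffix(".json")
    spec = None
    scale = EXPORT_SCALE
    genotype, comarker = "unknown", "PM"
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        spec = SceneSpec.from_dict(meta["spec"])
        scale = meta.get("export_scale", EXPORT_SCALE)
        genotype, comarker = spec.genotype_label, spec.comarker
    channels = {role: pages[i].astype(float) / scale
                for i, role in enumerate(CHANNEL_ORDER)}
    stack = ImageStack(channels=channels, genotype_label=genotype,
                       comarker=comarker, image_id=path.stem)
    return stack, spec
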