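"""Synthetic kernel silhouettes, masses and composed scenes with ground truth.

The real image set behind this pipeline (tray scenes of intact and damaged
maize kernels on a uniform background) is not distributed, so this module
emulates it.  Unbroken kernels are superellipse-like blobs with a
low-frequency radial perturbation; broken kernels are the same blobs minus a
random wedge or (ragged) half-plane cut, mimicking the loss of tissue that
shifts circularity, rectangularity and perimeter.  Mass follows an
area-volume allometry ``W = alpha * S_mm2^1.5 * exp(eps)`` so that projected
area is the dominant weight predictor; damage removes mass proportionally to
the removed area fraction.

Every generator output is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.special import gamma as _gamma
from skimage import measure

from .features import FEATURE_NAMES, extract_features
from .dataset import KernelDataset

DEFAULT_SEED = 2018


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class KernelSpec:
    """Parameters of one synthetic kernel silhouette.

    ``base_radius`` sets the area scale (the undamaged silhouette encloses
    ~pi*base_radius^2 px^2 regardless of elongation/squareness);
    ``elongation`` >= 1 is the long/short semi-axis ratio; ``squareness`` is
    the superellipse exponent (2 = ellipse, larger = blockier);
    ``boundary_roughness`` the relative amplitude of the radial
    perturbation; ``damage_fraction`` in [0, 0.6] the area fraction removed
    by the cut (0 iff unbroken); ``true_weight`` in grams, assigned by the
    weight model once the silhouette exists.
    """

    class_label: str
    base_radius: float
    elongation: float = 1.0
    boundary_roughness: float = 0.0
    damage_fraction: float = 0.0
    rotation: float = 0.0
    true_weight: float | None = None
    squareness: float = 2.0
    damage_mode: str = "wedge"  # "wedge" | "half_plane"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.class_label not in ("unbroken", "broken"):
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if (self.damage_fraction == 0) != (self.class_label == "unbroken"):
            raise ValueError("damage_fraction must be 0 iff class_label is 'unbroken'")
        if not 0 <= self.damage_fraction <= 0.6:
            raise ValueError("damage_fraction must lie in [0, 0.6]")
        if self.base_radius <= 2:
            raise ValueError("base_radius must exceed 2 px")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if self.true_weight is not None and self.true_weight <= 0:
            raise ValueError("true_weight must be positive")
        if self.damage_mode not in ("wedge", "half_plane"):
            raise ValueError(f"unknown damage_mode {self.damage_mode!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Layout of one multi-kernel scene raster."""

    n_kernels: int
    image_size: tuple[int, int] = (2048, 2592)  # (rows, cols), camera frame
    background_level: float = 40.0
    kernel_level: float = 200.0
    noise_sd: float = 5.0
    min_gap: int = 12
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.kernel_level - self.background_level <= 4 * self.noise_sd:
            raise ValueError(
                "kernel_level - background_level must exceed 4*noise_sd "
                "for the scene to be segmentable by construction"
            )
        if self.n_kernels < 0 or self.min_gap < 0:
            raise ValueError("n_kernels and min_gap must be non-negative")


@dataclass(frozen=True)
class WeightModel:
    """Allometric mass model W = alpha * S_intact_mm2^beta * (1 - damage) * exp(eps).

    ``alpha`` is tuned so a default unbroken kernel (base radius 5 mm)
    weighs ~0.35 g on average; ``beta = 1.5`` is the area-volume exponent;
    ``eps ~ Normal(0, sigma)`` is multiplicative lognormal noise standing in
    for thickness/density variation the 2-D silhouette cannot see.
    """

    alpha: float = 0.35 / (np.pi * 25.0) ** 1.5
    beta: float = 1.5
    sigma: float = 0.05
    mm_per_px: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.sigma < 0 or self.mm_per_px <= 0:
            raise ValueError("sigma must be >= 0 and mm_per_px > 0")


# ---------------------------------------------------------------------------
# silhouettes


def _superellipse_radius(theta: np.ndarray, a: float, b: float, n: float) -> np.ndarray:
    return (np.abs(np.cos(theta) / a) ** n + np.abs(np.sin(theta) / b) ** n) ** (-1.0 / n)


def _area_norm(a: float, b: float, n: float) -> float:
    """Scale factor making the superellipse area equal pi*a*b exactly."""
    area = 4 * a * b * _gamma(1 + 1 / n) ** 2 / _gamma(1 + 2 / n)
    return float(np.sqrt(np.pi * a * b / area))


def _label_count(mask: np.ndarray) -> int:
    return int(measure.label(mask, connectivity=1).max())


def generate_silhouette(spec: KernelSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Rasterize one kernel silhouette as a tight binary mask.

    With ``elongation=1, boundary_roughness=0, squareness=2`` the silhouette
    is a disc of radius ``base_radius``.  For broken specs the cut removes
    ``damage_fraction`` of the pixels (exact up to raster quantization of
    the cut line); a cut that disconnects the mask is retried with a new cut
    direction, up to 10 times.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    a = spec.base_radius * np.sqrt(spec.elongation)
    b = spec.base_radius / np.sqrt(spec.elongation)
    n = spec.squareness
    norm = _area_norm(a, b, n)

    # low-frequency radial perturbation (lobes k = 2..5)
    ks = np.arange(2, 6)
    amps = rng.normal(0.0, spec.boundary_roughness / 2.0, size=ks.size)
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)

    pad = int(np.ceil(norm * a * (1 + np.abs(amps).sum()) )) + 3
    c = pad
    size = 2 * pad + 1
    yy, xx = np.mgrid[0:size, 0:size]
    dx = (xx - c).astype(float)
    dy = (yy - c).astype(float)
    # rotate into the kernel frame
    ca, sa = np.cos(-spec.rotation), np.sin(-spec.rotation)
    rx = dx * ca - dy * sa
    ry = dx * sa + dy * ca
    theta = np.arctan2(ry, rx)
    radius = norm * _superellipse_radius(theta, a, b, n)
    perturb = 1.0 + sum(
        amps[i] * np.cos(ks[i] * theta + phases[i]) for i in range(ks.size)
    )
    mask = np.hypot(rx, ry) <= radius * np.clip(perturb, 0.3, None)

    if _label_count(mask) != 1:
        raise GenerationError("perturbation disconnected the silhouette")

    if spec.damage_fraction > 0:
        mask = _apply_damage(mask, spec, rng)

    return _tight_crop(mask)


def _tight_crop(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _apply_damage(mask: np.ndarray, spec: KernelSpec, rng: np.random.Generator) -> np.ndarray:
    d = spec.damage_fraction
    for _ in range(10):
        fg = np.nonzero(mask)
        ys, xs = fg[0].astype(float), fg[1].astype(float)
        cy, cx = ys.mean(), xs.mean()
        phi = rng.uniform(0, 2 * np.pi)
        if spec.damage_mode == "wedge":
            # remove the angular sector (seen from the centroid) holding the
            # d-quantile of pixels nearest direction phi
            ang = np.arctan2(ys - cy, xs - cx)
            delta = np.abs((ang - phi + np.pi) % (2 * np.pi) - np.pi)
            cut = delta <= np.quantile(delta, d)
        else:
            # half-plane cut at the (1-d) quantile of projections onto phi,
            # with a ragged (cracked) edge
            w = (xs - cx) * np.cos(phi) + (ys - cy) * np.sin(phi)
            s = -(xs - cx) * np.sin(phi) + (ys - cy) * np.cos(phi)
            q = np.quantile(w, 1 - d)
            jag_amp = rng.uniform(0.06, 0.14) * spec.base_radius
            freqs = rng.uniform(0.5, 2.0, size=3)
            ph = rng.uniform(0, 2 * np.pi, size=3)
            jag = sum(
                jag_amp / 3 * np.cos(2 * np.pi * freqs[i] * s / spec.base_radius + ph[i])
                for i in range(3)
            )
            cut = w > q + jag
        new = mask.copy()
        new[fg[0][cut], fg[1][cut]] = False
        achieved = 1 - new.sum() / mask.sum()
        if new.any() and _label_count(new) == 1 and abs(achieved - d) <= 0.05:
            return new
    raise GenerationError(
        f"could not cut damage_fraction={d} without disconnecting the mask"
    )


# ---------------------------------------------------------------------------
# mass


def assign_weight(
    mask: np.ndarray,
    spec: KernelSpec,
    params: WeightModel | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Kernel mass in grams from projected area via the allometric model."""
    params = params or WeightModel()
    if rng is None:
        rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    pixels = getattr(mask, "pixels", mask)
    s_px = float(np.asarray(pixels).astype(bool).sum())
    if s_px == 0:
        raise GenerationError("cannot weigh an empty mask")
    s_mm2 = s_px * params.mm_per_px**2
    s_intact = s_mm2 / (1 - spec.damage_fraction)
    eps = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
    w = params.alpha * s_intact**params.beta * (1 - spec.damage_fraction) * np.exp(eps)
    return float(w)


# ---------------------------------------------------------------------------
# default spec samplers (the study conditions)


def sample_kernel_spec(
    class_label: str, rng: np.random.Generator, base_radius_range: tuple[float, float] | None = None
) -> KernelSpec:
    """Draw a kernel spec from the default population."""
    if base_radius_range is None:
        base_radius_range = (42.0, 58.0) if class_label == "unbroken" else (34.0, 52.0)
    common = dict(
        class_label=class_label,
        base_radius=float(rng.uniform(*base_radius_range)),
        elongation=float(rng.uniform(1.15, 1.7)),
        squareness=float(rng.uniform(2.3, 3.2)),
        rotation=float(rng.uniform(0, np.pi)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if class_label == "unbroken":
        return KernelSpec(boundary_roughness=float(rng.uniform(0.01, 0.04)), **common)
    return KernelSpec(
        boundary_roughness=float(rng.uniform(0.02, 0.06)),
        damage_fraction=float(rng.uniform(0.2, 0.6)),
        damage_mode="wedge" if rng.random() < 0.6 else "half_plane",
        **common,
    )


def _realize(spec: KernelSpec, weight_model: WeightModel) -> tuple[KernelSpec, np.ndarray]:
    """Generate the mask and freeze the kernel's true weight into its spec."""
    mask = generate_silhouette(spec)
    if spec.true_weight is None:
        spec = dataclasses.replace(spec, true_weight=assign_weight(mask, spec, weight_model))
    return spec, mask


# ---------------------------------------------------------------------------
# scenes


def compose_scene(
    specs: list[KernelSpec],
    scene: SceneSpec,
    weight_model: WeightModel | None = None,
    scene_id: str = "scene",
) -> tuple[np.ndarray, list[np.ndarray], pd.DataFrame]:
    """Place kernels on a uniform background with pairwise >= min_gap
    separation, add Gaussian noise, and return (image, masks, ground truth).

    The ground-truth table has one row per placed kernel (same order as the
    returned masks) with columns kernel_id, scene_id, class, true_weight_g,
    bbox_row0, bbox_col0, bbox_row1, bbox_col1 (0-based, half-open).
    """
    weight_model = weight_model or WeightModel()
    rng = np.random.default_rng(scene.seed)
    rows, cols = scene.image_size
    occupied = np.zeros((rows, cols), dtype=bool)
    image = np.full((rows, cols), float(scene.background_level))
    gap = scene.min_gap
    structure = None
    if gap > 0:
        yy, xx = np.mgrid[-gap : gap + 1, -gap : gap + 1]
        structure = xx**2 + yy**2 <= gap**2

    placed_masks: list[np.ndarray] = []
    records = []
    for idx, spec in enumerate(specs):
        spec, mask = _realize(spec, weight_model)
        h, w = mask.shape
        if h > rows or w > cols:
            raise GenerationError(f"kernel {idx} does not fit in the image")
        for _ in range(1000):
            r0 = int(rng.integers(0, rows - h + 1))
            c0 = int(rng.integers(0, cols - w + 1))
            if not (occupied[r0 : r0 + h, c0 : c0 + w] & mask).any():
                break
        else:
            raise GenerationError(f"could not place kernel {idx} at min_gap={gap}")
        if structure is not None:
            grown = binary_dilation(np.pad(mask, gap), structure=structure)
        else:
            grown = mask
        hh, ww = grown.shape
        r_lo, c_lo = r0 - gap, c0 - gap
        rs, cs = max(r_lo, 0), max(c_lo, 0)
        re, ce = min(r_lo + hh, rows), min(c_lo + ww, cols)
        occupied[rs:re, cs:ce] |= grown[rs - r_lo : re - r_lo, cs - c_lo : ce - c_lo]
        image[r0 : r0 + h, c0 : c0 + w][mask] = float(scene.kernel_level)
        placed_masks.append(mask)
        records.append(
            {
                "kernel_id": idx,
                "scene_id": scene_id,
                "class": spec.class_label,
                "true_weight_g": spec.true_weight,
                "bbox_row0": r0,
                "bbox_col0": c0,
                "bbox_row1": r0 + h,
                "bbox_col1": c0 + w,
            }
        )

    if scene.noise_sd > 0:
        image = image + rng.normal(0.0, scene.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    columns = [
        "kernel_id", "scene_id", "class", "true_weight_g",
        "bbox_row0", "bbox_col0", "bbox_row1", "bbox_col1",
    ]
    truth = pd.DataFrame(records, columns=columns)
    return image, placed_masks, truth


# ---------------------------------------------------------------------------
# datasets


def _stratified_counts(class_sizes: dict[str, int], split_fraction: float) -> dict[str, int]:
    """Per-class calibration counts keeping split class proportions within
    5 points of the overall mix even at small n (rounding is searched over
    +/-1 per class for the least-deviating allocation; deterministic)."""
    labels = sorted(class_sizes)
    total = sum(class_sizes.values())
    overall = {c: class_sizes[c] / total for c in labels}

    def deviation(alloc: dict[str, int]) -> float:
        worst = 0.0
        for split_of in (alloc, {c: class_sizes[c] - alloc[c] for c in labels}):
            size = sum(split_of.values())
            if size == 0:
                return np.inf
            worst = max(
                worst, *(abs(split_of[c] / size - overall[c]) for c in labels)
            )
        return worst

    base = {
        c: min(max(int(round(class_sizes[c] * split_fraction)), 1), class_sizes[c] - 1)
        for c in labels
    }
    best, best_key = None, None
    for deltas in itertools.product((0, -1, 1), repeat=len(labels)):
        alloc = {
            c: min(max(base[c] + d, 1), class_sizes[c] - 1)
            for c, d in zip(labels, deltas)
        }
        key = (deviation(alloc), sum(abs(d) for d in deltas))
        if best_key is None or key < best_key:
            best, best_key = alloc, key
    return best


def generate_dataset(
    n_broken: int = 180,
    n_unbroken: int = 120,
    split_fraction: float = 0.75,
    seed: int = DEFAULT_SEED,
    weight_model: WeightModel | None = None,
    return_masks: bool = False,
):
    """Single-kernel feature dataset with a stratified calibration/prediction
    split (defaults: 180 broken -> 135/45, 120 unbroken -> 90/30)."""
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie strictly between 0 and 1")
    if n_broken < 4 or n_unbroken < 4:
        raise ValueError("need at least 4 kernels per class")
    weight_model = weight_model or WeightModel()
    rng = np.random.default_rng(seed)

    records = []
    masks = []
    kid = 0
    for class_label, count in (("broken", n_broken), ("unbroken", n_unbroken)):
        for _ in range(count):
            spec = sample_kernel_spec(class_label, rng)
            spec, mask = _realize(spec, weight_model)
            fv = extract_features(mask, scale=weight_model.mm_per_px)
            rec = {"kernel_id": kid, "class": class_label, "true_weight_g": spec.true_weight}
            rec.update(fv.as_dict())
            records.append(rec)
            masks.append(mask)
            kid += 1
    frame = pd.DataFrame(records, columns=["kernel_id", "class", "true_weight_g", *FEATURE_NAMES])

    frame["split"] = "prediction"
    counts = {c: int((frame["class"] == c).sum()) for c in ("broken", "unbroken")}
    for class_label, n_cal in _stratified_counts(counts, split_fraction).items():
        idx = frame.index[frame["class"] == class_label].to_numpy()
        chosen = rng.permutation(idx)[:n_cal]
        frame.loc[chosen, "split"] = "calibration"

    ds = KernelDataset(frame=frame, seed=seed)
    return (ds, masks) if return_masks else ds


# ---------------------------------------------------------------------------
# bench-test mixtures


def generate_mixture(
    target_rate: float,
    total_mass: float = 10.0,
    rng: np.random.Generator | int | None = None,
    weight_model: WeightModel | None = None,
    scene: SceneSpec | None = None,
    scene_id: str = "mixture",
    max_draws: int = 1000,
):
    """Assemble a scene whose ground-truth broken rate is within +/-0.5
    percentage points of ``target_rate`` (greedy mass packing of ~10 g).

    Returns ``(image, masks, truth_table, truth_result)`` where
    ``truth_result`` is a :class:`~kernelbreak.rate.BrokenRateResult` built
    from the exact packed masses.
    """
    from .rate import BrokenRateResult  # avoid a circular import at module load

    if not 0 <= target_rate <= 100:
        raise ValueError("target_rate must lie in [0, 100]")
    weight_model = weight_model or WeightModel()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def _draw(class_label):
        spec = sample_kernel_spec(class_label, rng)
        spec, _ = _realize(spec, weight_model)
        return spec

    specs: list[KernelSpec] = []
    m_s = 0.0
    if target_rate > 0:
        m_lo = (target_rate - 0.25) / 100 * total_mass
        m_hi = (target_rate + 0.25) / 100 * total_mass
        draws = 0
        while m_s < m_lo:
            if draws >= max_draws:
                raise GenerationError(
                    f"cannot pack broken mass for target rate {target_rate}%"
                )
            spec = _draw("broken")
            draws += 1
            if m_s + spec.true_weight <= m_hi:
                specs.append(spec)
                m_s += spec.true_weight

    # total-mass window: respect both the +/-0.5 pp rate band and ~total_mass
    if target_rate > 0:
        t_lo = max(m_s / ((target_rate + 0.5) / 100), total_mass - 0.5)
        t_hi = min(m_s / ((target_rate - 0.5) / 100) if target_rate > 0.5 else np.inf,
                   total_mass + 0.5)
    else:
        t_lo, t_hi = total_mass - 0.5, total_mass + 0.5
    if t_lo > t_hi:
        raise GenerationError(f"infeasible mass window for target rate {target_rate}%")
    target_total = min(max(total_mass, t_lo), t_hi)

    m_total = m_s
    draws = 0
    while m_total < t_lo or m_total < target_total - 0.3:
        if draws >= max_draws:
            raise GenerationError(
                f"cannot pack unbroken mass for target rate {target_rate}%"
            )
        spec = _draw("unbroken")
        draws += 1
        if m_total + spec.true_weight <= t_hi:
            specs.append(spec)
            m_total += spec.true_weight

    z_true = m_s / m_total * 100
    if abs(z_true - target_rate) > 0.5:
        raise GenerationError(
            f"packed rate {z_true:.2f}% misses target {target_rate}% by > 0.5 pp"
        )

    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    scene = scene or SceneSpec(n_kernels=len(specs), seed=int(rng.integers(0, 2**31 - 1)))
    if scene.n_kernels != len(specs):
        scene = dataclasses.replace(scene, n_kernels=len(specs))
    image, masks, truth = compose_scene(specs, scene, weight_model, scene_id=scene_id)

    per_kernel = truth[["kernel_id", "class", "true_weight_g"]].rename(
        columns={"class": "predicted_class", "true_weight_g": "predicted_weight_g"}
    )
    truth_result = BrokenRateResult.from_masses(
        m_s=float(truth.loc[truth["class"] == "broken", "true_weight_g"].sum()),
        m_i=float(truth["true_weight_g"].sum()),
        per_kernel=per_kernel,
    )
    return image, masks, truth, truth_result
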