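"""Labeled voxel head phantoms with randomized anatomy and lesions.

The study population is generated from a single reference head model.  Each
subject is derived from it by (optionally) inserting a spherical blood
lesion inside the cranial cavity, rescaling the volume along the three axes
to randomly drawn anthropometric head measures, and adding a hair layer of
random integer thickness.  The reference model here is a synthetic
concentric-ellipsoid head (skin, fat, muscle, skull, CSF, grey matter shell,
white matter core, ventricular CSF); any externally supplied labeled volume
with the same label map can be dropped in instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import ndimage
from scipy.stats import norm

__all__ = [
    "LABELS",
    "LABEL_MAP",
    "VoxelPhantom",
    "AnthropometricTable",
    "BleedingSpec",
    "DEFAULT_ANTHROPOMETRIC_TABLE",
    "make_reference_phantom",
    "combine_gender_percentiles",
    "draw_head_measures",
    "compute_scale_factors",
    "rescale_phantom",
    "add_hair",
    "insert_bleeding",
    "randomize_subject",
]

# Integer label codes.  Blood exists only after lesion insertion; hair only
# after the hair step.
LABELS = {
    "background": 0,
    "skin": 1,
    "fat": 2,
    "muscle": 3,
    "skull": 4,
    "csf": 5,
    "grey_matter": 6,
    "white_matter": 7,
    "hair": 8,
    "blood": 9,
}
LABEL_MAP = {v: k for k, v in LABELS.items()}

# Largest lesion volume considered clinically realistic here, in mL.
MAX_BLEEDING_ML = 105.0

Z99 = norm.ppf(0.99)  # 2.3263...


@dataclass
class BleedingSpec:
    """One spherical lesion: center voxel, radius (mm), achieved volume (mL)."""

    center: tuple[int, int, int]
    radius: float
    volume_ml: float


@dataclass
class VoxelPhantom:
    """3D integer-labeled tissue volume with physical voxel size.

    ``provenance`` accumulates a record per applied transform so a subject
    model is traceable to its reference and random draws.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_map: dict[int, str] = field(default_factory=lambda: dict(LABEL_MAP))
    provenance: list[dict] = field(default_factory=list)
    validate: bool = True
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a non-empty 3D array")
        if self.validate:  # O(n) scan; internal copies skip it
            present = set(np.unique(self.labels).tolist())
            unknown = present - set(self.label_map)
            if unknown:
                raise ValueError(f"labels {unknown} missing from label_map")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def extent_mm(self, axis: int) -> float:
        """Physical extent of non-background support along an axis."""
        support = self.labels != LABELS["background"]
        proj = np.any(support, axis=tuple(i for i in range(3) if i != axis))
        idx = np.flatnonzero(proj)
        if idx.size == 0:
            return 0.0
        return float((idx[-1] - idx[0] + 1) * self.voxel_size[axis])

    def tissue_mask(self, *names: str) -> np.ndarray:
        codes = [LABELS[n] for n in names]
        return np.isin(self.labels, codes)

    def cranial_cavity(self) -> np.ndarray:
        """Brain support eligible to host a lesion.

        Grey and white matter plus any enclosed (ventricular) CSF; the
        subarachnoid CSF shell outside the brain is excluded by the hole
        fill.
        """
        brain = self.tissue_mask("grey_matter", "white_matter", "blood")
        return ndimage.binary_fill_holes(brain)

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            labels=self.labels.copy(),
            voxel_size=tuple(self.voxel_size),
            label_map=dict(self.label_map),
            provenance=[dict(p) for p in self.provenance],
            validate=False,
        )

    # -- persistence -------------------------------------------------------

    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=self.labels.astype(np.int8),
                             compression="gzip")
            f.attrs["voxel_size"] = np.asarray(self.voxel_size, dtype=float)
            f.attrs["label_map"] = json.dumps(
                {str(k): v for k, v in self.label_map.items()})
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def load_hdf5(cls, path) -> "VoxelPhantom":
        with h5py.File(path, "r") as f:
            labels = f["labels"][...]
            voxel_size = tuple(float(v) for v in f.attrs["voxel_size"])
            label_map = {int(k): v for k, v in
                         json.loads(f.attrs["label_map"]).items()}
            provenance = json.loads(f.attrs["provenance"])
        return cls(labels=labels, voxel_size=voxel_size,
                   label_map=label_map, provenance=provenance)

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, labels=self.labels.astype(np.int8),
            voxel_size=np.asarray(self.voxel_size, dtype=float),
            label_map=json.dumps({str(k): v for k, v in self.label_map.items()}),
            provenance=json.dumps(self.provenance))


# ---------------------------------------------------------------------------
# Reference phantom
# ---------------------------------------------------------------------------

# Reference head measures (mm): ear-to-ear (x), forehead-to-neck (y),
# top-of-head to below-eye (z).
REFERENCE_MEASURES = (180.0, 210.0, 150.0)

DEFAULT_SHELLS_MM = {
    "skin": 2.0,
    "fat": 2.0,
    "muscle": 3.0,
    "skull": 7.0,
    "csf": 3.0,
    "grey_matter": 15.0,
}


def make_reference_phantom(
    measures: tuple[float, float, float] = REFERENCE_MEASURES,
    shells_mm: dict[str, float] | None = None,
    voxel_size: float = 1.0,
    ventricles: bool = True,
    margin_voxels: int = 2,
) -> VoxelPhantom:
    """Build the synthetic concentric-ellipsoid reference head.

    The outer ellipsoid has axis extents equal to ``measures``; successive
    shells (skin, fat, muscle, skull, CSF, grey matter) of the given
    thickness wrap a white-matter core.  Two small ellipsoidal CSF
    ventricles sit inside the white matter.  Shell thickness 0 removes that
    label from the output.
    """
    shells = dict(DEFAULT_SHELLS_MM)
    if shells_mm:
        shells.update(shells_mm)
    semi = np.asarray(measures, dtype=float) / 2.0
    order = ["skin", "fat", "muscle", "skull", "csf", "grey_matter"]
    total = sum(shells.get(n, 0.0) for n in order)
    if total >= semi.min():
        raise ValueError(
            f"cumulative shell thickness {total} mm exceeds the smallest "
            f"outer semi-axis {semi.min()} mm")

    shape = tuple(int(np.ceil(2 * s / voxel_size)) + 2 * margin_voxels + 1
                  for s in semi)
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * voxel_size for n in shape
    ]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]

    def ellipsoid(sa: np.ndarray, center=(0.0, 0.0, 0.0)) -> np.ndarray:
        return ((x - center[0]) / sa[0]) ** 2 + \
               ((y - center[1]) / sa[1]) ** 2 + \
               ((z - center[2]) / sa[2]) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int8)
    current = semi.copy()
    masks = []
    for name in order:
        t = shells.get(name, 0.0)
        masks.append((name, ellipsoid(current)))
        current = current - t
    masks.append(("white_matter", ellipsoid(current)))
    # paint outside-in so inner structures overwrite outer shells
    for name, mask in masks:
        labels[mask] = LABELS[name]
    if ventricles:
        v_semi = np.array([8.0, 25.0, 10.0])
        for cx in (-14.0, 14.0):
            labels[ellipsoid(v_semi, center=(cx, 0.0, 0.0))] = LABELS["csf"]

    phantom = VoxelPhantom(
        labels=labels,
        voxel_size=(voxel_size,) * 3,
        provenance=[{
            "op": "make_reference_phantom",
            "measures_mm": list(measures),
            "shells_mm": shells,
            "voxel_size_mm": voxel_size,
        }],
    )
    return phantom


# ---------------------------------------------------------------------------
# Anthropometric rescaling
# ---------------------------------------------------------------------------

def combine_gender_percentiles(male: tuple[float, float, float],
                               female: tuple[float, float, float]
                               ) -> tuple[float, float, float]:
    """Combine male and female (p1, p50, p99) head-measure percentiles.

    The pooled population spans the female 1st percentile to the male 99th;
    its median is the mean of the two medians.
    """
    for name, triple in (("male", male), ("female", female)):
        if not (triple[0] < triple[1] < triple[2]):
            raise ValueError(f"{name} percentiles must be strictly "
                             f"increasing, got {triple}")
    return (female[0], (male[1] + female[1]) / 2.0, male[2])


@dataclass(frozen=True)
class AnthropometricTable:
    """Per-measure (p1, p50, p99) percentiles, mm, by gender and combined."""

    male: dict[str, tuple[float, float, float]]
    female: dict[str, tuple[float, float, float]]

    @property
    def combined(self) -> dict[str, tuple[float, float, float]]:
        return {m: combine_gender_percentiles(self.male[m], self.female[m])
                for m in self.male}

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(self.male)


# US adult head-size percentiles (mm) for the three measures used to rescale
# the reference head.
DEFAULT_ANTHROPOMETRIC_TABLE = AnthropometricTable(
    male={
        "ear_ear": (142.0, 155.0, 169.0),
        "forehead_neck": (180.0, 196.0, 214.0),
        "top_below_eye": (112.0, 125.0, 137.0),
    },
    female={
        "ear_ear": (132.0, 145.0, 159.0),
        "forehead_neck": (162.0, 180.0, 198.0),
        "top_below_eye": (109.0, 122.0, 135.0),
    },
)


def draw_head_measures(table: AnthropometricTable,
                       rng: np.random.Generator) -> tuple[float, float, float]:
    """Draw one subject's three head measures (mm).

    Each measure is drawn independently from a normal with mean equal to the
    combined median and standard deviation ``(p99 - p1) / (2 z_{0.99})`` so
    the drawn 1st/99th percentiles match the combined table.  Draws are
    truncated to ``[p1 - (p50 - p1), p99 + (p99 - p50)]`` to exclude absurd
    tails (about +-4.7 sd, so the truncation is essentially never active).
    """
    out = []
    for measure in table.measures:
        p1, p50, p99 = table.combined[measure]
        sd = (p99 - p1) / (2.0 * Z99)
        v = rng.normal(p50, sd)
        v = float(np.clip(v, p1 - (p50 - p1), p99 + (p99 - p50)))
        out.append(v)
    return tuple(out)


def compute_scale_factors(targets, originals) -> tuple[float, float, float]:
    """Per-axis scale factors: ratio of desired to original measures."""
    targets = np.asarray(targets, dtype=float)
    originals = np.asarray(originals, dtype=float)
    if np.any(originals <= 0):
        raise ValueError("original measures must be positive")
    return tuple((targets / originals).tolist())


def _nn_index_map(n_out: int, factor: float, n_in: int) -> np.ndarray:
    # voxel-center alignment: output center (i+0.5)/factor in input units,
    # mapped to the nearest input voxel with round-half-up
    centers = (np.arange(n_out) + 0.5) / factor
    idx = np.floor(centers).astype(int)  # == round_half_up(centers - 0.5)
    return np.clip(idx, 0, n_in - 1)


def rescale_phantom(phantom: VoxelPhantom, factors) -> VoxelPhantom:
    """Nearest-neighbor resample of the label grid by per-axis factors.

    Output dimensions are ``round(n * factor)`` (half up); voxel size is
    unchanged, so the head is physically rescaled.
    """
    factors = tuple(float(f) for f in factors)
    if any(f <= 0 for f in factors):
        raise ValueError("scale factors must be positive")
    n_in = phantom.labels.shape
    n_out = tuple(int(np.floor(n * f + 0.5)) for n, f in zip(n_in, factors))
    if min(n_out) < 3:
        raise ValueError(f"output dimensions {n_out} too small (< 3 voxels)")
    out = phantom.labels
    for axis in range(3):
        idx = _nn_index_map(n_out[axis], factors[axis], n_in[axis])
        out = np.take(out, idx, axis=axis)
    return VoxelPhantom(
        labels=out,
        voxel_size=tuple(phantom.voxel_size),
        label_map=dict(phantom.label_map),
        provenance=phantom.provenance + [{
            "op": "rescale_phantom", "factors": list(factors)}],
        validate=False,
    )


# ---------------------------------------------------------------------------
# Hair
# ---------------------------------------------------------------------------

def add_hair(phantom: VoxelPhantom, thickness: int | None = None,
             rng: np.random.Generator | None = None,
             exclude: np.ndarray | None = None) -> VoxelPhantom:
    """Add a hair shell of integer thickness (mm) on the scalp surface.

    ``thickness`` is drawn uniformly from {0, ..., 4} when omitted.  The
    shell is the set of background voxels within ``thickness`` mm (Euclidean)
    of the head support, optionally minus an ``exclude`` mask (face/ears).
    """
    if thickness is None:
        if rng is None:
            raise ValueError("need rng to draw a random thickness")
        thickness = int(rng.integers(0, 5))
    thickness = int(thickness)
    if not (0 <= thickness <= 4):
        raise ValueError(f"hair thickness must be in 0..4 mm, got {thickness}")
    out = phantom.copy()
    out.provenance.append({"op": "add_hair", "thickness_mm": thickness})
    if thickness == 0:
        return out
    background = phantom.labels == LABELS["background"]
    dist = ndimage.distance_transform_edt(
        background, sampling=phantom.voxel_size)
    shell = background & (dist <= thickness)
    if exclude is not None:
        shell &= ~exclude
    out.labels[shell] = LABELS["hair"]
    return out


# ---------------------------------------------------------------------------
# Spherical bleeding
# ---------------------------------------------------------------------------

def radius_from_volume_ml(volume_ml: float) -> float:
    """Radius (mm) of a sphere of the given volume (mL = cm^3)."""
    return (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _offset_norms(max_radius_mm: float, voxel_size) -> np.ndarray:
    """Sorted distances (mm) from a voxel center to all lattice offsets
    within ``max_radius_mm``."""
    r = [int(np.ceil(max_radius_mm / v)) for v in voxel_size]
    ox = np.arange(-r[0], r[0] + 1) * voxel_size[0]
    oy = np.arange(-r[1], r[1] + 1) * voxel_size[1]
    oz = np.arange(-r[2], r[2] + 1) * voxel_size[2]
    d = np.sqrt(ox[:, None, None] ** 2 + oy[None, :, None] ** 2
                + oz[None, None, :] ** 2).ravel()
    return np.sort(d[d <= max_radius_mm])


def _cavity_geometry(phantom: VoxelPhantom):
    """Distance transform of the cranial cavity, cached on the phantom."""
    cache = phantom._cache
    if "cavity" not in cache:
        cavity = phantom.cranial_cavity()
        if not cavity.any():
            raise ValueError("phantom has no cranial cavity")
        edt = ndimage.distance_transform_edt(
            cavity, sampling=phantom.voxel_size)
        flat = np.flatnonzero(cavity)
        depths = edt.ravel()[flat]
        order = np.argsort(depths)
        cache["cavity"] = (cavity, flat[order], depths[order])
    return cache["cavity"]


def insert_bleeding(phantom: VoxelPhantom, rng: np.random.Generator,
                    volume_range_ml: tuple[float, float] = (0.0, MAX_BLEEDING_ML),
                    max_retries: int = 50,
                    ) -> tuple[VoxelPhantom, BleedingSpec]:
    """Insert one spherical blood lesion fully inside the cranial cavity.

    The sphere radius is drawn uniformly between the radii of the smallest
    and largest admissible volumes (which makes small lesion volumes
    dominate: the induced volume density is proportional to V^(-2/3)).  The
    upper radius is capped so the *voxelized* sphere never exceeds the upper
    volume bound.  The center is drawn uniformly from all cavity voxels
    whose distance to the cavity boundary is at least the radius; if none
    exist the radius is redrawn, up to ``max_retries`` times.
    """
    v_lo, v_hi = volume_range_ml
    if not (0.0 <= v_lo < v_hi):
        raise ValueError(f"invalid volume range {volume_range_ml}")
    vox_vol = phantom.voxel_volume_mm3
    r_lo = radius_from_volume_ml(v_lo) if v_lo > 0 else 0.0
    r_hi = radius_from_volume_ml(v_hi)
    norms = _offset_norms(r_hi + max(phantom.voxel_size), phantom.voxel_size)
    # cap the radius so the voxel count never exceeds the volume bound
    max_voxels = int(np.floor(v_hi * 1000.0 / vox_vol))
    if norms.size > max_voxels:
        r_cap = 0.5 * (norms[max_voxels - 1] + norms[max_voxels])
        r_hi = min(r_hi, np.nextafter(r_cap, 0.0))

    cavity, sorted_idx, sorted_depth = _cavity_geometry(phantom)

    for _ in range(max_retries):
        radius = float(rng.uniform(r_lo, r_hi))
        lo = np.searchsorted(sorted_depth, radius, side="left")
        n_eligible = sorted_idx.size - lo
        if n_eligible > 0:
            break
    else:
        raise RuntimeError(
            f"no eligible lesion center found in {max_retries} radius draws")
    pick = sorted_idx[lo + int(rng.integers(0, n_eligible))]
    center = tuple(int(c) for c in np.unravel_index(pick, phantom.labels.shape))

    out = phantom.copy()
    # relabel the voxelized ball inside a bounding box
    half = [int(np.ceil(radius / v)) for v in phantom.voxel_size]
    sl = tuple(slice(max(0, c - h), min(n, c + h + 1))
               for c, h, n in zip(center, half, phantom.labels.shape))
    grids = np.ogrid[sl]
    dist2 = sum(((g - c) * v) ** 2
                for g, c, v in zip(grids, center, phantom.voxel_size))
    ball = (dist2 <= radius ** 2) & cavity[sl]
    out.labels[sl][ball] = LABELS["blood"]
    volume_ml = float(ball.sum() * vox_vol / 1000.0)
    spec = BleedingSpec(center=center, radius=radius, volume_ml=volume_ml)
    out.provenance.append({
        "op": "insert_bleeding", "center": list(center),
        "radius_mm": radius, "volume_ml": volume_ml})
    return out, spec


def draw_bleeding_volume_ml(rng: np.random.Generator,
                            volume_range_ml=(0.0, MAX_BLEEDING_ML)) -> float:
    """Draw a lesion volume (mL) from the uniform-radius law.

    The sampler draws the sphere *radius* uniformly, so the induced volume
    density is proportional to V^(-2/3) and small volumes dominate.  This is
    the analytic form of the law realized voxel-wise by
    :func:`insert_bleeding`; surrogate cohorts share it without building a
    phantom.
    """
    v_lo, v_hi = volume_range_ml
    r_lo = radius_from_volume_ml(v_lo) if v_lo > 0 else 0.0
    r_hi = radius_from_volume_ml(v_hi)
    r = rng.uniform(r_lo, r_hi)
    return float(4.0 / 3.0 * np.pi * r ** 3 / 1000.0)


def sample_bleeding_volume(phantom: VoxelPhantom, rng: np.random.Generator,
                           volume_range_ml=(0.0, MAX_BLEEDING_ML)) -> float:
    """Draw a lesion and return only its achieved volume (mL).

    Convenience wrapper over :func:`insert_bleeding` used by surrogate
    cohorts, which need the lesion-volume law but not the voxel relabeling.
    """
    _, spec = insert_bleeding(phantom, rng, volume_range_ml)
    return spec.volume_ml


# ---------------------------------------------------------------------------
# Full subject randomization
# ---------------------------------------------------------------------------

def randomize_subject(reference: VoxelPhantom,
                      rng: np.random.Generator,
                      bleeding: bool = False,
                      table: AnthropometricTable = DEFAULT_ANTHROPOMETRIC_TABLE,
                      original_measures=REFERENCE_MEASURES,
                      volume_range_ml=(0.0, MAX_BLEEDING_ML),
                      bleed_before_rescale: bool = True,
                      ) -> tuple[VoxelPhantom, BleedingSpec | None]:
    """Derive one randomized subject from the reference head.

    Pipeline: insert the lesion (patients only) *before* rescaling, then
    draw target head measures, rescale by the target/original ratios, and
    add a random 0--4 mm hair layer.  ``bleed_before_rescale=False``
    reverses the lesion/rescale order for experimentation.
    """
    spec = None
    p = reference
    if bleeding and bleed_before_rescale:
        p, spec = insert_bleeding(p, rng, volume_range_ml)
    targets = draw_head_measures(table, rng)
    factors = compute_scale_factors(targets, original_measures)
    p = rescale_phantom(p, factors)
    if bleeding and not bleed_before_rescale:
        p, spec = insert_bleeding(p, rng, volume_range_ml)
    p = add_hair(p, thickness=None, rng=rng)
    return p, spec
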