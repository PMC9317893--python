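"""Synthetic T1-like brain phantoms, atlas libraries and study cohorts.

The phantom is a stylized brain: nested ellipsoids of CSF, cortical gray
matter and a white-matter core, with mirrored ventricles, thalami and globus
pallidus (GP) structures.  The GP sits between central gray matter (medial,
darker) and white matter (lateral, brighter), so that segmentation boundary
errors contaminate its intensity sample from both below and above — the
situation the percentile-based index has to be robust to.  A smooth
deterministic intensity texture rides on every tissue so that registration
and per-region atlas ranking are well posed inside otherwise homogeneous
tissue.

Cohorts emulate four groups that differ only in the GP intensity offset
relative to gray matter: healthy controls (no shift), cirrhosis without
encephalopathy (slight hyperintensity), cirrhosis with encephalopathy
(clear hyperintensity, from pallidal manganese deposition) and dementia
(slight hypointensity, from ischemic change).  Atlases are random smooth
diffeomorphic deformations of the template with per-atlas noise; their
ground-truth deformation fields are retained for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError, GeometryError, ValidationError
from .registration import DeformationField, exp_velocity, warp_array
from .volume_io import (
    COARSE,
    DEFAULT_FINE_LABELS,
    FINE,
    GP_LEFT,
    GP_RIGHT,
    LabelMap,
    Volume,
)

logger = logging.getLogger("pallidex")

GROUPS = ("HC", "LC_noHE", "LC_HE", "dementia")

_FWHM_TO_SIGMA = 1.0 / 2.35482004503


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and corruption model of one synthetic subject.

    Tissue means are in arbitrary scanner units before any normalization;
    ``gp_shift`` is the signed relative GP offset versus the gray-matter
    baseline (+0.08 = 8% hyperintense).  ``noise_sd`` is additive Gaussian
    noise as a fraction of the white-matter mean, applied after the
    multiplicative bias field.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_means: tuple[float, float, float] = (0.3, 0.7, 1.4)  # CSF, GM, WM
    gp_shift: float = 0.0
    gp_gradient: float = 1.0
    gp_extent_pct: float = 50.0
    noise_sd: float = 0.03
    bias_amplitude: float = 0.2
    bias_fwhm_mm: float = 48.0
    texture_amplitude: float = 0.15
    deform_amplitude_mm: float = 8.0
    deform_fwhm_mm: float = 24.0
    n_coarse_regions: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        csf, gm, wm = self.tissue_means
        if not (csf < gm < wm):
            raise ValidationError("tissue means must be strictly increasing CSF < GM < WM")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if abs(self.bias_amplitude) >= 1:
            raise ValidationError("|bias_amplitude| must be < 1")
        if min(self.grid_shape) < 32:
            raise ValidationError("grid_shape must be >= 32 per axis")
        if self.n_coarse_regions < 1:
            raise ValidationError("need at least one coarse region")


@dataclass(frozen=True)
class CohortSpec:
    """Four-group study layout.

    Default group sizes follow the study design (11 healthy controls, 16
    cirrhotics without encephalopathy, 10 with); the dementia arm (250 in
    the study) defaults to a desk-scale 12 and is configurable.  Per-group
    GP shifts are drawn from Normal(mean, sd).
    """

    sizes: dict = field(default_factory=lambda: {
        "HC": 11, "LC_noHE": 16, "LC_HE": 10, "dementia": 12})
    shift_means: dict = field(default_factory=lambda: {
        "HC": 0.0, "LC_noHE": 0.02, "LC_HE": 0.08, "dementia": -0.04})
    shift_sd: float = 0.03
    #: between-subject SD of the deposition extent (percent of GP volume)
    extent_sd: float = 8.0
    base: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.sizes.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r}")
            if n < 0:
                raise ValidationError("group sizes must be >= 0")
        if self.shift_sd < 0:
            raise ValidationError("shift_sd must be >= 0")


@dataclass
class Atlas:
    """One library entry: T1 volume, fine labels, coarse regions, truth field."""

    id: int
    volume: Volume
    fine: LabelMap
    coarse: LabelMap
    true_field: DeformationField | None = None


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _world_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World mm coordinates with the origin at the grid center."""
    shape = spec.grid_shape
    axes = [(np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * s
            for n, s in zip(shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def template_affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.diag(list(spec.spacing) + [1.0])
    aff[:3, 3] = [-(n - 1) / 2.0 * s for n, s in zip(spec.grid_shape, spec.spacing)]
    return aff


def _structure_geometry(spec: PhantomSpec) -> dict[str, tuple]:
    """Structure centers/semi-axes in mm, scaled to the field of view."""
    fov = min(n * s for n, s in zip(spec.grid_shape, spec.spacing))
    u = fov / 128.0   # geometry designed on a 128 mm field of view
    return {
        "brain": ((0, 0, 0), (52 * u, 44 * u, 44 * u)),
        "gm_outer": ((0, 0, 0), (47 * u, 40 * u, 40 * u)),
        "wm": ((0, 0, 0), (38 * u, 31 * u, 31 * u)),
        "ventricle_l": ((-6 * u, 8 * u, 8 * u), (5 * u, 10 * u, 6 * u)),
        "ventricle_r": ((6 * u, 8 * u, 8 * u), (5 * u, 10 * u, 6 * u)),
        "thalamus_l": ((-9 * u, -6 * u, -2 * u), (7 * u, 8 * u, 7 * u)),
        "thalamus_r": ((9 * u, -6 * u, -2 * u), (7 * u, 8 * u, 7 * u)),
        "gp_l": ((-18 * u, -4 * u, 0), (8 * u, 5 * u, 6 * u)),
        "gp_r": ((18 * u, -4 * u, 0), (8 * u, 5 * u, 6 * u)),
        "putamen_l": ((-28 * u, -2 * u, 0), (6 * u, 9 * u, 8 * u)),
        "putamen_r": ((28 * u, -2 * u, 0), (6 * u, 9 * u, 8 * u)),
        "caudate_l": ((-12 * u, 12 * u, 10 * u), (5 * u, 9 * u, 6 * u)),
        "caudate_r": ((12 * u, 12 * u, 10 * u), (5 * u, 9 * u, 6 * u)),
        "brainstem": ((0, -14 * u, -26 * u), (10 * u, 10 * u, 14 * u)),
    }


#: fine-label render order; later entries overwrite earlier ones
_STRUCTURE_ORDER: list[tuple[str, int]] = [
    ("brain", 1), ("gm_outer", 2), ("wm", 3),
    ("ventricle_l", 4), ("ventricle_r", 4),
    ("thalamus_l", 5), ("thalamus_r", 6),
    ("caudate_l", 11), ("caudate_r", 12),
    ("brainstem", 13),
    ("putamen_l", 9), ("putamen_r", 10),
    ("gp_l", 7), ("gp_r", 8),
]


def _carve_sulci(labels: np.ndarray, x, y, z) -> None:
    """CSF clefts cutting into the cortical shell (anatomical edge density)."""
    az = np.arctan2(y, x)
    el = np.arctan2(z, np.sqrt(x ** 2 + y ** 2) + 1e-9)
    clefts = (np.cos(5 * az + 0.4) > 0.90) | (np.cos(4 * el + 7 * az) > 0.95)
    labels[(labels == 2) & clefts] = 1


#: texture damping inside deep nuclei/ventricles (labels >= 4): deep gray
#: structures are far more homogeneous than cortex and white matter
_DEEP_TEXTURE_FACTOR = 0.3


def _texture(spec: PhantomSpec, x, y, z,
             labels: np.ndarray | None = None) -> np.ndarray:
    """Deterministic smooth multiplicative texture in [1-a, 1+a]."""
    a = spec.texture_amplitude
    t = (np.cos(2 * np.pi * x / 37.0)
         + np.cos(2 * np.pi * y / 29.0 + 0.7)
         + np.cos(2 * np.pi * z / 23.0 + 1.3)) / 3.0
    amp = np.full(t.shape, a)
    if labels is not None:
        amp[labels >= 4] = a * _DEEP_TEXTURE_FACTOR
    return 1.0 + amp * t


def _render(spec: PhantomSpec, labels: np.ndarray, gp_shift: float,
            texture: np.ndarray, x: np.ndarray,
            extent_pct: float | None = None) -> np.ndarray:
    csf, gm, wm = spec.tissue_means
    lut = np.zeros(16)
    lut[1] = csf            # csf shell
    lut[2] = gm             # cortex
    lut[3] = wm             # white matter
    lut[4] = csf            # ventricles
    lut[5] = gm             # thalamus L
    lut[6] = gm             # thalamus R
    lut[7] = gm             # GP L (shift applied below)
    lut[8] = gm             # GP R
    lut[9] = gm             # putamen L
    lut[10] = gm            # putamen R
    lut[11] = gm            # caudate L
    lut[12] = gm            # caudate R
    lut[13] = gm            # brainstem
    data = lut[labels]
    # GP intensity model.  Hyperintensity (manganese deposition) concentrates
    # in the lateral pallidal compartment: the profile is a sharp mean-one
    # sigmoid of the lateral coordinate, with the medial/lateral boundary at
    # ``extent_pct`` percent of the structure's volume — the deposition
    # *extent* varies between subjects, which is what makes mid-junction
    # statistics (the sample median) erratic while upper-middle percentiles
    # robustly sample the affected compartment.  The mean GP/GM ratio stays
    # exactly 1 + shift, and affected subjects show the bimodal
    # "high-intensity peak" histogram.  Hypointensity (diffuse ischemic
    # change, negative shift) applies uniformly.
    if extent_pct is None:
        extent_pct = spec.gp_extent_pct
    for lab in (7, 8):
        m = labels == lab
        if not m.any():
            continue
        if gp_shift > 0:
            u = np.abs(x[m])
            c = np.percentile(u, extent_pct)
            half = (u.max() - u.min()) / 2.0
            w = 0.06 * half if half > 0 else 1.0
            raw = 1.0 / (1.0 + np.exp(-(u - c) / w))
            g = 1.0 + spec.gp_gradient * (raw / raw.mean() - 1.0)
        else:
            g = 1.0
        data[m] = gm * (1.0 + gp_shift * g)
    return data * texture


def make_template(spec: PhantomSpec
                  ) -> tuple[Volume, LabelMap, LabelMap]:
    """Deterministic template: T1 volume, fine labels, coarse regions.

    The fine map has 8 nonzero labels including gp_left/gp_right; the coarse
    map tiles the brain into ``spec.n_coarse_regions`` compact regions
    (Voronoi cells of deterministically placed seeds).
    """
    x, y, z = _world_coords(spec)
    geo = _structure_geometry(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    for name, lab in _STRUCTURE_ORDER:
        c, s = geo[name]
        labels[_ellipsoid(x, y, z, c, s)] = lab
    _carve_sulci(labels, x, y, z)
    for lab in (7, 8):
        if not (labels == lab).any():
            raise GeometryError("grid too small: GP structure has no voxels")
    if len(np.unique(labels)) < 9:
        raise GeometryError("grid too small to contain all structures")

    texture = _texture(spec, x, y, z, labels)
    data = _render(spec, labels, spec.gp_shift, texture, x)
    aff = template_affine(spec)
    vol = Volume(data, spec.spacing, aff)
    fine = LabelMap(labels, spec.spacing, aff, FINE, dict(DEFAULT_FINE_LABELS))
    coarse = _coarse_partition(labels > 0, spec, aff)
    return vol, fine, coarse


def _coarse_partition(brain: np.ndarray, spec: PhantomSpec,
                      affine: np.ndarray) -> LabelMap:
    """Voronoi tiling of the brain mask into n compact large regions."""
    n = spec.n_coarse_regions
    coords = np.argwhere(brain)
    if len(coords) < n:
        raise GeometryError("fewer brain voxels than requested regions")
    # deterministic, seed-independent: evenly spaced picks in C-order,
    # compacted by a few Lloyd iterations (keeps every cell nonempty)
    picks = coords[np.linspace(0, len(coords) - 1, n).round().astype(int)]
    sp = np.asarray(spec.spacing)
    centers = picks * sp
    pts = coords * sp
    assign = None
    for _ in range(8):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(n):
            sel = pts[assign == c]
            if len(sel):
                centers[c] = sel.mean(axis=0)
    assign = assign + 1
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    labels[tuple(coords.T)] = assign
    ldict = {0: "background"}
    ldict.update({i + 1: f"region_{i + 1:02d}" for i in range(n)})
    return LabelMap(labels, spec.spacing, affine, COARSE, ldict)


# ---------------------------------------------------------------------------
# random smooth diffeomorphic deformations
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    raw = rng.standard_normal((3,) + tuple(shape))
    return np.stack([ndimage.gaussian_filter(raw[k], sigma_vox)
                     for k in range(3)])


def random_deformation(spec: PhantomSpec, rng: np.random.Generator,
                       amplitude_mm: float | None = None) -> DeformationField:
    """Random smooth diffeomorphic field on the template grid.

    A Gaussian-smoothed random velocity is scaled so its largest voxel
    displacement equals the requested amplitude, then integrated by
    scaling-and-squaring.  If the numerical Jacobian is not strictly
    positive the field is regenerated at reduced amplitude.
    """
    amp = spec.deform_amplitude_mm if amplitude_mm is None else amplitude_mm
    sp = np.asarray(spec.spacing)
    sigma_vox = spec.deform_fwhm_mm * _FWHM_TO_SIGMA / sp
    aff = template_affine(spec)
    if amp == 0:
        return DeformationField(np.zeros((3,) + tuple(spec.grid_shape)),
                                spec.spacing, aff)
    for attempt in range(5):
        vel = _smooth_field(rng, spec.grid_shape, sigma_vox)
        mx = np.sqrt((vel ** 2).sum(axis=0)).max()
        if mx > 0:
            vel *= (amp / sp.mean()) / mx
        disp_vox = exp_velocity(vel)
        field = DeformationField(disp_vox * sp[:, None, None, None],
                                 spec.spacing, aff)
        if field.min_jacobian() > 0:
            return field
        logger.warning("deformation had non-positive Jacobian; "
                       "retrying at reduced amplitude")
        amp *= 0.7
    raise GeometryError("could not generate a diffeomorphic deformation")


# ---------------------------------------------------------------------------
# atlases and subjects
# ---------------------------------------------------------------------------

def make_atlas_library(n_atlases: int, spec: PhantomSpec,
                       seed: int | None = None) -> list[Atlas]:
    """Warp the template by independent random diffeomorphisms.

    Intensities are warped linearly and perturbed by per-atlas noise;
    labels are warped nearest-neighbor by the same field.
    """
    if n_atlases < 1:
        raise ContractError("n_atlases must be >= 1")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tvol, tfine, tcoarse = make_template(spec)
    wm = spec.tissue_means[2]
    out = []
    for i in range(n_atlases):
        fld = random_deformation(spec, rng)
        dv = fld.disp_vox()
        data = warp_array(tvol.data, dv, order=1)
        if spec.noise_sd > 0:
            data = data + rng.standard_normal(data.shape) * spec.noise_sd * wm
        fine = tfine.with_labels(
            warp_array(tfine.labels.astype(np.float64), dv, order=0).astype(np.int32))
        coarse = tcoarse.with_labels(
            warp_array(tcoarse.labels.astype(np.float64), dv, order=0).astype(np.int32))
        out.append(Atlas(i, tvol.with_data(data), fine, coarse, fld))
    return out


def _draw_shift(group: str, cohort: CohortSpec, rng: np.random.Generator) -> float:
    return float(rng.normal(cohort.shift_means[group], cohort.shift_sd))


def make_subject(group: str, cohort: CohortSpec, seed: int
                 ) -> tuple[Volume, LabelMap]:
    """One synthetic subject of a group; returns (T1 volume, truth labels).

    Construction: GP intensity is set to GM * (1 + shift) with shift drawn
    from the group distribution; the template is randomly deformed (linear
    intensity / nearest-neighbor label warp), multiplied by a smooth random
    bias field and corrupted by additive Gaussian noise.  The ground-truth
    label map is for validation only; the segmentation path never sees it.
    """
    vol, truth, shift = _make_subject_full(group, cohort, seed)
    return vol, truth


def _make_subject_full(group: str, cohort: CohortSpec, seed: int
                       ) -> tuple[Volume, LabelMap, float]:
    if group not in GROUPS:
        raise ContractError(f"unrecognized group {group!r}")
    spec = cohort.base
    rng = np.random.default_rng(seed)
    shift = _draw_shift(group, cohort, rng)
    extent = float(np.clip(rng.normal(spec.gp_extent_pct, cohort.extent_sd),
                           30.0, 70.0))

    x, y, z = _world_coords(spec)
    geo = _structure_geometry(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    for name, lab in _STRUCTURE_ORDER:
        c, s = geo[name]
        labels[_ellipsoid(x, y, z, c, s)] = lab
    _carve_sulci(labels, x, y, z)
    texture = _texture(spec, x, y, z, labels)
    data = _render(spec, labels, shift, texture, x, extent_pct=extent)
    aff = template_affine(spec)

    if spec.deform_amplitude_mm > 0:
        fld = random_deformation(spec, rng)
        dv = fld.disp_vox()
        data = warp_array(data, dv, order=1)
        labels = warp_array(labels.astype(np.float64), dv, order=0).astype(np.int32)

    if spec.bias_amplitude != 0:
        sp = np.asarray(spec.spacing)
        sigma_vox = spec.bias_fwhm_mm * _FWHM_TO_SIGMA / sp
        b = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma_vox)
        mx = np.abs(b).max()
        if mx > 0:
            b = b / mx
        data = data * (1.0 + spec.bias_amplitude * b)

    if spec.noise_sd > 0:
        data = data + rng.standard_normal(data.shape) * spec.noise_sd * spec.tissue_means[2]

    vol = Volume(data, spec.spacing, aff, {"group": group, "seed": seed})
    truth = LabelMap(labels, spec.spacing, aff, FINE, dict(DEFAULT_FINE_LABELS))
    return vol, truth, shift


@dataclass
class Cohort:
    """Generated subjects per group plus the generation manifest."""

    subjects: dict[str, list[tuple[Volume, LabelMap]]]
    manifest: pd.DataFrame


def make_cohort(cohort: CohortSpec) -> Cohort:
    """Generate all groups with stream-split seeds; fully deterministic."""
    master = np.random.default_rng(cohort.seed)
    subjects: dict[str, list[tuple[Volume, LabelMap]]] = {}
    rows = []
    for group in GROUPS:
        n = cohort.sizes.get(group, 0)
        subjects[group] = []
        for j in range(n):
            sub_seed = int(master.integers(0, 2 ** 31 - 1))
            vol, truth, shift = _make_subject_full(group, cohort, sub_seed)
            subjects[group].append((vol, truth))
            rows.append({"subject_id": f"{group}_{j:03d}", "group": group,
                         "seed": sub_seed, "gp_shift": shift})
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "seed", "gp_shift"])
    return Cohort(subjects, manifest)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
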