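"""Synthetic labeled brain phantoms with controlled group-specific atrophy.

A cohort is generated from a shared geometric template (ellipsoid / shell
primitives carrying ROI labels and intensities) by applying, per subject:

1. a group-specific *atrophy* map — a smooth radial contraction toward each
   atrophied ROI's centre by a linear factor f in (0, 1], blended to identity
   by twice the ROI's radius, so the warped ROI volume shrinks by ~f^3;
2. a random smooth diffeomorphic warp (Gaussian vector noise, smoothed,
   scaled to a maximum displacement, exponentiated by scaling and squaring)
   emulating inter-subject anatomical variability;
3. additive Gaussian intensity noise.

Labels are resampled with the same composite map using nearest-neighbour
interpolation so image and labels stay voxel-consistent.  Everything is
deterministic given the spec seed; per-subject seeds are spawned from it.

The defaults in :func:`default_spec` define the study conditions used by the
end-to-end tests: two groups of 10 subjects on a 32^3 grid with a
hippocampus-analog contraction factor of 0.7 in the disease group.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .registration import _compose_disp, _identity_coords, exp_field, warp
from .volumes import Grid, ImageVolume, LabelVolume, VelocityField, DeformationField

__all__ = [
    "GROUPS",
    "RoiPrimitive",
    "PhantomSpec",
    "SubjectRecord",
    "PhantomError",
    "make_template",
    "sample_subject",
    "make_cohort",
    "write_cohort",
    "default_spec",
]

GROUPS = ("NC", "sMCI", "pMCI", "AD")

# 13-ROI vocabulary shared with the distance module
ROI_VOCAB = (
    "GM",
    "WM",
    "AMYG",
    "HIPPO",
    "CAUD",
    "PUTA",
    "PALLI",
    "THALA",
    "frontal",
    "parietal",
    "occipital",
    "temporal",
    "cingulate",
)


class PhantomError(ValueError):
    pass


@dataclass
class RoiPrimitive:
    """One labeled geometric primitive.

    ``kind`` is "ellipsoid" (filled) or "shell" (between inner_radii and
    radii).  Centre and radii are in mm.  Primitives are assigned in list
    order: a voxel keeps the first label that claims it.
    """

    roi_id: str
    label: int
    kind: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float
    inner_radii: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "shell"):
            raise PhantomError(f"unknown primitive kind {self.kind!r}")
        if self.kind == "shell" and self.inner_radii is None:
            raise PhantomError(f"shell primitive {self.roi_id!r} needs inner_radii")
        if self.roi_id not in ROI_VOCAB:
            raise PhantomError(
                f"roi_id {self.roi_id!r} not in ROI vocabulary {ROI_VOCAB}"
            )

    def membership(self, grid: Grid) -> np.ndarray:
        rho = _elliptic_radius(grid, self.center, self.radii)
        inside = rho <= 1.0
        if self.kind == "shell":
            rho_in = _elliptic_radius(grid, self.center, self.inner_radii)
            inside &= rho_in > 1.0
        return inside


def _elliptic_radius(grid: Grid, center, radii) -> np.ndarray:
    coords = _identity_coords(grid.dims)
    rho2 = np.zeros(grid.dims, dtype=np.float64)
    for i in range(3):
        mm = coords[i] * grid.spacing[i]
        rho2 += ((mm - center[i]) / radii[i]) ** 2
    return np.sqrt(rho2)


@dataclass
class PhantomSpec:
    grid_dims: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_geometry: list[RoiPrimitive] = field(default_factory=list)
    warp_smoothness_sigma: float = 4.0  # mm
    warp_amplitude: float = 1.5  # mm, max displacement of the random warp
    noise_sigma: float = 0.02  # intensity units
    atrophy: dict[str, dict[str, float]] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        seen: set[str] = set()
        for prim in self.roi_geometry:
            if prim.roi_id in seen:
                raise PhantomError(f"duplicate roi_id {prim.roi_id!r} in geometry")
            seen.add(prim.roi_id)
        for group, rois in self.atrophy.items():
            if group not in GROUPS:
                raise PhantomError(f"unknown group {group!r}; valid: {GROUPS}")
            for roi_id, f in rois.items():
                if not (0.0 < f <= 1.0):
                    raise PhantomError(
                        f"atrophy factor for {group}/{roi_id} must be in (0, 1], got {f}"
                    )
        for group in self.n_per_group:
            if group not in GROUPS:
                raise PhantomError(f"unknown group {group!r}; valid: {GROUPS}")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_dims, self.spacing)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["roi_geometry"] = [RoiPrimitive(**p) for p in d.get("roi_geometry", [])]
        d["grid_dims"] = tuple(d["grid_dims"])
        d["spacing"] = tuple(d["spacing"])
        return cls(**d)


@dataclass
class SubjectRecord:
    subject_id: str
    image: ImageVolume
    labels: LabelVolume
    group: str
    subject_seed: int | None = None


def make_template(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Rasterise the primitive list into intensity and label volumes.

    The template depends only on the geometry, never on the seed.  Raises if
    a primitive pokes outside the grid (2-voxel margin) or claims no voxels.
    """
    grid = spec.grid
    if any(d < 16 for d in grid.dims):
        raise PhantomError(f"grid dims must be >= 16 per axis, got {grid.dims}")
    img = np.zeros(grid.dims, dtype=np.float64)
    lab = np.zeros(grid.dims, dtype=np.int32)
    extent = [(d - 1) * s for d, s in zip(grid.dims, grid.spacing)]
    for prim in spec.roi_geometry:
        for i in range(3):
            lo = prim.center[i] - prim.radii[i]
            hi = prim.center[i] + prim.radii[i]
            margin = 2 * grid.spacing[i]
            if lo < margin or hi > extent[i] - margin:
                raise PhantomError(
                    f"primitive {prim.roi_id!r} exceeds grid along axis {i} "
                    f"(span [{lo:.1f}, {hi:.1f}] mm vs extent {extent[i]:.1f} mm)"
                )
        inside = prim.membership(grid) & (lab == 0)
        if not inside.any():
            raise PhantomError(f"primitive {prim.roi_id!r} covers no voxels")
        lab[inside] = prim.label
        img[inside] = prim.intensity
    return ImageVolume(img, grid), LabelVolume(lab, grid)


def _atrophy_displacement(spec: PhantomSpec, group: str) -> np.ndarray:
    """Pull-back displacement realising radial contraction of atrophied ROIs.

    Inside the ROI the map is an exact scaling about the ROI centre by 1/f
    (pull-back), so the warped ROI occupies ~f^3 of its template volume; the
    field ramps smoothly (cosine) to identity by twice the elliptic radius.
    """
    grid = spec.grid
    disp = np.zeros(grid.dims + (3,), dtype=np.float64)
    group_map = spec.atrophy.get(group, {})
    prim_by_id = {p.roi_id: p for p in spec.roi_geometry}
    coords = _identity_coords(grid.dims)
    for roi_id, f in group_map.items():
        if f == 1.0:
            continue
        if roi_id not in prim_by_id:
            raise PhantomError(f"atrophied roi {roi_id!r} has no geometric primitive")
        prim = prim_by_id[roi_id]
        rho = _elliptic_radius(grid, prim.center, prim.radii)
        ramp = np.where(
            rho <= 1.0,
            1.0,
            np.where(rho >= 2.0, 0.0, 0.5 * (1.0 + np.cos(np.pi * (rho - 1.0)))),
        )
        a = 1.0 / f - 1.0
        for i in range(3):
            mm = coords[i] * grid.spacing[i]
            disp[..., i] += a * (mm - prim.center[i]) * ramp
    return disp


def _random_warp(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random smooth diffeomorphic displacement (mm)."""
    grid = spec.grid
    if spec.warp_amplitude <= 0:
        return np.zeros(grid.dims + (3,), dtype=np.float64)
    raw = rng.standard_normal(grid.dims + (3,))
    sig = [spec.warp_smoothness_sigma / s for s in grid.spacing]
    for i in range(3):
        raw[..., i] = ndimage.gaussian_filter(raw[..., i], sig, mode="nearest")
    mag = np.sqrt((raw**2).sum(axis=-1)).max()
    if mag == 0:
        return np.zeros(grid.dims + (3,), dtype=np.float64)
    vel = raw * (spec.warp_amplitude / mag)
    return exp_field(VelocityField(vel, grid)).data


def _jacobian_det(disp: np.ndarray, grid: Grid) -> np.ndarray:
    """Jacobian determinant of the map x -> x + d(x)."""
    J = np.zeros(grid.dims + (3, 3), dtype=np.float64)
    for i in range(3):
        grads = np.gradient(disp[..., i], *grid.spacing)
        for j in range(3):
            J[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
    return np.linalg.det(J)


def sample_subject(
    template_image: ImageVolume,
    template_labels: LabelVolume,
    group: str,
    spec: PhantomSpec,
    subject_seed: int,
) -> SubjectRecord:
    """Draw one subject: atrophy, then random warp, then intensity noise."""
    if group not in GROUPS:
        raise PhantomError(f"unknown group {group!r}; valid: {GROUPS}")
    grid = spec.grid
    rng = np.random.default_rng(subject_seed)
    d_atrophy = _atrophy_displacement(spec, group)
    d_warp = _random_warp(spec, rng)
    # subject(x) = template(A(W(x))): warp is applied after atrophy, so its
    # pull-back displacement composes inside the atrophy map.
    d_total = _compose_disp(d_atrophy, d_warp, grid)
    jac = _jacobian_det(d_total, grid)
    if jac.min() <= 0:
        raise PhantomError(
            "composite map is not diffeomorphic (negative Jacobian determinant); "
            "reduce warp_amplitude or raise warp_smoothness_sigma/atrophy factor"
        )
    phi = DeformationField(d_total, grid)
    image = warp(template_image, phi, "linear")
    labels = warp(template_labels, phi, "nearest")
    if spec.noise_sigma > 0:
        noisy = image.data + rng.normal(0.0, spec.noise_sigma, grid.dims)
        image = ImageVolume(noisy, grid)
    return SubjectRecord(
        subject_id=f"{group}_{subject_seed}", image=image, labels=labels,
        group=group, subject_seed=subject_seed,
    )


def _subject_seeds(spec: PhantomSpec, n_total: int) -> list[int]:
    ss = np.random.SeedSequence(spec.seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_total)]


def make_cohort(spec: PhantomSpec) -> list[SubjectRecord]:
    """Generate the full cohort deterministically from spec.seed."""
    for g, n in spec.n_per_group.items():
        if n < 1:
            raise PhantomError(f"n_per_group[{g!r}] must be >= 1, got {n}")
    template_image, template_labels = make_template(spec)
    n_total = sum(spec.n_per_group.values())
    seeds = _subject_seeds(spec, n_total)
    cohort: list[SubjectRecord] = []
    idx = 0
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        for k in range(n):
            rec = sample_subject(
                template_image, template_labels, group, spec, seeds[idx]
            )
            rec.subject_id = f"{group}{k:03d}"
            cohort.append(rec)
            idx += 1
    return cohort


def write_cohort(cohort: list[SubjectRecord], spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write NIfTI volumes, the manifest TSV and the spec JSON; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        img_path = out / f"{rec.subject_id}_img.nii.gz"
        lab_path = out / f"{rec.subject_id}_lab.nii.gz"
        rec.image.save(img_path)
        rec.labels.save(lab_path)
        rows.append((rec.subject_id, img_path.name, lab_path.name, rec.group))
    manifest = out / "cohort.tsv"
    with open(manifest, "w") as fh:
        fh.write("subject_id\timage\tlabels\tgroup\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    (out / "phantom_spec.json").write_text(spec.to_json())
    return manifest


def default_spec(
    n_per_group: dict[str, int] | None = None,
    atrophy: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    grid_dims: tuple[int, int, int] = (32, 32, 32),
) -> PhantomSpec:
    """Standard two-group study phantom.

    A brain-like object: white-matter core ellipsoid wrapped in a gray-matter
    shell, with hippocampus- and caudate-analog blobs inside, on a 32^3
    1 mm grid.  The default contrast atrophies the hippocampus analog by a
    linear factor 0.7 in the AD group (roughly 34% volume loss) against
    untouched normal controls.
    """
    c = tuple((d - 1) / 2.0 for d in grid_dims)  # mm at unit spacing
    # geometry scales with the grid while keeping a >2-voxel outer margin
    r = ((min(grid_dims) - 1) / 2.0 - 2.6) / 13.0
    geometry = [
        RoiPrimitive("HIPPO", 3, "ellipsoid",
                     (c[0] - 5.5 * r, c[1] + 3.5 * r, c[2]),
                     (3.5 * r, 3.0 * r, 3.0 * r), 0.55),
        RoiPrimitive("CAUD", 4, "ellipsoid",
                     (c[0] + 5.5 * r, c[1] - 3.5 * r, c[2]),
                     (3.0 * r, 3.0 * r, 3.5 * r), 0.75),
        RoiPrimitive("GM", 1, "shell", c,
                     (13.0 * r, 12.0 * r, 12.0 * r), 0.6,
                     inner_radii=(10.0 * r, 9.0 * r, 9.0 * r)),
        RoiPrimitive("WM", 2, "ellipsoid", c,
                     (10.0 * r, 9.0 * r, 9.0 * r), 1.0),
    ]
    return PhantomSpec(
        grid_dims=grid_dims,
        roi_geometry=geometry,
        atrophy=atrophy if atrophy is not None else {"AD": {"HIPPO": 0.7}},
        n_per_group=n_per_group if n_per_group is not None else {"NC": 10, "AD": 10},
        seed=seed,
    )
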