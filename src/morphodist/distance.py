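"""ROI-restricted Riemannian shape distances from registration velocity fields.

For a registered pair (I_j fixed, I_k moving) with stationary velocity v, the
pairwise shape distance restricted to one region of interest is

    dist(I_j, I_k) = ( ||v|_ROI_j|| + ||(-v)|_ROI_k|| ) / 2

i.e. the average of the velocity-field norm masked by the ROI in each
subject's own frame.  The second term masks the velocity after pulling it
back into subject k's frame through the inverse deformation (since
||-w|| = ||w||, the sign is immaterial).  One registration per unordered
subject pair serves all ROIs: each distance is a masked read of the same
shared velocity field.

Norm modes: ``l2`` is the unnormalised field norm sqrt(sum ||v(x)||^2) over
masked voxels (ROI-size dependent); ``mean`` is the mean per-voxel magnitude
(ROI-size invariant).
"""
from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .registration import (
    RegistrationParams,
    RegistrationResult,
    _sample_vector,
    _warp_coords,
    register_symmetric,
)
from .volumes import GridMismatchError, LabelVolume, VelocityField

__all__ = [
    "ROI_NAMES",
    "RoiSpec",
    "DistanceMatrix",
    "roi_mask",
    "roi_velocity_norm",
    "pair_distance",
    "distance_matrix",
]

ROI_NAMES = (
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


class EmptyRoiError(ValueError):
    pass


@dataclass(frozen=True)
class RoiSpec:
    """A named region of interest as a set of label-volume integer ids."""

    name: str
    label_ids: frozenset[int]
    norm_mode: str = "l2"

    def __init__(self, name: str, label_ids, norm_mode: str = "l2") -> None:
        if name not in ROI_NAMES:
            raise ValueError(f"unknown ROI name {name!r}; valid: {ROI_NAMES}")
        ids = frozenset(int(i) for i in label_ids)
        if not ids:
            raise ValueError(f"ROI {name!r} has empty label_ids")
        if norm_mode not in ("l2", "mean"):
            raise ValueError(f"unknown norm_mode {norm_mode!r}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "label_ids", ids)
        object.__setattr__(self, "norm_mode", norm_mode)


@dataclass
class DistanceMatrix:
    roi: RoiSpec
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.subject_ids)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} subjects")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")
        if (v < 0).any():
            raise ValueError("distance matrix contains negative entries")
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix is not exactly symmetric")
        if np.diagonal(v).any():
            raise ValueError("distance matrix diagonal must be exactly zero")
        self.values = v

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.subject_ids)
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, roi: RoiSpec | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        roi = roi or RoiSpec(Path(path).stem.replace("dist_", ""), {1})
        return cls(roi, [str(i) for i in df.index], df.to_numpy(dtype=np.float64))


def roi_mask(labels: LabelVolume, roi: RoiSpec, subject_id: str = "?") -> np.ndarray:
    mask = np.isin(labels.data, list(roi.label_ids))
    if not mask.any():
        raise EmptyRoiError(
            f"ROI {roi.name!r} (labels {sorted(roi.label_ids)}) is empty "
            f"for subject {subject_id}"
        )
    return mask


def roi_velocity_norm(v: VelocityField, mask: np.ndarray, norm_mode: str = "l2") -> float:
    """Masked norm of the velocity field (mm; l2 additionally carries a
    voxel^(1/2) factor from the unnormalised sum)."""
    if mask.shape != v.data.shape[:3]:
        raise GridMismatchError("mask and velocity field grids differ")
    if not mask.any():
        raise EmptyRoiError("empty ROI mask")
    mags2 = (v.data[mask] ** 2).sum(axis=-1)
    if norm_mode == "l2":
        return float(np.sqrt(mags2.sum()))
    if norm_mode == "mean":
        return float(np.sqrt(mags2).mean())
    raise ValueError(f"unknown norm_mode {norm_mode!r}")


def pair_distance(
    reg: RegistrationResult,
    labels_j: LabelVolume,
    labels_k: LabelVolume,
    roi: RoiSpec,
    norm_mode: str | None = None,
    mask_in_fixed_frame: bool = False,
) -> float:
    """ROI-restricted distance for one registered pair (j fixed, k moving)."""
    norm_mode = norm_mode or roi.norm_mode
    v = reg.velocity
    mask_j = roi_mask(labels_j, roi, "fixed")
    term_j = roi_velocity_norm(v, mask_j, norm_mode)
    if mask_in_fixed_frame:
        # warp mask_k into the fixed frame through the forward map
        coords = _warp_coords(reg.forward.data, v.grid)
        from scipy.ndimage import map_coordinates

        lab_k_in_j = map_coordinates(
            labels_k.data.astype(np.float64), coords, order=0, mode="nearest"
        ).astype(np.int32)
        mask_k = np.isin(lab_k_in_j, list(roi.label_ids))
        if not mask_k.any():
            raise EmptyRoiError(f"ROI {roi.name!r} empty after warping into fixed frame")
        term_k = roi_velocity_norm(v, mask_k, norm_mode)
    else:
        # pull -v back into subject k's frame and mask with k's own labels
        coords = _warp_coords(reg.inverse.data, v.grid)
        v_in_k = VelocityField(_sample_vector(v.data, coords), v.grid)
        mask_k = roi_mask(labels_k, roi, "moving")
        term_k = roi_velocity_norm(v_in_k, mask_k, norm_mode)
    return 0.5 * (term_j + term_k)


# ---------------------------------------------------------------------------
# cohort-level matrix with on-disk caching


def _pair_key(id_a: str, id_b: str, img_a, img_b, params: RegistrationParams) -> str:
    h = hashlib.sha1()
    h.update(id_a.encode())
    h.update(id_b.encode())
    h.update(np.ascontiguousarray(img_a.data).tobytes())
    h.update(np.ascontiguousarray(img_b.data).tobytes())
    h.update(json.dumps(params.to_dict(), sort_keys=True).encode())
    return h.hexdigest()[:16]


def _atomic_save(path: Path, **arrays) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".npz")
    os.close(fd)
    try:
        with open(tmp, "wb") as fh:
            np.savez_compressed(fh, **arrays)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)


def _register_pair(rec_j, rec_k, params, cache_dir, audit):
    """Register one pair (lower index fixed), with npz caching."""
    if cache_dir is not None:
        key = _pair_key(rec_j.subject_id, rec_k.subject_id, rec_j.image, rec_k.image, params)
        cache_path = Path(cache_dir) / f"{rec_j.subject_id}__{rec_k.subject_id}__{key}.npz"
        if cache_path.exists():
            with np.load(cache_path) as z:
                vel = VelocityField(z["velocity"], rec_j.image.grid)
                from .registration import exp_field

                reg = RegistrationResult(
                    vel, exp_field(vel), exp_field(vel.negate()),
                    list(z["energy_trace"]), bool(z["converged"]),
                )
            audit.append(("cached", rec_j.subject_id, rec_k.subject_id))
            return reg
    reg = register_symmetric(rec_j.image, rec_k.image, params)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        _atomic_save(
            cache_path,
            velocity=reg.velocity.data,
            energy_trace=np.asarray(reg.energy_trace),
            converged=np.asarray(reg.converged),
        )
        meta = cache_path.with_suffix(".json")
        meta.write_text(json.dumps({
            "fixed": rec_j.subject_id, "moving": rec_k.subject_id,
            "params": params.to_dict(),
        }, indent=2))
    audit.append(("computed", rec_j.subject_id, rec_k.subject_id))
    return reg


def distance_matrix(
    cohort,
    rois: list[RoiSpec],
    params: RegistrationParams | None = None,
    cache_dir: str | Path | None = None,
    norm_mode: str | None = None,
    n_jobs: int = 1,
    mask_in_fixed_frame: bool = False,
    audit: list | None = None,
) -> list[DistanceMatrix]:
    """All-pairs ROI distance matrices from n(n-1)/2 registrations.

    The subject with the lower cohort index is the fixed image of each pair;
    inverse consistency of the registration makes the orientation immaterial
    up to tolerance.  ``audit`` (optional list) collects ("computed"|"cached",
    fixed_id, moving_id) tuples for cache verification.
    """
    params = params or RegistrationParams()
    audit = audit if audit is not None else []
    n = len(cohort)
    ids = [rec.subject_id for rec in cohort]
    pairs = [(j, k) for j in range(n) for k in range(j + 1, n)]

    def one_pair(j: int, k: int):
        reg = _register_pair(cohort[j], cohort[k], params, cache_dir, audit)
        d = {
            roi.name: pair_distance(
                reg, cohort[j].labels, cohort[k].labels, roi,
                norm_mode=norm_mode, mask_in_fixed_frame=mask_in_fixed_frame,
            )
            for roi in rois
        }
        return j, k, d

    if n_jobs == 1:
        results = [one_pair(j, k) for j, k in pairs]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(one_pair)(j, k) for j, k in pairs)

    out = []
    for roi in rois:
        values = np.zeros((n, n), dtype=np.float64)
        for j, k, d in results:
            values[j, k] = values[k, j] = d[roi.name]
        out.append(DistanceMatrix(roi, ids, values))
    return out
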