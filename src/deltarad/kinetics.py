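"""Voxel-wise kinetic maps from three-point DCE-MRI dynamics.

A DCE acquisition with a pre-contrast volume ``I0`` and two post-contrast
volumes ``I1`` (early, ~2.5 min) and ``I2`` (late, ~7.5 min) supports four
voxel-wise kinetic summaries inside the tumor mask:

* **PE** — peak enhancement, ``max_t (I_t - I0) / I0`` over the post-contrast
  times, with ``tPE`` the earliest time achieving the maximum;
* **SER** — signal enhancement ratio, ``(I1 - I0) / (I2 - I0)``, the ratio of
  early to late enhancement (values > 1 indicate wash-out kinetics);
* **WIS** — wash-in slope, ``PE / (tPE - t0)`` (per minute), zero when
  ``tPE == t0``;
* **WOS** — wash-out slope, ``(I2 - I1) / (t2 - tPE)`` (intensity units per
  minute), zero when ``t2 == tPE``.

Degenerate voxels (non-positive pre-contrast signal, or late enhancement
numerically equal to baseline for SER) are handled by the documented
policies on :func:`compute_kinetic_maps`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class DceSeries:
    """One subject/time-point dynamic stack on a single voxel grid.

    Parameters
    ----------
    volumes : ndarray, shape (3, nx, ny, nz)
        Signal intensity for pre-contrast, first and second post-contrast
        acquisitions (I0, I1, I2), arbitrary units.
    times : tuple of float
        Acquisition times in minutes, strictly increasing, ``times[0]`` is
        the pre-contrast time (conventionally 0).
    spacing : tuple of float
        Voxel spacing in mm per axis.
    mask : ndarray of bool, same grid
        Binary tumor mask with at least one voxel.
    subject_id, timepoint : str
        Provenance labels (e.g. ``"subj007"``, ``"T1"``).
    """

    volumes: np.ndarray
    times: tuple
    spacing: tuple
    mask: np.ndarray
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.volumes.ndim != 4 or self.volumes.shape[0] != 3:
            raise ValueError("volumes must have shape (3, nx, ny, nz)")
        if self.volumes.shape[1:] != self.mask.shape:
            raise ValueError("mask shape must match volume grid")
        t0, t1, t2 = self.times
        if not (t0 < t1 < t2):
            raise ValueError("acquisition times must be strictly increasing")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if not np.isfinite(self.volumes).all():
            raise ValueError("intensities must be finite")


@dataclass
class KineticMapSet:
    """Voxel-wise kinetic maps defined on the tumor mask.

    ``pe``, ``ser``, ``wis``, ``wos`` are full-grid arrays that are only
    meaningful where ``mask`` is True; ``tpe`` holds the per-voxel peak time
    in minutes.  ``valid`` marks mask voxels with a usable pre-contrast
    signal (``I0 > 0``); ``n_invalid`` counts the flagged ones.
    """

    pe: np.ndarray
    ser: np.ndarray
    wis: np.ndarray
    wos: np.ndarray
    tpe: np.ndarray
    mask: np.ndarray
    valid: np.ndarray
    spacing: tuple
    n_invalid: int = 0
    provenance: str = ""
    maps_order: tuple = field(default=("PE", "SER", "WIS", "WOS"))

    def map_dict(self):
        return {"PE": self.pe, "SER": self.ser, "WIS": self.wis, "WOS": self.wos}


def compute_kinetic_maps(series: DceSeries, ser_eps_rel: float = 1e-9) -> KineticMapSet:
    """Compute PE, SER, WIS, WOS (and tPE) maps within the mask.

    Policies for degenerate voxels:

    * ``I0 <= 0``: the voxel is flagged invalid (excluded from ``valid``)
      and its map values set to 0; the count is recorded in ``n_invalid``.
    * ``|I2 - I0| < ser_eps_rel * I0``: SER is set to 0, marking "no net
      late enhancement" instead of propagating an infinity.
    * PE maximization runs over the post-contrast times {t1, t2} only
      ((I_t - I0)/I0 is identically 0 at t0); the earliest maximizing time
      is taken as tPE.
    """
    I0, I1, I2 = series.volumes
    t0, t1, t2 = (float(t) for t in series.times)
    mask = series.mask

    valid = mask & (I0 > 0)
    n_invalid = int(mask.sum() - valid.sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(valid, (I1 - I0) / np.where(I0 != 0, I0, 1.0), 0.0)
        e2 = np.where(valid, (I2 - I0) / np.where(I0 != 0, I0, 1.0), 0.0)

    # earliest maximizing post-contrast time: t1 wins ties
    take_t2 = e2 > e1
    pe = np.where(take_t2, e2, e1)
    tpe = np.where(take_t2, t2, t1)

    wis = np.where(tpe != t0, pe / np.where(tpe != t0, tpe - t0, 1.0), 0.0)
    wos = np.where(
        tpe != t2, (I2 - I1) / np.where(tpe != t2, t2 - tpe, 1.0), 0.0
    )

    denom = I2 - I0
    degenerate = np.abs(denom) < ser_eps_rel * np.abs(I0)
    ser = np.where(
        valid & ~degenerate, (I1 - I0) / np.where(degenerate, 1.0, denom), 0.0
    )

    zero = ~valid
    for arr in (pe, ser, wis, wos):
        arr[zero] = 0.0
    tpe = np.where(valid, tpe, t1)

    return KineticMapSet(
        pe=pe, ser=ser, wis=wis, wos=wos, tpe=tpe,
        mask=mask, valid=valid, spacing=tuple(series.spacing),
        n_invalid=n_invalid,
        provenance=f"{series.subject_id}:{series.timepoint}",
    )


def compute_kinetic_voxel(I0, I1, I2, times, ser_eps_rel=1e-9):
    """Scalar per-voxel reference for the kinetic maps (oracle route).

    Returns ``(pe, ser, wis, wos, tpe)`` for a single voxel; kept as an
    independent, loop-free-of-vectorization implementation against which the
    array routine is verified.
    """
    t0, t1, t2 = times
    if I0 <= 0:
        return 0.0, 0.0, 0.0, 0.0, t1
    e1 = (I1 - I0) / I0
    e2 = (I2 - I0) / I0
    if e2 > e1:
        pe, tpe = e2, t2
    else:
        pe, tpe = e1, t1
    wis = pe / (tpe - t0) if tpe != t0 else 0.0
    wos = (I2 - I1) / (t2 - tpe) if t2 != tpe else 0.0
    if abs(I2 - I0) < ser_eps_rel * abs(I0):
        ser = 0.0
    else:
        ser = (I1 - I0) / (I2 - I0)
    return pe, ser, wis, wos, tpe


def resample_inplane(volume: np.ndarray, mask: np.ndarray,
                     target_shape=(256, 256), spacing=None):
    """Resample each axial slice to ``target_shape`` in-plane.

    Intensity volumes are interpolated bilinearly; the mask is resampled
    nearest-neighbor so it stays binary.  Output coordinate ``i`` maps to
    input coordinate ``i * in_size / out_size`` (origin-aligned), so a x2
    upsampling places new samples at the midpoints between original voxels.
    Slice count is unchanged.  If ``spacing`` is given the in-plane spacing
    is rescaled accordingly and the new spacing returned as third element.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    tx, ty = target_shape
    if tx <= 0 or ty <= 0:
        raise ValueError("target shape must be positive")
    nx, ny, nz = volume.shape
    xi = np.arange(tx) * (nx / tx)
    yi = np.arange(ty) * (ny / ty)
    xx, yy = np.meshgrid(xi, yi, indexing="ij")
    out_v = np.empty((tx, ty, nz))
    out_m = np.empty((tx, ty, nz), dtype=mask.dtype)
    coords = np.stack([xx, yy])
    for z in range(nz):
        out_v[:, :, z] = ndimage.map_coordinates(
            volume[:, :, z], coords, order=1, mode="nearest")
        out_m[:, :, z] = ndimage.map_coordinates(
            mask[:, :, z], coords, order=0, mode="nearest")
    if spacing is not None:
        sx, sy, sz = spacing
        new_spacing = (sx * nx / tx, sy * ny / ty, sz)
        return out_v, out_m.astype(mask.dtype), new_spacing
    return out_v, out_m.astype(mask.dtype)


def compute_ftv(kinetics: KineticMapSet, pe_threshold: float = 0.7,
                unit: str = "mm3") -> float:
    """Enhancement-threshold functional tumor volume.

    FTV is the number of mask voxels whose peak enhancement reaches
    ``pe_threshold``, times the voxel volume.  This is a simplified
    covariate surrogate for the clinical FTV protocol (no bounding boxes,
    SER criteria, or manual refinement).

    Parameters
    ----------
    pe_threshold : float
        Minimum PE (unitless relative enhancement), must be >= 0.
    unit : {"mm3", "cm3"}
    """
    if pe_threshold < 0:
        raise ValueError("pe_threshold must be >= 0")
    voxel_mm3 = float(np.prod(kinetics.spacing))
    count = int(np.count_nonzero(kinetics.mask & kinetics.valid
                                 & (kinetics.pe >= pe_threshold)))
    ftv = count * voxel_mm3
    if unit == "cm3":
        return ftv / 1000.0
    if unit != "mm3":
        raise ValueError("unit must be 'mm3' or 'cm3'")
    return ftv
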