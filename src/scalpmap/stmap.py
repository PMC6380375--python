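"""Scalp x time mass-univariate mapping with permutation FWE inference.

Each subject/condition ERP is interpolated onto a 32 x 32 pixel scalp grid
per 5 ms time bin and stacked into a 32 x 32 x 101 spatiotemporal volume.
Subject-level contrast volumes go into a group one-sample t-map; family-wise
error over the whole volume is controlled by sign-flip permutation of the
subject contrasts, using the max-|t| null for peak-level p-values and the
max cluster-mass null (at a cluster-forming threshold) for cluster-level
p-values.  A small-volume correction restricts the same machinery to a mask
derived from an orthogonal contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError
from scipy import stats

from .eegsim import Montage
from .erpstats import Erp

__all__ = [
    "ScalpGrid",
    "StVolume",
    "ContrastSpec",
    "StatMap",
    "ClusterTable",
    "PermScheme",
    "project_montage",
    "interpolate_scalp_frame",
    "build_volume",
    "smooth_volume",
    "subject_contrast",
    "group_t_map",
    "permutation_fwe",
    "small_volume_correct",
    "write_volume_nifti",
    "read_volume_nifti",
]

GRID_SIZE = 32
N_TIME_BINS = 101
#: Physical scale: the projected scalp disc (28 pixels across) is taken to
#: span 180 mm, giving ~6.43 mm per pixel.
SCALP_DIAMETER_MM = 180.0
DISC_DIAMETER_PX = 28.0
MM_PER_PIXEL = SCALP_DIAMETER_MM / DISC_DIAMETER_PX
TIME_BIN_MS = 5.0


@dataclass
class ScalpGrid:
    """32 x 32 lattice with projected electrode coordinates and scalp mask."""

    size: int
    pixel_mm: float
    electrode_xy: np.ndarray  # (n_channels, 2) pixel coordinates
    mask: np.ndarray  # (size, size) bool, convex hull of electrodes
    channels: list[str]
    triangulation: Delaunay


@dataclass
class StVolume:
    """One 32 x 32 x 101 spatiotemporal image (space, space, time)."""

    data: np.ndarray  # (size, size, n_time)
    time: np.ndarray  # ms per bin
    mask: np.ndarray  # (size, size) bool
    subject: str = ""
    condition: str = ""
    smoothed: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[:2] != self.mask.shape:
            raise ValueError("mask/data shape mismatch")
        if self.data.shape[2] != len(self.time):
            raise ValueError("time axis length mismatch")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside the scalp mask")


@dataclass(frozen=True)
class ContrastSpec:
    """Named per-condition weights; difference contrasts sum to zero."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError("contrast needs at least one nonzero weight")

    def vector(self, conditions: list[str]) -> np.ndarray:
        return np.array([self.weights.get(c, 0.0) for c in conditions])


@dataclass
class StatMap:
    data: np.ndarray  # (size, size, n_time) statistic values
    time: np.ndarray
    mask: np.ndarray
    stat: str  # e.g. "t"
    df: int
    degenerate: np.ndarray | None = None  # voxels with zero variance


@dataclass
class PermScheme:
    """Sign-flip permutation settings for FWE inference."""

    n_permutations: int = 1000
    seed: int = 0
    forming_p: float = 0.001  # uncorrected two-sided cluster-forming threshold
    tail: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 < self.forming_p < 1:
            raise ValueError("forming threshold must be an uncorrected p in (0, 1)")
        if self.n_permutations < 100:
            warnings.warn(
                f"{self.n_permutations} permutations give p-value granularity "
                f"1/{self.n_permutations + 1}; use >= 100 for reported p-values"
            )


ClusterTable = pd.DataFrame  # columns: cluster, peak_t, peak_x, peak_y, peak_time_ms, extent, p_fwe_peak, p_fwe_cluster


# ---------------------------------------------------------------------------
# Projection and interpolation

def project_montage(montage: Montage, grid_size: int = GRID_SIZE) -> ScalpGrid:
    """Azimuthal-equidistant projection of the electrode sphere to the grid.

    The vertex (+z pole) maps to the grid centre; the polar angle becomes
    the planar radius, scaled so the outermost electrode ring fits a
    28-pixel-diameter disc.  The scalp mask is the convex hull of the
    projected electrodes.
    """
    pos = montage.positions
    theta = np.arccos(np.clip(pos[:, 2], -1, 1))  # polar angle from vertex
    rho = np.hypot(pos[:, 0], pos[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(rho > 1e-12, pos[:, 0] / rho, 0.0)
        uy = np.where(rho > 1e-12, pos[:, 1] / rho, 0.0)
    r = theta / theta.max() * (DISC_DIAMETER_PX / 2.0)
    centre = (grid_size - 1) / 2.0
    xy = np.column_stack([centre + r * ux, centre + r * uy])

    try:
        tri = Delaunay(xy)
    except QhullError as err:
        raise ValueError("degenerate montage: projected electrodes are collinear") from err

    gx, gy = np.meshgrid(np.arange(grid_size), np.arange(grid_size), indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    inside_hull = tri.find_simplex(pts) >= 0
    # Boundary electrodes can round to a pixel centre just outside the hull;
    # keep any pixel within one pixel of an electrode in the mask too.
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    mask = (inside_hull | (d2 <= 0.75**2)).reshape(grid_size, grid_size)
    return ScalpGrid(
        size=grid_size,
        pixel_mm=MM_PER_PIXEL,
        electrode_xy=xy,
        mask=mask,
        channels=list(montage.labels),
        triangulation=tri,
    )


def interpolate_scalp_frame(channel_values: np.ndarray, grid: ScalpGrid) -> np.ndarray:
    """Linear barycentric interpolation of one value per electrode onto the
    grid; pixels outside the electrode hull are zero (masked)."""
    vals = np.asarray(channel_values, dtype=float)
    if vals.shape[0] != len(grid.channels):
        raise ValueError(
            f"expected {len(grid.channels)} channel values, got {vals.shape[0]}"
        )
    if not np.all(np.isfinite(vals)):
        raise ValueError("missing (non-finite) channel value")
    frames = _interpolate_frames(vals[:, None], grid)
    return frames[:, :, 0]


def _interpolate_frames(values: np.ndarray, grid: ScalpGrid) -> np.ndarray:
    """(n_channels, n_frames) -> (size, size, n_frames), zero outside mask.

    Linear barycentric inside the electrode hull; the thin rind of masked
    pixels outside the hull takes the nearest electrode's value.
    """
    from scipy.interpolate import NearestNDInterpolator

    interp = LinearNDInterpolator(grid.triangulation, values, fill_value=np.nan)
    gx, gy = np.meshgrid(np.arange(grid.size), np.arange(grid.size), indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    out = interp(pts).reshape(grid.size, grid.size, values.shape[1])
    rind = grid.mask & np.isnan(out[:, :, 0])
    if rind.any():
        nearest = NearestNDInterpolator(grid.electrode_xy, values)
        out[rind] = nearest(np.column_stack(np.nonzero(rind)).astype(float))
    out[~grid.mask] = 0.0
    return np.nan_to_num(out, nan=0.0)


def build_volume(erp: Erp, grid: ScalpGrid, expected_rate: float = 200.0) -> StVolume:
    """Stack one interpolated frame per time bin into a spatiotemporal volume."""
    if not np.isclose(erp.fs, expected_rate):
        raise ValueError(f"expected {expected_rate:g} Hz ERPs, got {erp.fs:g} Hz")
    if erp.channels != grid.channels:
        raise ValueError("ERP channel order does not match the grid's montage")
    data = _interpolate_frames(erp.data, grid)
    return StVolume(
        data=data, time=erp.time.copy(), mask=grid.mask, condition=erp.condition
    )


def smooth_volume(
    vol: StVolume, fwhm: tuple[float, float, float] = (8.0, 8.0, 20.0)
) -> StVolume:
    """Separable Gaussian smoothing with FWHM in (mm, mm, ms).

    Smoothing is renormalised by the smoothed mask so constants inside the
    mask are preserved at its edges.
    """
    if any(f <= 0 for f in fwhm):
        raise ValueError("FWHM must be positive")
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    sigmas = (
        fwhm[0] / MM_PER_PIXEL / factor,
        fwhm[1] / MM_PER_PIXEL / factor,
        fwhm[2] / TIME_BIN_MS / factor,
    )
    masked = vol.data * vol.mask[:, :, None]
    num = ndimage.gaussian_filter(masked, sigmas, mode="constant")
    den = ndimage.gaussian_filter(
        np.broadcast_to(vol.mask[:, :, None].astype(float), vol.data.shape).copy(),
        sigmas,
        mode="constant",
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / den, 0.0)
    out[~vol.mask] = 0.0
    return StVolume(
        data=out,
        time=vol.time,
        mask=vol.mask,
        subject=vol.subject,
        condition=vol.condition,
        smoothed=True,
    )


# ---------------------------------------------------------------------------
# Contrasts and group inference

def subject_contrast(
    condition_volumes: dict[str, StVolume], contrast: ContrastSpec
) -> StVolume:
    """Voxelwise weighted sum of one subject's condition volumes."""
    missing = [c for c, w in contrast.weights.items() if w != 0 and c not in condition_volumes]
    if missing:
        raise ValueError(f"missing condition volumes: {missing}")
    ref = next(iter(condition_volumes.values()))
    data = np.zeros_like(ref.data)
    for cond, w in contrast.weights.items():
        if w != 0:
            data += w * condition_volumes[cond].data
    return StVolume(
        data=data,
        time=ref.time,
        mask=ref.mask,
        subject=ref.subject,
        condition=contrast.name,
        smoothed=ref.smoothed,
    )


def _stack(contrast_volumes: list[StVolume]) -> tuple[np.ndarray, StVolume]:
    shapes = {v.data.shape for v in contrast_volumes}
    if len(shapes) != 1:
        raise ValueError(f"subject volumes disagree in shape: {shapes}")
    return np.stack([v.data for v in contrast_volumes]), contrast_volumes[0]


def _t_from_stack(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t over axis 0; zero-variance voxels become +/-inf sentinels."""
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
        t[degenerate] = np.sign(mean[degenerate]) * np.inf
    t[degenerate & (mean == 0)] = 0.0
    return t, degenerate


def group_t_map(contrast_volumes: list[StVolume]) -> StatMap:
    """Voxelwise one-sample t-map across subjects, df = n - 1."""
    if len(contrast_volumes) < 2:
        raise ValueError("need >= 2 subjects")
    stack, ref = _stack(contrast_volumes)
    t, degenerate = _t_from_stack(stack)
    n_bad = int((degenerate & ref.mask[:, :, None]).sum())
    if n_bad:
        warnings.warn(f"{n_bad} zero-variance voxels inside the mask flagged")
    return StatMap(
        data=t,
        time=ref.time,
        mask=ref.mask,
        stat="t",
        df=stack.shape[0] - 1,
        degenerate=degenerate,
    )


#: 6-connectivity in (x, y, time): faces only.
_CONN6 = ndimage.generate_binary_structure(3, 1)


def _cluster_masses(supra: np.ndarray, absT: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, n = ndimage.label(supra, structure=_CONN6)
    if n == 0:
        return labels, np.array([])
    masses = ndimage.sum_labels(absT, labels, index=np.arange(1, n + 1))
    return labels, masses


def _perm_signs(n_subjects: int, scheme: PermScheme, rng: np.random.Generator) -> np.ndarray:
    """Sign-flip matrix; the identity flip is row 0, followed by
    ``n_permutations`` random flips (so the smallest attainable p-value is
    1 / (n_permutations + 1))."""
    n_unique = 2 ** n_subjects
    n_perm = scheme.n_permutations
    if n_perm + 1 >= n_unique:
        warnings.warn(
            f"{n_perm} permutations exceed the {n_unique} unique sign flips "
            f"for n={n_subjects}; enumerating all of them"
        )
        bits = np.arange(n_unique)[:, None] >> np.arange(n_subjects)[None, :]
        return np.where(bits & 1, -1.0, 1.0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm + 1, n_subjects))
    signs[0] = 1.0
    return signs


def permutation_fwe(
    contrast_volumes: list[StVolume],
    scheme: PermScheme,
    mask: np.ndarray | None = None,
) -> tuple[StatMap, ClusterTable]:
    """Sign-flip max-statistic FWE inference.

    Returns the observed t-map and a cluster table with peak-level FWE
    p-values (max-|t| null) and cluster-level FWE p-values (max cluster-mass
    null at the forming threshold).  The identity permutation is included in
    the null, so the smallest achievable p is 1/n_permutations.
    """
    n = len(contrast_volumes)
    if n < 6:
        raise ValueError(f"need >= 6 subjects for a meaningful sign-flip null, got {n}")
    stack, ref = _stack(contrast_volumes)
    if mask is None:
        mask = ref.mask[:, :, None] & np.ones(stack.shape[3], dtype=bool)[None, None, :]
    mask = np.asarray(mask, dtype=bool)
    if mask.shape == ref.mask.shape:  # 2-D spatial mask: extend over time
        mask = mask[:, :, None] & np.ones(stack.shape[3], dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")

    df = n - 1
    t_obs, degenerate = _t_from_stack(stack)
    tmap = StatMap(data=t_obs, time=ref.time, mask=ref.mask, stat="t", df=df,
                   degenerate=degenerate)
    t_form = stats.t.isf(scheme.forming_p / 2.0, df)

    rng = np.random.default_rng(scheme.seed)
    signs = _perm_signs(n, scheme, rng)
    n_perm = signs.shape[0]

    flat = stack.reshape(n, -1)
    flat_mask = mask.ravel()
    X = flat[:, flat_mask]
    sx2 = (X**2).sum(axis=0)
    max_t = np.empty(n_perm)
    max_mass = np.zeros(n_perm)
    vol_shape = stack.shape[1:]
    for p in range(n_perm):
        m = signs[p] @ X / n
        var = (sx2 - n * m**2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / np.sqrt(var / n)
        t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
        absT = np.abs(t)
        max_t[p] = absT.max()
        supra_flat = np.zeros(flat.shape[1], dtype=bool)
        supra_flat[flat_mask] = absT > t_form
        if supra_flat.any():
            absT_full = np.zeros(flat.shape[1])
            absT_full[flat_mask] = absT
            _, masses = _cluster_masses(
                supra_flat.reshape(vol_shape), absT_full.reshape(vol_shape)
            )
            max_mass[p] = masses.max() if len(masses) else 0.0

    # Observed clusters (identity permutation).
    absT_obs = np.where(mask, np.abs(t_obs), 0.0)
    supra = absT_obs > t_form
    labels, masses = _cluster_masses(supra, absT_obs)
    rows = []
    for k in range(1, labels.max() + 1):
        sel = labels == k
        peak_idx = np.unravel_index(np.argmax(np.where(sel, absT_obs, -np.inf)), absT_obs.shape)
        peak_t = float(t_obs[peak_idx])
        mass = float(masses[k - 1])
        rows.append(
            {
                "cluster": k,
                "peak_t": peak_t,
                "peak_x": int(peak_idx[0]),
                "peak_y": int(peak_idx[1]),
                "peak_time_ms": float(ref.time[peak_idx[2]]),
                "extent": int(sel.sum()),
                "p_fwe_peak": float((max_t >= abs(peak_t) - 1e-12).mean()),
                "p_fwe_cluster": float((max_mass >= mass - 1e-12).mean()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster", "peak_t", "peak_x", "peak_y", "peak_time_ms",
            "extent", "p_fwe_peak", "p_fwe_cluster",
        ],
    )
    if len(table):
        table = table.sort_values("peak_t", key=np.abs, ascending=False).reset_index(drop=True)
    return tmap, table


def orthogonal_contrasts(a: ContrastSpec, b: ContrastSpec, conditions: list[str]) -> bool:
    """True when the two contrast weight vectors are orthogonal."""
    return bool(np.isclose(a.vector(conditions) @ b.vector(conditions), 0.0))


def small_volume_correct(
    contrast_volumes: list[StVolume],
    scheme: PermScheme,
    mask: np.ndarray,
    tested: ContrastSpec | None = None,
    mask_source: ContrastSpec | None = None,
    conditions: list[str] | None = None,
) -> ClusterTable:
    """Permutation FWE restricted to a reduced search volume.

    The mask must come from a contrast orthogonal to the one under test;
    when both specs are supplied the orthogonality is audited and a
    violation refused.
    """
    if tested is not None and mask_source is not None:
        if conditions is None:
            conditions = sorted(set(tested.weights) | set(mask_source.weights))
        if not orthogonal_contrasts(tested, mask_source, conditions):
            raise ValueError(
                f"SVC mask contrast {mask_source.name!r} is not orthogonal to the "
                f"tested contrast {tested.name!r}"
            )
    if not np.asarray(mask).any():
        raise ValueError("empty SVC mask")
    _, table = permutation_fwe(contrast_volumes, scheme, mask=mask)
    return table


# ---------------------------------------------------------------------------
# NIfTI I/O

def write_volume_nifti(vol: StVolume, path) -> None:
    """Volume as NIfTI with (x, y, time) axes; pixel size in mm, time step
    recorded in the zooms (ms) and a JSON sidecar."""
    import json

    import nibabel as nib

    affine = np.diag([MM_PER_PIXEL, MM_PER_PIXEL, 1.0, 1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms((MM_PER_PIXEL, MM_PER_PIXEL, TIME_BIN_MS))
    nib.save(img, str(path))
    sidecar = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "time_ms": list(map(float, vol.time)),
                "subject": vol.subject,
                "condition": vol.condition,
                "smoothed": vol.smoothed,
                "pixel_mm": MM_PER_PIXEL,
            },
            fh,
        )


def read_volume_nifti(path, mask: np.ndarray | None = None) -> StVolume:
    import json
    import os

    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    sidecar = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
        time = np.array(meta["time_ms"])
        subject, condition = meta.get("subject", ""), meta.get("condition", "")
        smoothed = bool(meta.get("smoothed", False))
    else:
        time = np.arange(data.shape[2], dtype=float) * TIME_BIN_MS
        subject = condition = ""
        smoothed = False
    if mask is None:
        mask = np.ones(data.shape[:2], dtype=bool)
    return StVolume(
        data=data, time=time, mask=mask, subject=subject,
        condition=condition, smoothed=smoothed,
    )
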