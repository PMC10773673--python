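"""Binary airway masks and the image-derived fields driving the active surface.

A segmented lumen arrives as a {0,1} voxel volume (NIFTI) with anisotropic
spacing.  The active-surface energy needs a smoothed copy I_sigma = G_sigma * I_seg
and the force field grad(||grad I_sigma||^2), whose maxima sit on the mask
boundary; both live on the voxel lattice and are interpolated trilinearly at
arbitrary world-coordinate points.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "BinaryImage",
    "ScalarField",
    "ForceField",
    "read_mask",
    "write_mask",
    "gaussian_smooth",
    "image_force",
]


def _default_affine(spacing):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class BinaryImage:
    """3D {0,1} voxel volume with world geometry.

    data is indexed (i, j, k); world coordinates in mm follow the affine,
    world = affine @ (i, j, k, 1).
    """

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray = None  # type: ignore[assignment]
    empty: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim} dimensions")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("binary image must contain only {0, 1}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        self.empty = bool(self.data.sum() == 0)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T) + self.affine[:3, 3]

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine[:3, :3])
        return (xyz - self.affine[:3, 3]) @ inv.T


@dataclass
class ScalarField:
    """Real-valued field on the lattice of a parent :class:`BinaryImage`."""

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray

    def interp(self, xyz) -> np.ndarray:
        """Trilinear interpolation at world-coordinate points (mm)."""
        ijk = _world_to_voxel(self.affine, xyz)
        return ndimage.map_coordinates(self.data, ijk.T, order=1, mode="nearest")


@dataclass
class ForceField:
    """Lattice field of 3-vectors (mm^-1 per component), trilinearly interpolated."""

    data: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple
    affine: np.ndarray

    def interp(self, xyz) -> np.ndarray:
        ijk = _world_to_voxel(self.affine, xyz)
        out = np.empty((ijk.shape[0], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(self.data[..., c], ijk.T, order=1, mode="nearest")
        return out


def _world_to_voxel(affine, xyz):
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    inv = np.linalg.inv(affine[:3, :3])
    return (xyz - affine[:3, 3]) @ inv.T


def read_mask(path) -> BinaryImage:
    """Read a binary airway mask from a 3D NIFTI file.

    Values above 0.5 map to 1 so float-saved masks are tolerated.  An all-zero
    volume is accepted but flagged (``empty``) with a warning.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIFTI volume, got shape {data.shape}")
    binary = (data > 0.5).astype(np.uint8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    out = BinaryImage(data=binary, spacing=spacing, affine=np.asarray(img.affine))
    if out.empty:
        warnings.warn(f"mask {path} contains no foreground voxels", stacklevel=2)
    return out


def write_mask(img: BinaryImage, path):
    nib.save(nib.Nifti1Image(img.data.astype(np.uint8), img.affine), str(path))


def gaussian_smooth(img: BinaryImage, sigma: float = 2.0) -> ScalarField:
    """Gaussian smoothing of the binary mask; sigma in voxel units.

    The filter softens the staircase boundary rather than denoising: the result
    is a [0,1] field with a smooth transition band whose 0.5 level set tracks
    the binary boundary.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sm = ndimage.gaussian_filter(img.data.astype(float), sigma=sigma, mode="nearest")
    return ScalarField(data=sm, spacing=img.spacing, affine=img.affine)


def edge_density(fld: ScalarField) -> ScalarField:
    """Image-energy density ||grad I_sigma||^2, normalized to peak at 1.

    Gradients are spacing-aware central differences (one-sided at the volume
    faces).  The density is a ridge along the mask boundary; normalizing by
    its maximum makes the image-energy weight lambda comparable across images
    and voxel spacings.  A constant field yields an all-zero density.
    """
    if not np.all(np.isfinite(fld.data)):
        raise ValueError("field contains non-finite values")
    gx, gy, gz = np.gradient(fld.data, *fld.spacing)
    density = gx * gx + gy * gy + gz * gz
    peak = density.max()
    if peak > 0:
        density = density / peak
    return ScalarField(data=density, spacing=fld.spacing, affine=fld.affine)


def image_force(fld: ScalarField) -> ForceField:
    """Force field grad(||grad I_sigma||^2) driving the surface to the boundary.

    The input is the smoothed image; the (normalized) squared-gradient
    magnitude peaks at the mask boundary, so its spatial gradient points from
    either side toward the boundary ridge.
    """
    density = edge_density(fld)
    fx, fy, fz = np.gradient(density.data, *fld.spacing)
    return ForceField(data=np.stack([fx, fy, fz], axis=-1), spacing=fld.spacing, affine=fld.affine)
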