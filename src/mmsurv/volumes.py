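"""Final imaging preprocessing: resampling, shape standardization, z-score.

A :class:`VolumeStack` is a 4-channel (T1, T1C, T2, FLAIR) 3D array with a
voxel spacing, an affine, and an optional lesion mask on the same grid.
z-scoring happens BEFORE zero-padding so padded background never biases the
per-scan statistics; volumes loaded from disk are reoriented to RAS first so
axis flips are well-defined.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

DEFAULT_SPACING = (1.0, 1.0, 4.0)
DEFAULT_SHAPE = (160, 192, 40)
CHANNELS = ("t1", "t1c", "t2", "flair")


@dataclass
class VolumeStack:
    data: np.ndarray                    # (4, X, Y, Z)
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None      # (X, Y, Z) binary

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != len(CHANNELS):
            raise ValueError(f"expected (4, X, Y, Z) data, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape[1:]:
                raise ValueError("mask shape must match volume grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


def resample(stack: VolumeStack, target_spacing=DEFAULT_SPACING) -> VolumeStack:
    """Trilinear resampling of intensities (nearest-neighbour for the mask)
    onto the target voxel spacing."""
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    factors = tuple(s / t for s, t in zip(stack.spacing, target_spacing))
    if np.allclose(factors, 1.0):
        return replace(stack, spacing=tuple(target_spacing))
    channels = [
        ndimage.zoom(stack.data[c], factors, order=1, mode="nearest")
        for c in range(stack.data.shape[0])
    ]
    mask = None
    if stack.mask is not None:
        mask = ndimage.zoom(stack.mask.astype(np.float32), factors, order=0,
                            mode="nearest").astype(stack.mask.dtype)
    affine = None
    if stack.affine is not None:
        affine = stack.affine.copy()
        scale = np.array([t / s for s, t in zip(stack.spacing, target_spacing)])
        affine[:3, :3] = affine[:3, :3] @ np.diag(scale)
    return VolumeStack(np.stack(channels), tuple(target_spacing), affine, mask)


def _center_slices(size: int, target: int) -> tuple[slice, tuple[int, int]]:
    """Return (crop slice, pad pair) centering ``size`` onto ``target``;
    odd remainders put the extra voxel on the trailing side."""
    if size > target:
        start = (size - target) // 2
        return slice(start, start + target), (0, 0)
    pad_total = target - size
    before = pad_total // 2
    return slice(0, size), (before, pad_total - before)


def standardize_shape(stack: VolumeStack, target_shape=DEFAULT_SHAPE) -> VolumeStack:
    """Center-crop or zero-pad each axis independently to ``target_shape``."""
    slices, pads = [], [(0, 0)]
    for size, tgt in zip(stack.shape, target_shape):
        sl, pad = _center_slices(size, tgt)
        slices.append(sl)
        pads.append(pad)
    data = stack.data[(slice(None), *slices)]
    data = np.pad(data, pads, mode="constant")
    mask = None
    if stack.mask is not None:
        mask = np.pad(stack.mask[tuple(slices)], pads[1:], mode="constant")
    return replace(stack, data=data, mask=mask)


def zscore(stack: VolumeStack) -> VolumeStack:
    """Per-channel, per-scan normalization to zero mean / unit variance over
    all voxels.  Constant channels become all zeros with a warning."""
    out = np.empty_like(stack.data)
    for c in range(stack.data.shape[0]):
        chan = stack.data[c]
        sd = chan.std()
        if sd == 0:
            log.warning("channel %s has zero variance; set to zeros", CHANNELS[c])
            out[c] = 0.0
        else:
            out[c] = (chan - chan.mean()) / sd
    return replace(stack, data=out)


def preprocess(stack: VolumeStack, target_spacing=DEFAULT_SPACING,
               target_shape=DEFAULT_SHAPE) -> VolumeStack:
    """resample -> z-score -> standardize shape (z before padding)."""
    return standardize_shape(zscore(resample(stack, target_spacing)), target_shape)


# ---------------------------------------------------------------------------
# NIfTI IO
# ---------------------------------------------------------------------------

def load_stack(paths, mask_path=None) -> VolumeStack:
    """Load a 4-channel stack from one 4D NIfTI or four 3D NIfTIs,
    reoriented to RAS."""
    import nibabel as nib

    def canonical(p):
        return nib.as_closest_canonical(nib.load(str(p)))

    if isinstance(paths, (str, bytes)) or not isinstance(paths, (list, tuple)):
        img = canonical(paths)
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim != 4 or arr.shape[3] != len(CHANNELS):
            raise ValueError(f"expected 4D NIfTI with 4 channels, got {arr.shape}")
        data = np.moveaxis(arr, 3, 0)
        affine = img.affine
    else:
        if len(paths) != len(CHANNELS):
            raise ValueError("expected four channel files (T1, T1C, T2, FLAIR)")
        imgs = [canonical(p) for p in paths]
        shapes = {i.shape for i in imgs}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes disagree: {shapes}")
        data = np.stack([np.asarray(i.dataobj, dtype=np.float64) for i in imgs])
        affine = imgs[0].affine
    spacing = tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    mask = None
    if mask_path is not None:
        mimg = canonical(mask_path)
        mask = (np.asarray(mimg.dataobj) > 0.5).astype(np.uint8)
    return VolumeStack(data, spacing, affine, mask)


def save_stack(stack: VolumeStack, path, mask_path=None) -> None:
    """Write the stack as a single 4D NIfTI (channels last), preserving the
    affine."""
    import nibabel as nib

    arr = np.moveaxis(stack.data, 0, 3).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, stack.affine), str(path))
    if mask_path is not None and stack.mask is not None:
        nib.save(nib.Nifti1Image(stack.mask.astype(np.uint8), stack.affine),
                 str(mask_path))
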