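"""File interfaces: FSL-dialect gradient tables, NIfTI maps, mask arrays."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import AcquisitionProtocol, SamplingMask, ShellSample

__all__ = [
    "write_gradient_table",
    "read_gradient_table",
    "save_nifti",
    "load_nifti",
    "save_param_maps",
    "masks_to_array",
    "save_masks",
    "load_masks",
]


def write_gradient_table(protocol: AcquisitionProtocol, prefix: str | Path
                         ) -> None:
    """Write ``<prefix>.bval`` / ``.bvec`` (FSL layout) and ``.beta``."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), protocol.bvals[None], fmt="%.1f")
    np.savetxt(prefix.with_suffix(".bvec"), protocol.bvecs.T, fmt="%.8f")
    np.savetxt(prefix.with_suffix(".beta"), protocol.betas[:, None],
               fmt="%.6f")


def read_gradient_table(prefix: str | Path, **protocol_kwargs
                        ) -> AcquisitionProtocol:
    """Read bval/bvec(/beta) files back into a protocol."""
    prefix = Path(prefix)
    bvals = np.atleast_1d(np.loadtxt(prefix.with_suffix(".bval")).ravel())
    bvecs = np.loadtxt(prefix.with_suffix(".bvec"))
    bvecs = np.atleast_2d(bvecs)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    beta_file = prefix.with_suffix(".beta")
    if beta_file.exists():
        betas = np.atleast_1d(np.loadtxt(beta_file).ravel())
    else:
        betas = np.ones_like(bvals)
    shells = {b: i for i, b in enumerate(sorted(set(bvals)))}
    samples = []
    for b, g, beta in zip(bvals, bvecs, betas):
        g = g / max(np.linalg.norm(g), 1e-12) if np.linalg.norm(g) > 0 \
            else np.array([0.0, 0.0, 1.0])
        samples.append(ShellSample(b=float(b), direction=tuple(map(float, g)),
                                   beta=float(beta), shell_id=shells[b]))
    return AcquisitionProtocol(samples=tuple(samples), **protocol_kwargs)


def save_nifti(data: np.ndarray, path: str | Path,
               voxel_size: tuple[float, ...] = (1.0, 1.0, 1.0),
               units: str | None = None) -> None:
    """Save an array as NIfTI with an optional JSON units sidecar."""
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    if units is not None:
        sidecar = Path(str(path)).with_suffix("").with_suffix(".json") \
            if str(path).endswith(".nii.gz") else Path(str(path) + ".json")
        sidecar.write_text(json.dumps({"units": units}))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_param_maps(maps: dict[str, np.ndarray], outdir: str | Path,
                    voxel_size=(1.0, 1.0, 1.0)) -> None:
    units = {"fa": "fraction", "fw": "fraction", "p2": "dimensionless",
             "Da": "um^2/ms", "De_par": "um^2/ms", "De_perp": "um^2/ms",
             "FA": "dimensionless", "MD": "um^2/ms", "MK": "dimensionless"}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, data in maps.items():
        save_nifti(data, outdir / f"{name}.nii",
                   voxel_size=voxel_size, units=units.get(name))


def masks_to_array(masks: list[SamplingMask]) -> np.ndarray:
    """(n_vol, Ny, n_kz) boolean stack."""
    return np.stack([m.grid for m in masks])


def save_masks(masks: list[SamplingMask], path: str | Path) -> None:
    np.save(str(path), masks_to_array(masks))


def load_masks(path: str | Path) -> np.ndarray:
    return np.load(str(path))
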