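"""Digital multi-slab head phantom and multi-coil k-space simulator.

Generates a labeled tissue phantom (CSF core, WM bundles including a
corpus-callosum-like region, GM rim) with per-region compartment
parameters and ODFs, smooth complex coil sensitivities, a raised-cosine
slab excitation profile, per-shot motion-induced phase maps, and the
resulting noisy multi-channel k-space plus low-resolution 2D navigators.

The readout (kx) axis is fully sampled and therefore kept in image space;
encoding happens over the (ky, kz) phase-encode plane only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import cfftn, icfftn, crop_center
from .protocol import AcquisitionProtocol, SamplingMask
from .signal_model import (
    CompartmentParams,
    ODFModel,
    bandlimited_odf,
    synthesize_signal,
    uniform_odf,
)

__all__ = [
    "DigitalPhantom",
    "ShotPhaseSet",
    "KSpaceData",
    "NavigatorData",
    "build_phantom",
    "simulate_coils",
    "simulate_shot_phases",
    "simulate_acquisition",
    "slab_profile",
    "DEFAULT_REGIONS",
]

# label -> (name, params, odf mean direction, odf p2); CC values follow the
# in-vivo corpus-callosum estimates used as simulation inputs.
DEFAULT_REGIONS: dict[int, dict] = {
    1: dict(name="GM", params=CompartmentParams(0.25, 2.0, 1.2, 0.8, fw=0.10),
            mu=(0.0, 0.0, 1.0), p2=0.05),
    2: dict(name="WM", params=CompartmentParams(0.50, 2.10, 1.9, 0.7, fw=0.02),
            mu=(0.0, 1.0, 0.0), p2=0.35),
    3: dict(name="CC", params=CompartmentParams(0.60, 2.27, 1.8, 0.6, fw=0.05),
            mu=(1.0, 0.0, 0.0), p2=0.40),
    4: dict(name="CSF", params=CompartmentParams(0.0, 1.0, 1.0, 1.0, fw=1.0),
            mu=None, p2=0.0),
}

CC_LABEL = 3
CSF_LABEL = 4


@dataclass
class DigitalPhantom:
    """Ground-truth tissue phantom for one slab."""

    label_map: np.ndarray                       # (nx, ny, nz) int
    region_params: dict[int, CompartmentParams]
    region_odfs: dict[int, ODFModel]
    S0_map: np.ndarray                          # (nx, ny, nz)
    coil_sens: np.ndarray                       # (n_coil, nx, ny, nz) complex
    slab_profile: np.ndarray                    # (nz,) in [0, 1]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_map.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.label_map > 0

    def signal_volumes(self, protocol: AcquisitionProtocol,
                       apply_profile: bool = True) -> np.ndarray:
        """(n_vol, nx, ny, nz) noiseless magnitude images.

        Signals are constant within a label, so each region's q-vector is
        synthesized once and broadcast.
        """
        out = np.zeros((protocol.n_volumes,) + self.shape)
        for label, params in self.region_params.items():
            mask = self.label_map == label
            if not mask.any():
                continue
            sig = synthesize_signal(protocol, params, self.region_odfs[label])
            out[:, mask] = sig[:, None]
        out *= self.S0_map[None]
        if apply_profile:
            out *= self.slab_profile[None, None, None, :]
        return out

    def param_map(self, name: str) -> np.ndarray:
        """Voxelwise ground-truth map of one compartment parameter."""
        out = np.zeros(self.shape)
        for label, params in self.region_params.items():
            out[self.label_map == label] = getattr(params, name)
        return out


@dataclass
class ShotPhaseSet:
    """Smooth per-(volume, shot) 2D motion-phase maps in radians."""

    phase_maps: np.ndarray  # (n_vol, n_shots, nx, ny)
    severity: float

    @property
    def n_volumes(self) -> int:
        return self.phase_maps.shape[0]

    def zeros_like(self) -> "ShotPhaseSet":
        return ShotPhaseSet(np.zeros_like(self.phase_maps), 0.0)


@dataclass
class KSpaceData:
    """Multi-channel k-space; entries outside each volume's mask are zero."""

    data: np.ndarray            # (n_vol, n_coil, nx, ny, nz) complex
    masks: list[SamplingMask]
    noise_sigma: float
    b0_data: np.ndarray | None = None   # (n_coil, nx, ny, nz), fully sampled


@dataclass
class NavigatorData:
    """Low-resolution single-slice k-space per (volume, shot)."""

    data: np.ndarray            # (n_vol, n_shots, n_coil, nav_nx, nav_ny)
    ky_mask: np.ndarray         # (nav_ny,) bool, undersampling along ky
    coil_sens: np.ndarray       # (n_coil, nav_nx, nav_ny) complex
    noise_sigma: float


def slab_profile(nz: int, slab_frac: float = 0.7, edge_frac: float = 0.15
                 ) -> np.ndarray:
    """Raised-cosine-edged excitation profile over the slab FOVz.

    The flat top spans ``slab_frac`` of the FOV (14 of 20 mm by default)
    with cosine roll-offs of width ``edge_frac`` on either side.
    """
    z = (np.arange(nz) + 0.5) / nz - 0.5          # in (-0.5, 0.5)
    half = slab_frac / 2.0
    edge = max(edge_frac, 1e-6)
    d = np.abs(z) - half
    prof = np.where(
        d <= 0, 1.0,
        np.where(d >= edge, 0.0, 0.5 * (1.0 + np.cos(np.pi * d / edge))),
    )
    return prof


def build_phantom(shape: tuple[int, int, int], seed: int = 0,
                  regions: dict[int, dict] | None = None,
                  grid_order: int = 1000) -> DigitalPhantom:
    """Deterministic labeled head phantom with 8-coil sensitivities."""
    nx, ny, nz = shape
    if nx < 16 or ny < 16 or nz < 4:
        raise ValueError(f"phantom shape too small: {shape}")
    regions = DEFAULT_REGIONS if regions is None else regions

    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.zeros((1, 1, nz))
    rr = np.sqrt((x / 0.92) ** 2 + (y / 0.88) ** 2) + z

    label = np.zeros(shape, dtype=int)
    label[rr < 1.0] = 1                                   # GM rim
    label[rr < 0.82] = 2                                  # WM interior
    cc = (np.abs(y) < 0.16) & (np.abs(x) < 0.55) & (rr < 0.82)
    label[np.broadcast_to(cc, shape)] = 3                 # CC-like bar
    csf = (np.sqrt((x / 0.18) ** 2 + ((y - 0.35) / 0.22) ** 2) + z) < 1.0
    label[np.broadcast_to(csf, shape) & (rr < 0.82)] = 4  # ventricle CSF

    region_params = {k: v["params"] for k, v in regions.items()}
    region_odfs = {}
    for k, v in regions.items():
        if v["mu"] is None or v["p2"] <= 0:
            region_odfs[k] = uniform_odf(grid_order)
        else:
            region_odfs[k] = bandlimited_odf(v["mu"], v["p2"], grid_order)

    rng = np.random.default_rng(seed)
    # mild smooth S0 shading so S0 is not a trivial constant
    gx = rng.uniform(-0.1, 0.1)
    gy = rng.uniform(-0.1, 0.1)
    S0 = (1.0 + gx * x + gy * y + 0.0 * z) * (label > 0)

    coils = simulate_coils(8, shape, seed=seed + 1)
    prof = slab_profile(nz)
    return DigitalPhantom(
        label_map=label,
        region_params=region_params,
        region_odfs=region_odfs,
        S0_map=np.broadcast_to(S0, shape).copy(),
        coil_sens=coils,
        slab_profile=prof,
    )


def simulate_coils(n_coils: int, shape: tuple[int, int, int],
                   seed: int = 0) -> np.ndarray:
    """Smooth complex coil maps, unit root-sum-of-squares everywhere."""
    if n_coils < 1:
        raise ValueError("need at least one coil")
    nx, ny, nz = shape
    rng = np.random.default_rng(seed)
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    maps = np.empty((n_coils,) + tuple(shape), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cx, cy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 0.9 ** 2))
        mag = mag * (1.0 + 0.1 * rng.uniform(-1, 1) * z)
        ph = (rng.uniform(-np.pi, np.pi)
              + 0.5 * rng.standard_normal() * x
              + 0.5 * rng.standard_normal() * y
              + 0.2 * rng.standard_normal() * x * y)
        maps[c] = mag * np.exp(1j * ph)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= np.maximum(rss, 1e-12)[None]
    return maps


def simulate_shot_phases(protocol: AcquisitionProtocol,
                         masks: list[SamplingMask],
                         shape_xy: tuple[int, int],
                         severity: float = 0.5,
                         seed: int = 0) -> ShotPhaseSet:
    """Second-order polynomial phase per shot, N(0, severity^2 * b/1000)
    coefficients; identically zero for b = 0 volumes."""
    if severity < 0:
        raise ValueError("severity must be >= 0")
    nx, ny = shape_xy
    n_shots = max(m.n_shots for m in masks) if masks else 0
    x = np.linspace(-1, 1, nx)[:, None]
    y = np.linspace(-1, 1, ny)[None, :]
    basis = np.stack([np.ones((nx, ny)) + 0 * x, x + 0 * y, y + 0 * x,
                      x * y, x ** 2 + 0 * y, y ** 2 + 0 * x])
    rng = np.random.default_rng(seed)
    phases = np.zeros((protocol.n_volumes, n_shots, nx, ny))
    for v, sample in enumerate(protocol.samples):
        scale = severity * np.sqrt(sample.b / 1000.0)
        coeffs = rng.standard_normal((n_shots, 6)) * scale
        if sample.b == 0:
            continue
        phases[v] = np.tensordot(coeffs, basis, axes=(1, 0))
    return ShotPhaseSet(phase_maps=phases, severity=severity)


def simulate_acquisition(phantom: DigitalPhantom,
                         protocol: AcquisitionProtocol,
                         masks: list[SamplingMask],
                         phases: ShotPhaseSet | None = None,
                         snr: float = np.inf,
                         seed: int = 0,
                         nav_size: int = 32,
                         ry_nav: int = 3) -> tuple[KSpaceData, NavigatorData]:
    """Forward-simulate the undersampled multi-coil acquisition.

    Per shot the phased, coil-weighted image is Fourier transformed over
    (y, z) and restricted to the shot's (ky, kz) samples. A fully sampled
    non-DW (zero phase) k-space and per-shot low-resolution navigators are
    produced alongside.
    """
    nx, ny, nz = phantom.shape
    if len(masks) != protocol.n_volumes:
        raise ValueError("need one mask per DW volume")
    for m in masks:
        if m.grid.shape != (ny, nz):
            raise ValueError(
                f"mask grid {m.grid.shape} does not match phantom ({ny},{nz})"
            )
    if phases is None:
        n_shots = max(m.n_shots for m in masks)
        phases = ShotPhaseSet(
            np.zeros((protocol.n_volumes, n_shots, nx, ny)), 0.0)

    images = phantom.signal_volumes(protocol)      # (Q, nx, ny, nz)
    b0_img = phantom.S0_map * phantom.slab_profile[None, None, :]
    fg = phantom.foreground
    sigma = 0.0 if np.isinf(snr) else float(np.mean(b0_img[fg]) / snr)
    rng = np.random.default_rng(seed)

    n_coils = phantom.coil_sens.shape[0]
    ksp = np.zeros((protocol.n_volumes, n_coils, nx, ny, nz), dtype=complex)
    nav_n = min(nav_size, nx, ny)
    navs = np.zeros((protocol.n_volumes, phases.phase_maps.shape[1],
                     n_coils, nav_n, nav_n), dtype=complex)
    zc = nz // 2

    for q in range(protocol.n_volumes):
        mask = masks[q]
        for kz, shot in mask.shot_assignment.items():
            phased = images[q] * np.exp(
                1j * phases.phase_maps[q, shot])[:, :, None]
            coil_imgs = phantom.coil_sens * phased[None]
            k = cfftn(coil_imgs, axes=(2, 3))      # over (y, z)
            ky_idx = np.nonzero(mask.grid[:, kz])[0]
            ksp[q, :, :, ky_idx, kz] = np.transpose(k[:, :, ky_idx, kz],
                                                    (2, 0, 1))
            # navigator: central slice of the same phased object
            nav_k = cfftn(
                phantom.coil_sens[:, :, :, zc] * phased[None, :, :, zc],
                axes=(1, 2))
            navs[q, shot] = crop_center(nav_k, (nav_n, nav_n), axes=(1, 2))

    ky_mask = np.zeros(nav_n, dtype=bool)
    ky_mask[::ry_nav] = True
    navs[:, :, :, :, ~ky_mask] = 0.0

    b0_k = cfftn(phantom.coil_sens * b0_img[None], axes=(2, 3))

    if sigma > 0:
        noise = rng.normal(scale=sigma / np.sqrt(2),
                           size=ksp.shape + (2,))
        sampled = np.zeros_like(ksp, dtype=bool)
        for q, m in enumerate(masks):
            sampled[q] = m.grid[None, None, :, :]
        ksp += np.where(sampled, noise[..., 0] + 1j * noise[..., 1], 0.0)
        b0_k += (rng.normal(scale=sigma / np.sqrt(2), size=b0_k.shape)
                 + 1j * rng.normal(scale=sigma / np.sqrt(2), size=b0_k.shape))
        nav_noise = (rng.normal(scale=sigma / np.sqrt(2), size=navs.shape)
                     + 1j * rng.normal(scale=sigma / np.sqrt(2),
                                       size=navs.shape))
        navs += np.where(ky_mask[None, None, None, None, :], nav_noise, 0.0)

    # low-resolution coil maps for navigator SENSE, from the central slice
    coil_slice_k = cfftn(phantom.coil_sens[:, :, :, zc], axes=(1, 2))
    coils_low = icfftn(crop_center(coil_slice_k, (nav_n, nav_n), axes=(1, 2)),
                       axes=(1, 2))
    rss = np.sqrt(np.sum(np.abs(coils_low) ** 2, axis=0))
    coils_low /= np.maximum(rss, 1e-12)[None]

    kdata = KSpaceData(data=ksp, masks=masks, noise_sigma=sigma, b0_data=b0_k)
    nav = NavigatorData(data=navs, ky_mask=ky_mask, coil_sens=coils_low,
                        noise_sigma=sigma)
    return kdata, nav
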