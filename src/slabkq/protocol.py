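"""Acquisition protocols, CAIPI sampling masks, and scan-time arithmetic.

A protocol is the full q-space design of a multi-shell, multi-slab
acquisition: one :class:`ShellSample` per diffusion-weighted (DW) volume
(b-value, unit gradient direction, encoding-shape scalar ``beta``), plus the
timing and slab geometry needed to schedule the 3D k-space shots.

Undersampling follows a randomized 2D CAIPI scheme over the (ky, kz)
phase-encode plane: each DW volume samples ``n_shots`` kz planes (an even
partition of the kz axis with a per-volume random circular offset) and,
within each sampled plane, every ``Ry``-th ky line with a kz-dependent
CAIPI offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "ShellSample",
    "AcquisitionProtocol",
    "SamplingConfig",
    "SamplingMask",
    "InvalidProtocolError",
    "build_protocol",
    "hemisphere_directions",
    "generate_caipi_masks",
    "volume_acquisition_time",
    "total_scan_time",
    "net_undersampling_factor",
    "slab_coverage",
    "fovz_from_slab",
]


class InvalidProtocolError(ValueError):
    """Raised when protocol/sampling parameters are inconsistent."""


@dataclass(frozen=True)
class ShellSample:
    """One DW volume's encoding: b-value (s/mm^2), direction, shape beta."""

    b: float
    direction: tuple[float, float, float]
    beta: float = 1.0
    shell_id: int = 0

    def __post_init__(self) -> None:
        if self.b < 0:
            raise InvalidProtocolError(f"negative b-value: {self.b}")
        if not 0.0 <= self.beta <= 1.0:
            raise InvalidProtocolError(f"beta outside [0, 1]: {self.beta}")
        n = math.sqrt(sum(c * c for c in self.direction))
        if abs(n - 1.0) > 1e-9:
            raise InvalidProtocolError(f"direction not unit-norm: |g|={n}")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered q-space samples plus timing and slab geometry."""

    samples: tuple[ShellSample, ...]
    TR: float = 2.0                  # seconds
    FOVz: float = 20.0               # mm
    slice_thickness: float = 1.0     # mm
    n_slabs: int = 8
    slab_thickness: float = 14.0     # mm
    oversampling_fraction: float = 0.4
    Ny: int = 210
    n_nondw_fully_sampled: int = 1

    def __post_init__(self) -> None:
        if not self.samples:
            raise InvalidProtocolError("protocol has no samples")
        for name in ("TR", "FOVz", "slice_thickness", "slab_thickness"):
            if getattr(self, name) <= 0:
                raise InvalidProtocolError(f"non-positive {name}")
        if self.n_slabs < 1 or self.Ny < 1:
            raise InvalidProtocolError("n_slabs and Ny must be >= 1")

    @property
    def n_kz(self) -> int:
        return round(self.FOVz / self.slice_thickness)

    @property
    def n_volumes(self) -> int:
        return len(self.samples)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([s.b for s in self.samples])

    @property
    def bvecs(self) -> np.ndarray:
        """(n_volumes, 3) unit directions."""
        return np.array([s.direction for s in self.samples])

    @property
    def betas(self) -> np.ndarray:
        return np.array([s.beta for s in self.samples])

    @property
    def shell_ids(self) -> np.ndarray:
        return np.array([s.shell_id for s in self.samples])


@dataclass(frozen=True)
class SamplingConfig:
    """CAIPI undersampling parameters.

    ``Rz`` is kept rational (e.g. ``Fraction(20, 6)`` for the printed 3.33)
    so shot counts are exact integers.
    """

    Ry: int = 3
    Rz: Fraction = Fraction(20, 6)
    seed: int = 0
    caipi_shift: int = 1

    def __post_init__(self) -> None:
        if self.Ry < 1:
            raise InvalidProtocolError(f"Ry must be >= 1, got {self.Ry}")
        if self.Rz < 1:
            raise InvalidProtocolError(f"Rz must be >= 1, got {self.Rz}")

    def n_shots(self, n_kz: int) -> int:
        if self.Rz > n_kz:
            raise InvalidProtocolError(
                f"Rz={self.Rz} exceeds n_kz={n_kz}")
        shots = int(math.ceil(n_kz / self.Rz))
        if not 1 <= shots <= n_kz:
            raise InvalidProtocolError(
                f"Rz={self.Rz} incompatible with n_kz={n_kz}"
            )
        return shots


def parse_rz(text: str | float | Fraction) -> Fraction:
    """Parse an Rz spec like ``"20/6"``, ``2`` or a Fraction."""
    if isinstance(text, Fraction):
        return text
    if isinstance(text, (int, float)):
        return Fraction(text).limit_denominator(1000)
    return Fraction(text)


@dataclass(frozen=True)
class SamplingMask:
    """Boolean (Ny, n_kz) grid of sampled phase encodes for one DW volume."""

    grid: np.ndarray                      # bool, shape (Ny, n_kz)
    shot_assignment: dict[int, int]       # sampled kz plane -> shot index
    Ry: int

    def __post_init__(self) -> None:
        if self.grid.dtype != bool:
            raise TypeError("mask grid must be boolean")

    @property
    def sampled_kz(self) -> list[int]:
        return sorted(self.shot_assignment)

    @property
    def n_shots(self) -> int:
        return len(set(self.shot_assignment.values()))


def hemisphere_directions(n: int, seed: int = 0, iters: int = 400) -> np.ndarray:
    """Approximately uniform directions on the hemisphere by electrostatic
    repulsion between antipodally symmetrized point pairs.

    Returns an (n, 3) array of unit vectors with nonnegative z.
    """
    rng = np.random.default_rng(seed)
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.1
    for it in range(iters):
        # force from both each point and its antipode
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            d = x[:, None, :] - sign * x[None, :, :]
            r2 = np.sum(d * d, axis=-1)
            np.fill_diagonal(r2, np.inf)
            r2 = np.maximum(r2, 1e-12)
            force += np.sum(d / (r2[..., None] * np.sqrt(r2)[..., None]), axis=1)
        x = x + step * force / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step *= 0.99
    x[x[:, 2] < 0] *= -1.0
    return x


def build_protocol(
    shell_bvalues: Sequence[float],
    n_dirs_per_shell: int | Sequence[int],
    betas: Sequence[float] | None = None,
    *,
    TR: float = 2.0,
    FOVz: float = 20.0,
    slice_thickness: float = 1.0,
    n_slabs: int = 8,
    slab_thickness: float = 14.0,
    oversampling_fraction: float = 0.4,
    Ny: int = 210,
    n_nondw_fully_sampled: int = 1,
    seed: int = 0,
) -> AcquisitionProtocol:
    """Build a multi-shell protocol with seeded repulsion direction sets.

    Parameters
    ----------
    shell_bvalues : distinct b-values in s/mm^2, one per shell.
    n_dirs_per_shell : directions per shell (scalar or per-shell list).
    betas : encoding-shape scalar per shell (default: all 1.0, linear).
    """
    bvals = list(shell_bvalues)
    if len(set(bvals)) != len(bvals):
        raise InvalidProtocolError("shell b-values must be distinct")
    if any(b < 0 for b in bvals):
        raise InvalidProtocolError("shell b-values must be >= 0")
    if isinstance(n_dirs_per_shell, int):
        ndirs = [n_dirs_per_shell] * len(bvals)
    else:
        ndirs = list(n_dirs_per_shell)
    if len(ndirs) != len(bvals) or any(n < 1 for n in ndirs):
        raise InvalidProtocolError("need n_dirs >= 1 for every shell")
    if betas is None:
        betas = [1.0] * len(bvals)
    if len(betas) != len(bvals):
        raise InvalidProtocolError("need one beta per shell")

    samples: list[ShellSample] = []
    for sid, (b, nd, beta) in enumerate(zip(bvals, ndirs, betas)):
        dirs = hemisphere_directions(nd, seed=seed + sid)
        for g in dirs:
            samples.append(
                ShellSample(b=float(b), direction=tuple(map(float, g)),
                            beta=float(beta), shell_id=sid)
            )
    return AcquisitionProtocol(
        samples=tuple(samples), TR=TR, FOVz=FOVz,
        slice_thickness=slice_thickness, n_slabs=n_slabs,
        slab_thickness=slab_thickness,
        oversampling_fraction=oversampling_fraction, Ny=Ny,
        n_nondw_fully_sampled=n_nondw_fully_sampled,
    )


def _caipi_mask_for_volume(
    Ny: int, n_kz: int, cfg: SamplingConfig, vol_idx: int
) -> SamplingMask:
    rng = np.random.default_rng([cfg.seed, vol_idx])
    n_shots = cfg.n_shots(n_kz)
    spacing = n_kz / n_shots
    offset = rng.uniform(0.0, n_kz)
    kz_planes = sorted(int(math.floor(offset + i * spacing)) % n_kz
                       for i in range(n_shots))
    base_ky_offset = int(rng.integers(cfg.Ry))
    grid = np.zeros((Ny, n_kz), dtype=bool)
    shot_assignment: dict[int, int] = {}
    for rank, kz in enumerate(kz_planes):
        ky0 = (base_ky_offset + cfg.caipi_shift * rank) % cfg.Ry
        grid[ky0::cfg.Ry, kz] = True
        shot_assignment[kz] = rank
    return SamplingMask(grid=grid, shot_assignment=shot_assignment, Ry=cfg.Ry)


def generate_caipi_masks(
    protocol: AcquisitionProtocol, cfg: SamplingConfig
) -> list[SamplingMask]:
    """One randomized CAIPI mask per DW volume; deterministic given cfg.seed."""
    n_kz = protocol.n_kz
    cfg.n_shots(n_kz)  # validates Rz vs n_kz
    return [
        _caipi_mask_for_volume(protocol.Ny, n_kz, cfg, v)
        for v in range(protocol.n_volumes)
    ]


def volume_acquisition_time(
    protocol: AcquisitionProtocol, cfg: SamplingConfig
) -> float:
    """Seconds to acquire one DW volume: kz shots x TR."""
    return cfg.n_shots(protocol.n_kz) * protocol.TR


def total_scan_time(protocol: AcquisitionProtocol, cfg: SamplingConfig) -> float:
    """Seconds for all DW volumes plus fully sampled non-DW volumes."""
    vat = volume_acquisition_time(protocol, cfg)
    nondw = protocol.n_nondw_fully_sampled * protocol.n_kz * protocol.TR
    return protocol.n_volumes * vat + nondw


def net_undersampling_factor(mask: SamplingMask) -> float:
    """(Ny x n_kz) / number of sampled (ky, kz) points."""
    n_sampled = int(mask.grid.sum())
    if n_sampled == 0:
        raise InvalidProtocolError("mask samples no points")
    return mask.grid.size / n_sampled


def slab_coverage(protocol: AcquisitionProtocol) -> float:
    """Nominal contiguous slice-direction coverage in mm."""
    return protocol.n_slabs * protocol.slab_thickness


def fovz_from_slab(
    slab_thickness: float, oversampling_fraction: float, slice_thickness: float
) -> float:
    """Slab FOVz: thickness x (1 + oversampling), rounded up to a whole
    number of slices (14 mm x 1.4 = 19.6 -> 20 mm at 1 mm slices)."""
    raw = slab_thickness * (1.0 + oversampling_fraction)
    return math.ceil(raw / slice_thickness - 1e-9) * slice_thickness
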