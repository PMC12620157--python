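"""Phase-compensated SENSE operators and the joint k-q reconstruction.

The forward model maps the volume stack S (one complex 3D image per DW
volume) to multi-coil k-space: per shot, multiply by the shot's estimated
motion phase and each coil sensitivity, Fourier transform over the (y, z)
phase encodes, and restrict to the shot's sampled (ky, kz) points.

The joint reconstruction minimizes

    || A(S) - Y ||^2 + lambda1 * TV(S) + lambda2 * || S - Q(S) ||^2

by half-quadratic alternation: (i) freeze the denoiser output Z = Q(|S|),
(ii) CG-solve the quadratic data + anchor subproblem, (iii) apply an
approximate TV proximal step to the magnitudes. lambda2 = 0 gives the
ablated variant; lambda1 = lambda2 = 0 is plain phase-compensated
CG-SENSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from .dae_prior import DAEModel, denoise
from .fourier import cfftn, icfftn, zeropad_center
from .phantom import KSpaceData, NavigatorData
from .protocol import SamplingMask

__all__ = [
    "ReconConfig",
    "DWVolumeSet",
    "sense_forward",
    "sense_adjoint",
    "cg_solve",
    "cg_sense_navigator",
    "upsample_phase_maps",
    "estimate_navigator_phases",
    "qmodel_reconstruct",
    "tv_prox",
    "tv_norm",
    "combine_slabs",
    "sense_b0_image",
]


@dataclass(frozen=True)
class ReconConfig:
    lambda1: float = 0.0            # TV weight
    lambda2: float = 0.0            # DAE-prior weight
    outer_iters: int = 15
    cg_tol: float = 1e-6
    cg_max_iters: int = 30
    tv_inner_iters: int = 10
    mu_tv: float = 0.5              # half-quadratic penalty for the TV split

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be >= 0")
        if not 0.0 < self.cg_tol < 1.0:
            raise ValueError("cg_tol must lie in (0, 1)")
        if self.lambda1 > 0 and self.mu_tv <= 0:
            raise ValueError("TV split needs mu_tv > 0")


@dataclass
class DWVolumeSet:
    """Reconstructed volume stack for one slab."""

    data: np.ndarray                 # (n_vol, nx, ny, nz) complex
    b0: np.ndarray | None = None     # (nx, ny, nz)
    meta: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


def _shot_items(mask: SamplingMask):
    return sorted(mask.shot_assignment.items(), key=lambda kv: kv[1])


def sense_forward(S: np.ndarray, coil_sens: np.ndarray,
                  shot_phases: np.ndarray,
                  masks: list[SamplingMask]) -> np.ndarray:
    """A(S): (n_vol, nx, ny, nz) -> (n_vol, n_coil, nx, ny, nz) k-space."""
    n_vol, nx, ny, nz = S.shape
    if len(masks) != n_vol:
        raise ValueError("one mask per volume required")
    n_coil = coil_sens.shape[0]
    Y = np.zeros((n_vol, n_coil, nx, ny, nz), dtype=complex)
    for q in range(n_vol):
        items = _shot_items(masks[q])
        shots = [s for _, s in items]
        phasor = np.exp(1j * shot_phases[q, shots])          # (S, nx, ny)
        stack = (S[q][None, None]
                 * phasor[:, None, :, :, None]
                 * coil_sens[None])                          # (S, C, x, y, z)
        k = cfftn(stack, axes=(3, 4))
        for si, (kz, _) in enumerate(items):
            ky_idx = np.nonzero(masks[q].grid[:, kz])[0]
            Y[q, :, :, ky_idx, kz] = np.transpose(k[si][:, :, ky_idx, kz],
                                                  (2, 0, 1))
    return Y


def sense_adjoint(Y: np.ndarray, coil_sens: np.ndarray,
                  shot_phases: np.ndarray,
                  masks: list[SamplingMask]) -> np.ndarray:
    """Exact adjoint of :func:`sense_forward`."""
    n_vol, n_coil, nx, ny, nz = Y.shape
    S = np.zeros((n_vol, nx, ny, nz), dtype=complex)
    for q in range(n_vol):
        items = _shot_items(masks[q])
        ksel = np.zeros((len(items), n_coil, nx, ny, nz), dtype=complex)
        for si, (kz, _) in enumerate(items):
            ky_idx = np.nonzero(masks[q].grid[:, kz])[0]
            # both sides index (ky, coil, x): advanced indices non-adjacent,
            # so broadcast dims move to the front on both get and set
            ksel[si, :, :, ky_idx, kz] = Y[q, :, :, ky_idx, kz]
        img = icfftn(ksel, axes=(3, 4))
        combined = np.sum(np.conj(coil_sens)[None] * img, axis=1)  # (S,x,y,z)
        shots = [s for _, s in items]
        phasor = np.exp(-1j * shot_phases[q, shots])
        S[q] = np.sum(combined * phasor[:, :, :, None], axis=0)
    return S


def _normal_op(coil_sens, shot_phases, masks) -> Callable:
    def op(S: np.ndarray) -> np.ndarray:
        return sense_adjoint(
            sense_forward(S, coil_sens, shot_phases, masks),
            coil_sens, shot_phases, masks)
    return op


def cg_solve(op: Callable, rhs: np.ndarray, x0: np.ndarray | None = None,
             tol: float = 1e-6, max_iters: int = 30
             ) -> tuple[np.ndarray, dict]:
    """Conjugate gradients on a Hermitian PSD operator.

    Returns the iterate and a history dict with residual norms and the
    quadratic objective 0.5 x'Ax - Re x'b (non-increasing under CG).
    """
    x = np.zeros_like(rhs) if x0 is None else x0.copy()
    r = rhs - op(x)
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    rhs_norm = float(np.linalg.norm(rhs)) or 1.0
    res_hist = [np.sqrt(rs) / rhs_norm]
    obj_hist = [float(0.5 * np.vdot(x, rhs - r).real - np.vdot(x, rhs).real)]
    for _ in range(max_iters):
        if np.sqrt(rs) / rhs_norm < tol:
            break
        Ap = op(p)
        denom = float(np.vdot(p, Ap).real)
        if denom <= 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * Ap
        rs_new = float(np.vdot(r, r).real)
        p = r + (rs_new / rs) * p
        rs = rs_new
        res_hist.append(np.sqrt(rs) / rhs_norm)
        obj_hist.append(
            float(0.5 * np.vdot(x, rhs - r).real - np.vdot(x, rhs).real))
    return x, {"residuals": res_hist, "objective": obj_hist}


# ---------------------------------------------------------------------------
# navigator phase estimation


def _cg_nav_images(nav: NavigatorData, cg_tol: float = 1e-6,
                   cg_max_iters: int = 30,
                   smooth_sigma: float = 1.0,
                   ridge: float = 1e-3) -> np.ndarray:
    """CG-SENSE each navigator shot; returns smoothed complex images.

    A small Tikhonov ridge keeps the unaliasing well conditioned where
    coil geometry is weak; the complex Gaussian smoothing implements the
    low-pass filtering of the phase estimate.
    """
    n_vol, n_shots, n_coil, nn, _ = nav.data.shape
    C = nav.coil_sens
    kmask = nav.ky_mask[None, None, :]  # broadcast over (coil, x, y)

    def op(x):
        k = cfftn(C * x[None], axes=(1, 2))
        k = np.where(kmask, k, 0.0)
        return (np.sum(np.conj(C) * icfftn(k, axes=(1, 2)), axis=0)
                + ridge * x)

    imgs = np.zeros((n_vol, n_shots, nn, nn), dtype=complex)
    for q in range(n_vol):
        for s in range(n_shots):
            y = nav.data[q, s]
            rhs = np.sum(np.conj(C) * icfftn(np.where(kmask, y, 0.0),
                                             axes=(1, 2)), axis=0)
            img, _ = cg_solve(op, rhs, tol=cg_tol, max_iters=cg_max_iters)
            if smooth_sigma > 0:
                img = (gaussian_filter(img.real, smooth_sigma)
                       + 1j * gaussian_filter(img.imag, smooth_sigma))
            imgs[q, s] = img
    return imgs


def cg_sense_navigator(nav: NavigatorData, cg_tol: float = 1e-6,
                       cg_max_iters: int = 30,
                       smooth_sigma: float = 1.0) -> np.ndarray:
    """Per-shot navigator phase maps, (n_vol, n_shots, nav_n, nav_n) rad."""
    return np.angle(_cg_nav_images(nav, cg_tol, cg_max_iters, smooth_sigma))


def upsample_phase_maps(images: np.ndarray,
                        shape_xy: tuple[int, int]) -> np.ndarray:
    """Phase of the zero-padded Fourier interpolation of complex images.

    Upsampling the magnitude-weighted complex image (rather than a
    unit-magnitude phasor) keeps meaningless background phase from
    ringing into the object.
    """
    nx, ny = shape_xy
    k = cfftn(images, axes=(-2, -1))
    k = zeropad_center(k, (nx, ny), axes=(-2, -1))
    return np.angle(icfftn(k, axes=(-2, -1)))


def estimate_navigator_phases(nav: NavigatorData,
                              shape_xy: tuple[int, int],
                              **kwargs) -> np.ndarray:
    """Navigator CG-SENSE phases upsampled to (n_vol, n_shots, nx, ny)."""
    return upsample_phase_maps(_cg_nav_images(nav, **kwargs), shape_xy)


# ---------------------------------------------------------------------------
# TV proximal step


def _grad3(u: np.ndarray) -> np.ndarray:
    g = np.zeros((3,) + u.shape)
    g[0, :-1] = u[1:] - u[:-1]
    g[1, :, :-1] = u[:, 1:] - u[:, :-1]
    g[2, :, :, :-1] = u[:, :, 1:] - u[:, :, :-1]
    return g


def _div3(p: np.ndarray) -> np.ndarray:
    d = np.zeros(p.shape[1:])
    d[:-1] += p[0, :-1]
    d[1:] -= p[0, :-1]
    d[:, :-1] += p[1, :, :-1]
    d[:, 1:] -= p[1, :, :-1]
    d[:, :, :-1] += p[2, :, :, :-1]
    d[:, :, 1:] -= p[2, :, :, :-1]
    return d


def tv_norm(u: np.ndarray) -> float:
    """Isotropic discrete TV of one 3D volume."""
    g = _grad3(np.asarray(u, dtype=float))
    return float(np.sqrt(np.sum(g * g, axis=0)).sum())


def _tv_prox_volume(m: np.ndarray, weight: float, iters: int) -> np.ndarray:
    # Chambolle dual projection for prox_{weight * TV}
    p = np.zeros((3,) + m.shape)
    tau = 0.125
    for _ in range(iters):
        g = _grad3(_div3(p) - m / weight)
        denom = 1.0 + tau * np.sqrt(np.sum(g * g, axis=0))
        p = (p + tau * g) / denom[None]
    return m - weight * _div3(p)


def tv_prox(S: np.ndarray, weight: float, inner_iters: int = 10) -> np.ndarray:
    """Approximate prox of volume-wise spatial TV on magnitudes.

    Phase is preserved; ``weight`` = 0 is the identity.
    """
    if weight < 0:
        raise ValueError("TV weight must be >= 0")
    if weight == 0:
        return S.copy()
    out = np.empty_like(S)
    for q in range(S.shape[0]):
        mag = np.abs(S[q])
        sm = _tv_prox_volume(mag, weight, inner_iters)
        phase = np.exp(1j * np.angle(S[q])) if np.iscomplexobj(S) else 1.0
        out[q] = sm * phase
    return out


# ---------------------------------------------------------------------------
# joint reconstruction


def sense_b0_image(b0_kspace: np.ndarray, coil_sens: np.ndarray) -> np.ndarray:
    """SENSE-combine a fully sampled non-DW k-space (unit-RSS coils)."""
    imgs = icfftn(b0_kspace, axes=(2, 3))
    return np.abs(np.sum(np.conj(coil_sens) * imgs, axis=0))


def qmodel_reconstruct(kdata: KSpaceData, coil_sens: np.ndarray,
                       nav_phases: np.ndarray | None,
                       dae_model: DAEModel | None,
                       cfg: ReconConfig) -> DWVolumeSet:
    """Joint k-q reconstruction of all DW volumes of one slab."""
    Y = kdata.data
    n_vol, n_coil, nx, ny, nz = Y.shape
    if cfg.lambda2 > 0 and dae_model is None:
        raise ValueError("lambda2 > 0 requires a trained denoiser")
    if dae_model is not None and dae_model.n_q != n_vol:
        raise ValueError("denoiser width does not match volume count")
    masks = kdata.masks
    n_shots = max(m.n_shots for m in masks)
    if nav_phases is None:
        nav_phases = np.zeros((n_vol, n_shots, nx, ny))

    b0_img = None
    if kdata.b0_data is not None:
        b0_img = sense_b0_image(kdata.b0_data, coil_sens)

    AHy = sense_adjoint(Y, coil_sens, nav_phases, masks)
    normal = _normal_op(coil_sens, nav_phases, masks)
    lam1, lam2, mu = cfg.lambda1, cfg.lambda2, cfg.mu_tv

    # half-quadratic splitting: freeze denoiser output Z and TV-prox
    # output V, then CG-solve the resulting quadratic
    #   (A'A + lam2 + mu) S = A'Y + lam2 Z + mu V.
    anchor_weight = (lam2 if lam2 > 0 else 0.0) + (mu if lam1 > 0 else 0.0)
    S = AHy.copy()
    history: list[dict] = []
    for it in range(cfg.outer_iters):
        S_prev = S
        rhs = AHy
        if lam2 > 0:
            sig = np.moveaxis(np.abs(S), 0, -1)          # (x, y, z, q)
            Z = denoise(dae_model, sig, b0=b0_img)
            Z = np.moveaxis(np.clip(Z, 0.0, None), -1, 0)
            rhs = rhs + lam2 * Z.astype(complex)
        if lam1 > 0:
            V = tv_prox(S, lam1 / mu, cfg.tv_inner_iters)
            rhs = rhs + mu * V
        if anchor_weight > 0:
            op = lambda X: normal(X) + anchor_weight * X
        else:
            op = normal
        S, info = cg_solve(op, rhs, x0=S_prev, tol=cfg.cg_tol,
                           max_iters=cfg.cg_max_iters)
        history.append(info)
        rel = (np.linalg.norm(S - S_prev)
               / max(np.linalg.norm(S_prev), 1e-30))
        if rel < 1e-4:
            break
        if anchor_weight == 0:
            break  # pure quadratic problem: one CG solve suffices
    return DWVolumeSet(data=S, b0=b0_img,
                       meta={"cg_history": history, "config": cfg})


def combine_slabs(slab_volumes: list[np.ndarray],
                  slab_profiles: list[np.ndarray],
                  slab_positions: list[int],
                  nz_total: int | None = None) -> np.ndarray:
    """Profile-weighted average of overlapping slabs along z.

    ``slab_positions`` give each slab's starting z index on the combined
    grid; weights are renormalized to sum to 1 per z plane.
    """
    if nz_total is None:
        nz_total = max(pos + vol.shape[-1]
                       for pos, vol in zip(slab_positions, slab_volumes))
    out_shape = slab_volumes[0].shape[:-1] + (nz_total,)
    num = np.zeros(out_shape, dtype=slab_volumes[0].dtype)
    den = np.zeros(nz_total)
    for vol, prof, pos in zip(slab_volumes, slab_profiles, slab_positions):
        nzs = vol.shape[-1]
        num[..., pos:pos + nzs] += vol * prof
        den[pos:pos + nzs] += prof
    if np.any(den <= 1e-12):
        raise ValueError("slab profiles leave gaps in z coverage")
    return num / den
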