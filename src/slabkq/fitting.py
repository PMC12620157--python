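"""Compartment-parameter estimation, DTI/DKI validation fits, ROI stats.

The 3-compartment fit works on per-shell rotational invariants of the
signal: R0 (the spherical mean) and R2 (the l = 2 invariant), with a
scalar orientation-dispersion parameter p2 in [0, 1] absorbing the ODF.
For a kernel K and an axially symmetric ODF, Funk-Hecke gives the
signal's SH coefficients as s_lm = lambda_l * p_lm with

    lambda_l(b, beta) = 2*pi * Integral_{-1}^{1} K(b, beta, t^2) P_l(t) dt

so R0 = lambda_0 / sqrt(4*pi) and R2 = p2 * sqrt(5/(4*pi)) * |lambda_2|.
Three shells provide six invariants for the six unknowns
(fa, Da, De_par, De_perp, fw, p2); a bounded multistart nonlinear
least-squares picks the best branch and flags near-degenerate voxels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import sph_harm_y

from .protocol import AcquisitionProtocol
from .signal_model import CompartmentParams, sphere_quadrature

__all__ = [
    "FitResult",
    "ROIStats",
    "FitConfig",
    "spherical_mean",
    "shell_invariants",
    "kernel_invariants",
    "fit_compartments",
    "fit_voxel",
    "fit_dti",
    "fit_dki",
    "roi_statistics",
    "FLAG_OK",
    "FLAG_BRANCH",
    "FLAG_CSF",
]

FLAG_OK = 0
FLAG_BRANCH = 1   # Da <-> De_par branches indistinguishable (< 1% residual)
FLAG_CSF = 2      # free-water dominated, intra/extra parameters undefined

_B_SCALE = 1e-3


@dataclass
class FitConfig:
    n_starts: int = 10
    lmax: int = 4              # SH order for the data-side invariant fit
    seed: int = 0
    ftol: float = 1e-12
    branch_tol: float = 0.01


@dataclass
class FitResult:
    fa: np.ndarray
    Da: np.ndarray
    De_par: np.ndarray
    De_perp: np.ndarray
    fw: np.ndarray
    p2: np.ndarray
    residual: np.ndarray
    flags: np.ndarray
    converged: np.ndarray

    def params_at(self, idx) -> CompartmentParams:
        return CompartmentParams(
            fa=float(self.fa[idx]), Da=float(self.Da[idx]),
            De_par=float(self.De_par[idx]), De_perp=float(self.De_perp[idx]),
            fw=float(self.fw[idx]))


@dataclass
class ROIStats:
    """Per-(ROI, parameter) mean / SD / COV table."""

    table: dict[tuple[int, str], tuple[float, float, float]]
    excluded: list[int] = field(default_factory=list)

    def mean(self, roi: int, param: str) -> float:
        return self.table[(roi, param)][0]

    def sd(self, roi: int, param: str) -> float:
        return self.table[(roi, param)][1]

    def cov(self, roi: int, param: str) -> float:
        return self.table[(roi, param)][2]


# ---------------------------------------------------------------------------
# data-side invariants


def _shell_groups(protocol: AcquisitionProtocol) -> list[tuple[float, float, np.ndarray]]:
    """Distinct (b, beta) groups with their volume indices, b > 0 only."""
    groups: dict[tuple[float, float], list[int]] = {}
    for i, s in enumerate(protocol.samples):
        if s.b > 0:
            groups.setdefault((s.b, s.beta), []).append(i)
    return [(b, beta, np.array(ix)) for (b, beta), ix in sorted(groups.items())]


def _normalize(volumes: np.ndarray, protocol: AcquisitionProtocol,
               b0: np.ndarray | None) -> np.ndarray:
    """b0-normalize (q first axis); uses b=0 volumes if b0 is not given."""
    if b0 is None:
        zero = protocol.bvals == 0
        if not zero.any():
            raise ValueError("no b0 reference: pass b0 or include b=0 volumes")
        b0 = volumes[zero].mean(axis=0)
    return volumes / np.maximum(b0, 1e-12)[None]


def spherical_mean(volumes: np.ndarray, protocol: AcquisitionProtocol,
                   b0: np.ndarray | None = None
                   ) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Powder averages of b0-normalized signals per (b, beta) group.

    ``volumes`` has the q dimension first. Returns the group labels and a
    stacked array of per-group mean maps.
    """
    norm = _normalize(volumes, protocol, b0)
    groups = _shell_groups(protocol)
    labels = [(b, beta) for b, beta, _ in groups]
    means = np.stack([norm[ix].mean(axis=0) for _, _, ix in groups])
    return labels, means


def _real_sh_basis(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Real, orthonormal even-order SH design matrix (n_dirs, n_coeff)."""
    x, y, z = dirs.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            Y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.imag)
            elif m == 0:
                cols.append(Y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.real)
    return np.stack(cols, axis=-1)


def shell_invariants(volumes: np.ndarray, protocol: AcquisitionProtocol,
                     b0: np.ndarray | None = None, lmax: int = 4
                     ) -> tuple[list[tuple[float, float]], np.ndarray, np.ndarray]:
    """Per-shell rotational invariants R0 and R2 of the normalized signal.

    Returns (group labels, R0, R2); R0/R2 are (n_groups, ...) maps.
    """
    norm = _normalize(volumes, protocol, b0)
    groups = _shell_groups(protocol)
    labels, R0s, R2s = [], [], []
    for b, beta, ix in groups:
        dirs = protocol.bvecs[ix]
        lm = lmax if len(ix) >= 15 else 2
        B = _real_sh_basis(dirs, lm)
        sig = norm[ix].reshape(len(ix), -1)
        coef, *_ = np.linalg.lstsq(B, sig, rcond=None)
        R0 = np.abs(coef[0])
        R2 = np.sqrt(np.sum(coef[1:6] ** 2, axis=0))
        labels.append((b, beta))
        R0s.append(R0.reshape(norm.shape[1:]))
        R2s.append(R2.reshape(norm.shape[1:]))
    return labels, np.stack(R0s), np.stack(R2s)


# ---------------------------------------------------------------------------
# model-side invariants (Funk-Hecke projections of the kernel)

_GL_T, _GL_W = np.polynomial.legendre.leggauss(64)
_P0 = np.ones_like(_GL_T)
_P2 = 0.5 * (3.0 * _GL_T**2 - 1.0)


def _axis_lambda(b_ms: np.ndarray, D: float, beta: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """lambda_0 and lambda_2 of exp(-b*D*[beta*(t^2-1/3)+1/3])."""
    expo = -b_ms[:, None] * D * (beta[:, None] * (_GL_T[None, :] ** 2 - 1 / 3)
                                 + 1 / 3)
    K = np.exp(expo)
    l0 = 2 * np.pi * K @ (_GL_W * _P0)
    l2 = 2 * np.pi * K @ (_GL_W * _P2)
    return l0, l2


def kernel_invariants(bvals: np.ndarray, betas: np.ndarray,
                      params: CompartmentParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Model R0 and lambda_2 (signed) per (b, beta), for p2 = 1."""
    b_ms = np.asarray(bvals, dtype=float) * _B_SCALE
    betas = np.asarray(betas, dtype=float)
    ia0, ia2 = _axis_lambda(b_ms, params.Da, betas)
    d_delta = params.De_par - params.De_perp
    ex0, ex2 = _axis_lambda(b_ms, d_delta, betas)
    ex_pre = np.exp(-b_ms * params.De_perp)
    csf = params.fw * np.exp(-b_ms * params.Dw) * 4 * np.pi
    l0 = params.fa * ia0 + params.fe * ex_pre * ex0 + csf
    l2 = params.fa * ia2 + params.fe * ex_pre * ex2
    R0 = l0 / np.sqrt(4 * np.pi)
    return R0, l2


def _theta_to_params(theta: np.ndarray) -> tuple[CompartmentParams, float]:
    fa, Da, De_par, ratio, wfrac, p2 = theta
    fw = (1.0 - fa) * wfrac
    return CompartmentParams(fa=fa, Da=Da, De_par=De_par,
                             De_perp=ratio * De_par, fw=fw), p2


def _invariant_residual(theta: np.ndarray, bvals: np.ndarray,
                        betas: np.ndarray, R0_data: np.ndarray,
                        R2_data: np.ndarray) -> np.ndarray:
    params, p2 = _theta_to_params(theta)
    R0_m, l2 = kernel_invariants(bvals, betas, params)
    R2_m = p2 * np.sqrt(5.0 / (4 * np.pi)) * np.abs(l2)
    return np.concatenate([R0_m - R0_data, R2_m - R2_data])


_THETA_LO = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
_THETA_HI = np.array([1.0, 3.2, 3.2, 1.0, 1.0, 1.0])


def _latin_hypercube(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    d = len(_THETA_LO)
    cube = np.empty((n, d))
    for j in range(d):
        cube[:, j] = (rng.permutation(n) + rng.uniform(0, 1, n)) / n
    return _THETA_LO + cube * (_THETA_HI - _THETA_LO)


def fit_voxel(R0: np.ndarray, R2: np.ndarray, bvals: np.ndarray,
              betas: np.ndarray, cfg: FitConfig | None = None
              ) -> tuple[CompartmentParams, float, float, int]:
    """Multistart invariant fit of one voxel.

    Returns (params, p2, residual_norm, flag).
    """
    cfg = cfg or FitConfig()
    starts = _latin_hypercube(cfg.n_starts, cfg.seed)
    # nudge starts off the exact bounds
    starts = np.clip(starts, _THETA_LO + 1e-3, _THETA_HI - 1e-3)
    sols = []
    for x0 in starts:
        try:
            res = least_squares(
                _invariant_residual, x0, bounds=(_THETA_LO, _THETA_HI),
                args=(bvals, betas, R0, R2),
                ftol=cfg.ftol, xtol=cfg.ftol, gtol=cfg.ftol, max_nfev=400)
        except Exception:
            continue
        sols.append((float(np.linalg.norm(res.fun)), res.x))
    if not sols:
        raise RuntimeError("all fit starts failed")
    sols.sort(key=lambda t: t[0])
    best_res = sols[0][0]
    data_scale = float(np.linalg.norm(np.concatenate([R0, R2])))
    # solutions indistinguishable in residual (< 1% relative, with a floor
    # for exactly-fitting noiseless data) form a tie group
    tie_tol = cfg.branch_tol * max(best_res, 1e-6 * data_scale)
    group = [x for r, x in sols if r - best_res <= tie_tol]
    best_x = min(group, key=lambda x: x[1])      # tie-break: lowest Da
    params, p2 = _theta_to_params(best_x)

    flag = FLAG_OK
    if params.fw > 0.95 or params.fa < 0.05:
        # negligible intra-axonal fraction: Da unidentifiable
        flag = FLAG_CSF
    elif any(abs(x[1] - best_x[1]) > 0.05 for x in group):
        # a distinct parameter branch fits equally well
        flag = FLAG_BRANCH
    return params, float(p2), best_res, flag


def fit_compartments(volumes: np.ndarray, protocol: AcquisitionProtocol,
                     fit_cfg: FitConfig | None = None,
                     b0: np.ndarray | None = None,
                     mask: np.ndarray | None = None) -> FitResult:
    """Voxelwise invariant fit over a volume stack (q axis first)."""
    cfg = fit_cfg or FitConfig()
    labels, R0, R2 = shell_invariants(volumes, protocol, b0=b0, lmax=cfg.lmax)
    bvals = np.array([b for b, _ in labels])
    betas = np.array([beta for _, beta in labels])
    spatial = volumes.shape[1:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    out = {name: np.zeros(spatial) for name in
           ("fa", "Da", "De_par", "De_perp", "fw", "p2", "residual")}
    flags = np.zeros(spatial, dtype=int)
    converged = np.zeros(spatial, dtype=bool)
    R0f = R0.reshape(len(labels), -1)
    R2f = R2.reshape(len(labels), -1)
    flat_mask = mask.ravel()
    for vi in np.nonzero(flat_mask)[0]:
        params, p2, res, flag = fit_voxel(R0f[:, vi], R2f[:, vi],
                                          bvals, betas, cfg)
        idx = np.unravel_index(vi, spatial) if spatial else ()
        out["fa"][idx] = params.fa
        out["Da"][idx] = params.Da
        out["De_par"][idx] = params.De_par
        out["De_perp"][idx] = params.De_perp
        out["fw"][idx] = params.fw
        out["p2"][idx] = p2
        out["residual"][idx] = res
        flags[idx] = flag
        converged[idx] = True
    return FitResult(fa=out["fa"], Da=out["Da"], De_par=out["De_par"],
                     De_perp=out["De_perp"], fw=out["fw"], p2=out["p2"],
                     residual=out["residual"], flags=flags,
                     converged=converged)


# ---------------------------------------------------------------------------
# DTI / DKI


def _sym_terms(dirs: np.ndarray, order: int) -> np.ndarray:
    """Multinomial-weighted monomials g^alpha, |alpha| = order."""
    cols = []
    for i, j, k in itertools.product(range(order + 1), repeat=3):
        if i + j + k != order:
            continue
        mult = math.factorial(order) // (
            math.factorial(i) * math.factorial(j) * math.factorial(k))
        cols.append(mult * dirs[:, 0] ** i * dirs[:, 1] ** j * dirs[:, 2] ** k)
    return np.stack(cols, axis=-1)


def _design_dti(bvals_ms: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [np.ones((len(dirs), 1)), -bvals_ms[:, None] * _sym_terms(dirs, 2)],
        axis=1)


def _design_dki(bvals_ms: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [np.ones((len(dirs), 1)),
         -bvals_ms[:, None] * _sym_terms(dirs, 2),
         (bvals_ms[:, None] ** 2 / 6.0) * _sym_terms(dirs, 4)],
        axis=1)


def _tensor_from_coeffs(d6: np.ndarray) -> np.ndarray:
    """(..., 6) [xx, xy, xz, yy, yz, zz] monomial coeffs -> (..., 3, 3).

    _sym_terms(order=2) enumerates (i,j,k) in itertools.product order:
    (0,0,2)=zz, (0,1,1)=yz, (0,2,0)=yy, (1,0,1)=xz, (1,1,0)=xy, (2,0,0)=xx,
    each already carrying its multiplicity.
    """
    zz, yz, yy, xz, xy, xx = np.moveaxis(d6, -1, 0)
    T = np.empty(d6.shape[:-1] + (3, 3))
    T[..., 0, 0] = xx
    T[..., 1, 1] = yy
    T[..., 2, 2] = zz
    # design columns already carry the multiplicity-2 factor, so the
    # fitted cross coefficients equal the tensor elements directly
    T[..., 0, 1] = T[..., 1, 0] = xy
    T[..., 0, 2] = T[..., 2, 0] = xz
    T[..., 1, 2] = T[..., 2, 1] = yz
    return T


def _wlls(X: np.ndarray, logy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched weighted linear least squares; w are per-sample weights."""
    A = np.einsum("vm,mi,mj->vij", w, X, X)
    b = np.einsum("vm,mi,vm->vi", w, X, logy)
    return np.linalg.solve(A, b[..., None])[..., 0]


def _prep_logs(volumes: np.ndarray, protocol: AcquisitionProtocol,
               b0: np.ndarray | None, beta_only: float | None = 1.0
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    keep = protocol.bvals > 0
    if beta_only is not None:
        keep &= protocol.betas == beta_only
    if keep.sum() < 6:
        raise ValueError("need >= 6 directions with linear encoding")
    norm = _normalize(volumes, protocol, b0)
    spatial = volumes.shape[1:]
    sig = norm[keep].reshape(keep.sum(), -1).T            # (n_vox, n_meas)
    sig = np.clip(sig, 1e-10, None)
    bvals_ms = protocol.bvals[keep] * _B_SCALE
    dirs = protocol.bvecs[keep]
    # the normalized b = 0 point (ln S = 0) anchors the intercept; without
    # it a 2-shell kurtosis design is rank deficient in its l = 0 channel
    logs = np.concatenate([np.log(sig), np.zeros((sig.shape[0], 1))], axis=1)
    bvals_ms = np.append(bvals_ms, 0.0)
    dirs = np.vstack([dirs, [0.0, 0.0, 1.0]])
    return logs, bvals_ms, dirs, spatial


def fit_dti(volumes: np.ndarray, protocol: AcquisitionProtocol,
            b0: np.ndarray | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted log-linear tensor fit; returns (FA, MD) maps (um^2/ms)."""
    logs, bvals_ms, dirs, spatial = _prep_logs(volumes, protocol, b0)
    X = _design_dti(bvals_ms, dirs)
    w = np.exp(logs) ** 2
    coef = _wlls(X, logs, w)
    D = _tensor_from_coeffs(coef[:, 1:7])
    evals = np.linalg.eigvalsh(D)
    md = evals.mean(axis=-1)
    num = np.sqrt(np.sum((evals - md[..., None]) ** 2, axis=-1))
    den = np.sqrt(np.sum(evals ** 2, axis=-1))
    fa = np.sqrt(1.5) * num / np.maximum(den, 1e-12)
    return fa.reshape(spatial), md.reshape(spatial)


def fit_dki(volumes: np.ndarray, protocol: AcquisitionProtocol,
            b0: np.ndarray | None = None, n_eval_dirs: int = 256,
            k_clip: tuple[float, float] = (0.0, 10.0)) -> np.ndarray:
    """Kurtosis-tensor fit; returns the mean-kurtosis (MK) map.

    MK is the (quadrature-weighted) average over ``n_eval_dirs`` uniform
    directions of K_app = V(g) / D_app(g)^2, clamped to ``k_clip``.
    """
    logs, bvals_ms, dirs, spatial = _prep_logs(volumes, protocol, b0)
    if len(np.unique(bvals_ms[bvals_ms > 0])) < 2:
        raise ValueError("DKI needs at least two nonzero shells")
    X = _design_dki(bvals_ms, dirs)
    w = np.exp(logs) ** 2
    coef = _wlls(X, logs, w)
    eval_dirs, eval_w = sphere_quadrature(n_eval_dirs)
    M2 = _sym_terms(eval_dirs, 2)        # (n_eval, 6)
    M4 = _sym_terms(eval_dirs, 4)        # (n_eval, 15)
    d_app = coef[:, 1:7] @ M2.T          # (n_vox, n_eval)
    v_app = coef[:, 7:] @ M4.T
    k_app = v_app / np.maximum(d_app, 1e-12) ** 2
    k_app = np.clip(k_app, *k_clip)
    mk = k_app @ eval_w
    return mk.reshape(spatial)


# ---------------------------------------------------------------------------
# ROI statistics


def roi_statistics(param_maps: dict[str, np.ndarray], label_map: np.ndarray,
                   roi_ids: list[int]) -> ROIStats:
    """Mean, SD (n-1 denominator) and COV (%) per ROI and parameter."""
    table: dict[tuple[int, str], tuple[float, float, float]] = {}
    excluded: list[int] = []
    for roi in roi_ids:
        sel = label_map == roi
        if not sel.any():
            excluded.append(roi)
            continue
        for name, pmap in param_maps.items():
            vals = np.asarray(pmap)[sel]
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            cov = 100.0 * sd / mean if mean != 0 else np.inf
            table[(roi, name)] = (mean, sd, cov)
    return ROIStats(table=table, excluded=excluded)
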