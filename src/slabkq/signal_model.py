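"""Three-compartment diffusion signal kernel with B-tensor encoding shape.

The per-direction kernel for encoding shape ``beta`` (1 = linear, 0 =
spherical) and squared cosine ``c = (g.n)^2`` between gradient and fiber
axis is

    K = fa * exp(-b*Da*[beta*(c - 1/3) + 1/3])
      + fe * exp(-b*De_perp - b*(De_par - De_perp)*[beta*(c - 1/3) + 1/3])
      + fw * exp(-b*Dw)

with fe = 1 - fa - fw. b-values are supplied in s/mm^2 and converted to
ms/um^2 internally so diffusivities in um^2/ms multiply directly.

Signals are ODF convolutions of this kernel; powder (spherical-mean)
averages have a closed form through erf.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "CompartmentParams",
    "ODFModel",
    "DW_FREE_WATER",
    "sphere_quadrature",
    "kernel_response",
    "synthesize_signal",
    "powder_average",
    "watson_odf",
    "bandlimited_odf",
    "uniform_odf",
]

DW_FREE_WATER = 3.0  # um^2/ms, fixed free-water diffusivity
_D_MAX = 3.2         # um^2/ms, upper bound on tissue diffusivities
_B_SCALE = 1e-3      # s/mm^2 -> ms/um^2


@dataclass(frozen=True)
class CompartmentParams:
    """Per-voxel tissue parameters (diffusivities in um^2/ms)."""

    fa: float
    Da: float
    De_par: float
    De_perp: float
    fw: float = 0.0
    Dw: float = DW_FREE_WATER

    def __post_init__(self) -> None:
        if not (0.0 <= self.fa <= 1.0 and 0.0 <= self.fw <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fa + self.fw > 1.0 + 1e-12:
            raise ValueError("fa + fw exceeds 1")
        if not 0.0 <= self.Da <= _D_MAX:
            raise ValueError(f"Da outside [0, {_D_MAX}]")
        if not 0.0 <= self.De_perp <= self.De_par <= _D_MAX:
            raise ValueError("need 0 <= De_perp <= De_par <= 3.2")
        if self.Dw < 0:
            raise ValueError("negative Dw")

    @property
    def fe(self) -> float:
        return 1.0 - self.fa - self.fw

    def as_array(self) -> np.ndarray:
        return np.array([self.fa, self.Da, self.De_par, self.De_perp, self.fw])


def sphere_quadrature(n_nodes: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic antipodally-symmetric spherical quadrature.

    Gauss-Legendre nodes in cos(theta) crossed with an even uniform phi
    grid; exact for high-order smooth integrands. Returns (nodes, weights)
    with nodes (n, 3) and weights summing to 1.
    """
    n_theta = max(4, int(round(np.sqrt(n_nodes))))
    n_phi = n_theta + (n_theta % 2)  # even count -> antipodal symmetry
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(1.0 - ct**2)
    nodes = np.stack(
        [
            np.outer(st, np.cos(phi)).ravel(),
            np.outer(st, np.sin(phi)).ravel(),
            np.outer(ct, np.ones(n_phi)).ravel(),
        ],
        axis=-1,
    )
    weights = np.outer(wt, np.ones(n_phi)).ravel()
    weights = weights / weights.sum()
    return nodes, weights


@dataclass(frozen=True)
class ODFModel:
    """Orientation distribution on a quadrature grid.

    ``weights`` already include the quadrature weights, so the signal is a
    plain weighted sum over nodes; they are nonnegative and sum to 1, and
    the node set is antipodally symmetric.
    """

    kind: str
    nodes: np.ndarray       # (n, 3) unit vectors
    weights: np.ndarray     # (n,) nonnegative, sum 1
    mu: tuple[float, float, float] | None = None
    kappa: float | None = None

    def __post_init__(self) -> None:
        if self.weights.min() < -1e-12:
            raise ValueError("negative ODF weights")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("ODF weights must sum to 1")


def _shape_exponent(b: np.ndarray, D: float, beta: np.ndarray,
                    cos2: np.ndarray) -> np.ndarray:
    """b*D*[beta*(cos2 - 1/3) + 1/3], b already in ms/um^2."""
    return b * D * (beta * (cos2 - 1.0 / 3.0) + 1.0 / 3.0)


def kernel_response(b, beta, cos2, params: CompartmentParams):
    """Signal fraction of the 3-compartment kernel (broadcasts over arrays).

    Parameters: b in s/mm^2, beta in [0, 1], cos2 = (g.n)^2 in [0, 1].
    """
    b = np.asarray(b, dtype=float) * _B_SCALE
    beta = np.asarray(beta, dtype=float)
    cos2 = np.asarray(cos2, dtype=float)
    if np.any(cos2 < -1e-12) or np.any(cos2 > 1.0 + 1e-12):
        raise ValueError("cos2 outside [0, 1]")
    intra = params.fa * np.exp(-_shape_exponent(b, params.Da, beta, cos2))
    extra = params.fe * np.exp(
        -b * params.De_perp
        - _shape_exponent(b, params.De_par - params.De_perp, beta, cos2)
    )
    csf = params.fw * np.exp(-b * params.Dw)
    out = intra + extra + csf
    return out if out.ndim else float(out)


def _stick_powder(b_ms: np.ndarray, D: float, beta) -> np.ndarray:
    """Spherical mean of exp(-b*D*[beta*(c-1/3)+1/3]) over fiber axis c.

    With x = b*D*beta the mean over c ~ (g.n)^2 on the sphere is
    exp(-b*D*(1-beta)/3) * sqrt(pi/(4x)) * erf(sqrt(x)); x -> 0 reduces to
    exp(-b*D/3).
    """
    b_ms = np.asarray(b_ms, dtype=float)
    beta = np.asarray(beta, dtype=float)
    x = b_ms * D * beta
    pre = np.exp(-b_ms * D * (1.0 - beta) / 3.0)
    small = x < 1e-8
    xs = np.where(small, 1.0, x)
    factor = np.where(
        small,
        np.exp(-x / 3.0),  # first-order consistent limit
        np.sqrt(np.pi / (4.0 * xs)) * erf(np.sqrt(xs)),
    )
    return pre * factor


def powder_average(b, beta, params: CompartmentParams):
    """Closed-form spherical mean of the kernel (b in s/mm^2)."""
    b_ms = np.asarray(b, dtype=float) * _B_SCALE
    beta = np.asarray(beta, dtype=float)
    intra = params.fa * _stick_powder(b_ms, params.Da, beta)
    dpar = params.De_par - params.De_perp
    extra = (
        params.fe
        * np.exp(-b_ms * params.De_perp)
        * _stick_powder(b_ms, dpar, beta)
    )
    csf = params.fw * np.exp(-b_ms * params.Dw)
    out = intra + extra + csf
    return out if out.ndim else float(out)


def uniform_odf(grid_order: int = 1000) -> ODFModel:
    nodes, weights = sphere_quadrature(grid_order)
    return ODFModel(kind="discrete", nodes=nodes, weights=weights)


def watson_odf(mu, kappa: float, grid_order: int = 1000) -> ODFModel:
    """Watson distribution, weights ~ quadrature_weight * exp(kappa*(mu.n)^2)."""
    if kappa < 0:
        raise ValueError("negative Watson concentration")
    mu = np.asarray(mu, dtype=float)
    if abs(np.linalg.norm(mu) - 1.0) > 1e-9:
        raise ValueError("mu must be a unit vector")
    nodes, qw = sphere_quadrature(grid_order)
    t2 = (nodes @ mu) ** 2
    w = qw * np.exp(kappa * (t2 - 1.0))  # -1 keeps exp bounded
    w = w / w.sum()
    return ODFModel(kind="watson", nodes=nodes, weights=w,
                    mu=tuple(map(float, mu)), kappa=float(kappa))


def bandlimited_odf(mu, p2: float, grid_order: int = 1000) -> ODFModel:
    """Axially symmetric ODF with only l in {0, 2} content:
    P(n) ~ 1 + 5*p2*P2(mu.n). Requires p2 in [0, 0.4] for nonnegativity.

    Because the ODF is exactly band-limited, sampled signals carry no
    l >= 4 energy, making low-order rotational-invariant fits alias-free.
    """
    if not 0.0 <= p2 <= 0.4:
        raise ValueError("band-limited ODF needs p2 in [0, 0.4]")
    mu = np.asarray(mu, dtype=float)
    if abs(np.linalg.norm(mu) - 1.0) > 1e-9:
        raise ValueError("mu must be a unit vector")
    nodes, qw = sphere_quadrature(grid_order)
    t2 = (nodes @ mu) ** 2
    p2_leg = 0.5 * (3.0 * t2 - 1.0)
    w = qw * (1.0 + 5.0 * p2 * p2_leg)
    w = np.maximum(w, 0.0)
    w = w / w.sum()
    return ODFModel(kind="discrete", nodes=nodes, weights=w,
                    mu=tuple(map(float, mu)), kappa=None)


def synthesize_signal(protocol, params: CompartmentParams, odf: ODFModel,
                      S0: float = 1.0) -> np.ndarray:
    """Per-volume signal: S0 * sum_n w(n) K(b_q, beta_q, (g_q.n)^2)."""
    if abs(odf.weights.sum() - 1.0) > 1e-6:
        raise ValueError("ODF weights must sum to 1")
    g = protocol.bvecs                       # (Q, 3)
    cos2 = (g @ odf.nodes.T) ** 2            # (Q, N)
    K = kernel_response(
        protocol.bvals[:, None], protocol.betas[:, None], cos2, params
    )
    return S0 * (K @ odf.weights)


def signals_for_params(protocol, params_list, odf_list, S0=1.0) -> np.ndarray:
    """Stack synthesize_signal over paired parameter/ODF lists."""
    return np.stack([
        synthesize_signal(protocol, p, o, S0)
        for p, o in zip(params_list, odf_list)
    ])
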