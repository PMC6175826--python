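"""Stress estimation from displacement fields via plane-strain Hooke's law.

Small-strain kinematics (finite differences on the PIV grid) give the
in-plane strain tensor; assuming strains involving the z-axis vanish (plane
strain), generalized Hooke's law for an isotropic material,

    sigma_ij = E/(1+v) * eps_ij + v*E/((1+v)(1-2v)) * eps_kk * delta_ij,

yields the stress tensor, including the out-of-plane normal stress
sigma_33 = lambda * eps_kk that plane strain induces.  The maximum principal
stress (largest eigenvalue of the 3x3 tensor) is reported per node and
field-wide.  Because the matrix actually yields and flows, a linear-elastic
estimate is an *upper bound* on the true stress sustained by the material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .displacement import DisplacementField
from .rheology import ElasticParams

__all__ = ["StrainField", "StressField", "strain_field", "hooke_stress",
           "principal_stress"]


@dataclass
class StrainField:
    """Small-strain tensor components per grid node (dimensionless);
    eps12 is the symmetric shear component 1/2(du/dy + dv/dx)."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    eps11: np.ndarray
    eps22: np.ndarray
    eps12: np.ndarray
    valid_mask: np.ndarray
    plane_strain: bool = True


@dataclass
class StressField:
    """Plane-strain stress tensor components per node (Pa)."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    sigma11: np.ndarray
    sigma22: np.ndarray
    sigma12: np.ndarray
    sigma33: np.ndarray
    valid_mask: np.ndarray
    params: ElasticParams
    principal_max: np.ndarray | None = None


def _grid_spacing(coords: np.ndarray, axis: int) -> float:
    d = np.diff(coords, axis=axis)
    step = float(d.flat[np.flatnonzero(d)[0]]) if np.any(d) else 1.0
    if not np.allclose(d, step):
        raise ValueError("grid must be regular")
    return step


def strain_field(field: DisplacementField, method: str = "central") -> StrainField:
    """Differentiate a displacement field into the small-strain tensor.

    ``method='central'`` uses central differences (one-sided at boundaries);
    ``method='element'`` evaluates bilinear-element strains at element
    centres and averages them back to nodes (parity option for
    element-based pipelines).  Invalid displacement nodes propagate to
    invalid strain nodes.
    """
    if field.u.shape[0] < 3 or field.u.shape[1] < 3:
        raise ValueError("need at least 3 nodes per axis")
    dx = _grid_spacing(field.grid_x, axis=1)
    dy = _grid_spacing(field.grid_y, axis=0)
    u = np.where(field.valid_mask, field.u, np.nan)
    v = np.where(field.valid_mask, field.v, np.nan)

    if method == "central":
        du_dy, du_dx = np.gradient(u, dy, dx)
        dv_dy, dv_dx = np.gradient(v, dy, dx)
    elif method == "element":
        # bilinear shape-function strains evaluated at element centres
        # (constant over each 2x2 element), then averaged back to nodes
        du_dx_e = np.diff(u, axis=1) / dx
        du_dx_c = 0.5 * (du_dx_e[:-1, :] + du_dx_e[1:, :])
        dv_dy_e = np.diff(v, axis=0) / dy
        dv_dy_c = 0.5 * (dv_dy_e[:, :-1] + dv_dy_e[:, 1:])
        du_dy_e = np.diff(u, axis=0) / dy
        du_dy_c = 0.5 * (du_dy_e[:, :-1] + du_dy_e[:, 1:])
        dv_dx_e = np.diff(v, axis=1) / dx
        dv_dx_c = 0.5 * (dv_dx_e[:-1, :] + dv_dx_e[1:, :])

        def to_nodes(e: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
            acc = np.zeros(shape)
            cnt = np.zeros(shape)
            for oy in (0, 1):
                for ox in (0, 1):
                    sl = (slice(oy, e.shape[0] + oy), slice(ox, e.shape[1] + ox))
                    good = np.isfinite(e)
                    acc[sl] += np.where(good, e, 0.0)
                    cnt[sl] += good
            with np.errstate(invalid="ignore"):
                return np.where(cnt > 0, acc / cnt, np.nan)

        du_dx = to_nodes(du_dx_c, u.shape)
        dv_dy = to_nodes(dv_dy_c, u.shape)
        du_dy = to_nodes(du_dy_c, u.shape)
        dv_dx = to_nodes(dv_dx_c, u.shape)
    else:
        raise ValueError(f"unknown strain method {method!r}")

    eps11, eps22 = du_dx, dv_dy
    eps12 = 0.5 * (du_dy + dv_dx)
    valid = (np.isfinite(eps11) & np.isfinite(eps22) & np.isfinite(eps12)
             & field.valid_mask)
    return StrainField(grid_x=field.grid_x, grid_y=field.grid_y,
                       eps11=eps11, eps22=eps22, eps12=eps12,
                       valid_mask=valid, plane_strain=True)


def hooke_stress(strain: StrainField, params: ElasticParams) -> StressField:
    """Plane-strain generalized Hooke's law applied pointwise.

    With eps_33 = eps_13 = eps_23 = 0, the trace is eps_kk = eps11 + eps22;
    sigma_33 = lambda * eps_kk is nonzero and carried along for the
    principal-stress eigenproblem.  Singular (rejected) at v = 0.5.
    """
    if params.v >= 0.5:
        raise ValueError(
            "plane-strain Hooke's law is singular at v = 0.5 (incompressible "
            "limit); use v < 0.5")
    two_mu = params.E / (1 + params.v)            # E/(1+v) = 2*mu
    lam = params.lame_lambda
    trace = strain.eps11 + strain.eps22
    s11 = two_mu * strain.eps11 + lam * trace
    s22 = two_mu * strain.eps22 + lam * trace
    s12 = two_mu * strain.eps12
    s33 = lam * trace
    return StressField(grid_x=strain.grid_x, grid_y=strain.grid_y,
                       sigma11=s11, sigma22=s22, sigma12=s12, sigma33=s33,
                       valid_mask=strain.valid_mask, params=params)


def principal_stress(stress: StressField,
                     include_sigma33: bool = True) -> tuple[np.ndarray, float]:
    """Maximum principal stress per node and its field-wide maximum (Pa).

    Eigenvalues of [[s11, s12, 0], [s12, s22, 0], [0, 0, s33]]: the in-plane
    pair (s11+s22)/2 +- sqrt(((s11-s22)/2)^2 + s12^2) plus s33 (included by
    default; plane strain makes it nonzero).
    """
    mean = 0.5 * (stress.sigma11 + stress.sigma22)
    radius = np.sqrt((0.5 * (stress.sigma11 - stress.sigma22)) ** 2
                     + stress.sigma12 ** 2)
    p_in = mean + radius
    pmax = np.maximum(p_in, stress.sigma33) if include_sigma33 else p_in
    stress.principal_max = pmax
    if not stress.valid_mask.any():
        raise ValueError("no valid nodes in stress field")
    return pmax, float(np.nanmax(pmax[stress.valid_mask]))
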