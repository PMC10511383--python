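"""Modified one-term Ogden hyperelastic model.

The strain energy is split into an isochoric and a volumetric part,

    Psi_iso = (2 mu / alpha^2) * (lb1^alpha + lb2^alpha + lb3^alpha - 3),
    Psi_vol = (kappa / 4) * (J^2 - 1 - 2 ln J),

with isochoric principal stretches ``lb_a = J^(-1/3) * lambda_a`` and the
bulk modulus tied to the shear modulus through the linear-elastic relation
``kappa = mu * 2(1+nu) / (3(1-2nu))``.  The Cauchy stress follows in spectral
form from the eigenstructure of the left Cauchy-Green tensor ``b = F F^T``.

A negative nonlinearity parameter ``alpha`` produces the pronounced
compression-tension asymmetry characteristic of brain tissue.

All quantities are SI (m, N, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InvalidParameterError",
    "NumericalEvaluationError",
    "OracleFailureError",
    "OgdenParameters",
    "Kinematics",
    "StressState",
    "bulk_modulus",
    "strain_energy",
    "cauchy_stress",
    "material_tangent",
    "first_piola_tangent",
    "homogeneous_uniaxial",
    "homogeneous_uniaxial_incompressible",
    "homogeneous_simple_shear",
    "apparent_torsion_stress",
]

#: smallest admissible |alpha|; the energy is singular at alpha = 0
ALPHA_MIN_DEFAULT = 0.1

#: relative spread below which two principal stretches are treated as coincident
_EIG_COINCIDENCE_RTOL = 1e-7
#: relative perturbation applied to coincident stretches before tangent assembly
_EIG_PERTURBATION = 1e-8


class InvalidParameterError(ValueError):
    """Material parameters outside their admissible range."""


class NumericalEvaluationError(FloatingPointError):
    """A constitutive evaluation produced non-finite values."""


class OracleFailureError(RuntimeError):
    """A closed-form/root-finding oracle failed to converge."""


def bulk_modulus(mu: float, nu: float) -> float:
    """Bulk modulus from shear modulus and initial Poisson's ratio.

    ``kappa = mu * 2(1+nu) / (3(1-2nu))``, taken from the linear elastic
    regime; diverges monotonically as ``nu -> 0.5`` (incompressible limit).
    """
    if mu <= 0.0:
        raise InvalidParameterError(f"shear modulus must be positive, got mu={mu}")
    if not 0.0 <= nu < 0.5:
        raise InvalidParameterError(
            f"Poisson's ratio must lie in [0, 0.5); nu={nu} "
            "(nu = 0.5 is the incompressible limit, kappa -> inf)"
        )
    return mu * 2.0 * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))


@dataclass(frozen=True)
class OgdenParameters:
    """Material parameter vector m = (mu, alpha) with fixed nu and derived kappa.

    Parameters
    ----------
    mu : float
        Shear modulus in Pa, > 0.
    alpha : float
        Dimensionless nonlinearity parameter, |alpha| >= `alpha_min`.
        Negative values make compression stiffer than tension.
    nu : float
        Initial Poisson's ratio in [0, 0.5); only used to derive kappa.
    alpha_min : float
        Configured lower bound on |alpha| (energy singular at alpha = 0).
    """

    mu: float
    alpha: float
    nu: float = 0.45
    alpha_min: float = ALPHA_MIN_DEFAULT
    kappa: float = field(init=False)

    def __post_init__(self) -> None:
        if abs(self.alpha) < self.alpha_min:
            raise InvalidParameterError(
                f"|alpha| must be >= {self.alpha_min}, got alpha={self.alpha}"
            )
        object.__setattr__(self, "kappa", bulk_modulus(self.mu, self.nu))

    def to_dict(self) -> dict:
        return {
            "mu_Pa": self.mu,
            "alpha": self.alpha,
            "nu": self.nu,
            "kappa_Pa": self.kappa,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OgdenParameters":
        p = cls(mu=d["mu_Pa"], alpha=d["alpha"], nu=d["nu"])
        if "kappa_Pa" in d and not np.isclose(d["kappa_Pa"], p.kappa, rtol=1e-9):
            raise InvalidParameterError(
                f"stored kappa={d['kappa_Pa']} inconsistent with mu, nu "
                f"(re-derived kappa={p.kappa})"
            )
        return p


@dataclass(frozen=True)
class Kinematics:
    """Spectral kinematic data of a deformation gradient F.

    Holds J = det F, the left Cauchy-Green tensor b = F F^T, the principal
    stretches (descending), the isochoric stretches J^(-1/3) lambda_a and the
    orthonormal eigenvectors of b (columns of ``n_hat``).
    """

    F: np.ndarray
    J: float = field(init=False)
    b: np.ndarray = field(init=False)
    lambda_a: np.ndarray = field(init=False)
    lambda_bar_a: np.ndarray = field(init=False)
    n_hat: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError(f"deformation gradient must be 3x3, got {F.shape}")
        object.__setattr__(self, "F", F)
        J = float(np.linalg.det(F))
        if not np.isfinite(J) or J <= 0.0:
            raise NumericalEvaluationError(f"det F must be positive, got J={J}")
        b = F @ F.T
        eigval, eigvec = np.linalg.eigh(b)
        # eigh returns ascending; store descending stretches
        order = np.argsort(eigval)[::-1]
        lam = np.sqrt(np.clip(eigval[order], 0.0, None))
        vec = eigvec[:, order]
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "lambda_a", lam)
        object.__setattr__(self, "lambda_bar_a", lam * J ** (-1.0 / 3.0))
        object.__setattr__(self, "n_hat", vec)


@dataclass(frozen=True)
class StressState:
    """Cauchy stress with its spectral isochoric/volumetric decomposition."""

    sigma: np.ndarray
    sigma_iso_a: np.ndarray
    p_vol: float


# ---------------------------------------------------------------------------
# batched core (shared with the FE solver): arrays of quadrature-point states
# ---------------------------------------------------------------------------

def _spectral_data(F: np.ndarray):
    """Eigen-data of b = F F^T for a batch of deformation gradients.

    Parameters: F with shape (..., 3, 3).  Returns (J, lam, vec) with lam
    descending along the last axis and vec the matching eigenvector columns.
    """
    J = np.linalg.det(F)
    b = F @ np.swapaxes(F, -1, -2)
    eigval, eigvec = np.linalg.eigh(b)
    # descending order
    eigval = eigval[..., ::-1]
    eigvec = eigvec[..., ::-1]
    lam = np.sqrt(np.clip(eigval, 0.0, None))
    return J, lam, eigvec


def _principal_stresses(J, lam, p: OgdenParameters):
    """Principal isochoric Cauchy stresses and volumetric pressure (batched).

    sigma_iso_a = (2 mu / (alpha J)) * (lb_a^alpha - mean(lb^alpha)),
    p_vol       = (kappa / 2) * (J - 1/J)     [= J^-1 * J dPsi_vol/dJ].
    """
    lb = lam * J[..., None] ** (-1.0 / 3.0)
    lb_a = lb ** p.alpha
    sig_iso = (2.0 * p.mu / (p.alpha * J[..., None])) * (
        lb_a - lb_a.mean(axis=-1, keepdims=True)
    )
    p_vol = 0.5 * p.kappa * (J - 1.0 / J)
    return sig_iso, p_vol


def _cauchy_batch(F: np.ndarray, p: OgdenParameters) -> np.ndarray:
    """Cauchy stress tensors for a batch of deformation gradients."""
    J, lam, vec = _spectral_data(F)
    sig_iso, p_vol = _principal_stresses(J, lam, p)
    sig_a = sig_iso + p_vol[..., None]
    # sigma = sum_a sig_a n_a (x) n_a
    return np.einsum("...a,...ia,...ja->...ij", sig_a, vec, vec)


def _perturb_coincident(lam: np.ndarray) -> np.ndarray:
    """Split coincident principal stretches by a tiny relative perturbation.

    Guarantees finite off-diagonal tangent coefficients; the induced error in
    the tangent is O(1e-8) relative, far below Newton's needs.
    """
    lam = lam.copy()
    scale = lam.mean(axis=-1, keepdims=True)
    shifts = np.array([0.0, 1.0, 2.0]) * _EIG_PERTURBATION
    for a in range(3):
        for b in range(a + 1, 3):
            close = np.abs(lam[..., a] - lam[..., b]) < (
                _EIG_COINCIDENCE_RTOL * scale[..., 0]
            )
            lam[..., b] = np.where(close, lam[..., b] * (1.0 - shifts[b]), lam[..., b])
    return lam


def _spatial_tangent_batch(F: np.ndarray, p: OgdenParameters):
    """Spatial elasticity tensor c (batched) plus the matching Cauchy stress.

    Principal-stretch form for isotropic hyperelasticity (with Kirchhoff
    principal values ``tau_a`` and ``D_ab = d tau_a / d ln(lambda_b)``):

        J c = sum_ab (D_ab - 2 tau_a delta_ab) n_a (x) n_a (x) n_b (x) n_b
            + sum_{a != b} g_ab (n_a (x) n_b (x) n_a (x) n_b
                                 + n_a (x) n_b (x) n_b (x) n_a),
        g_ab = (tau_a lam_b^2 - tau_b lam_a^2) / (lam_a^2 - lam_b^2).

    This is the tangent conjugate to the updated-Lagrangian weak form, i.e.
    the stiffness is ``grad N : (c + I (x) sigma_geo) : grad N``.
    Returns (c, sigma) with shapes (..., 3,3,3,3) and (..., 3,3).
    """
    J, lam0, vec = _spectral_data(F)

    def _kirchhoff(lam):
        lb_a = (lam * J[..., None] ** (-1.0 / 3.0)) ** p.alpha
        S = lb_a.sum(axis=-1, keepdims=True)
        tau = (2.0 * p.mu / p.alpha) * (lb_a - S / 3.0) + (
            0.5 * p.kappa * (J**2 - 1.0)
        )[..., None]
        return lb_a, S, tau

    # stress from the exact stretches; tangent coefficients from stretches
    # with coincident pairs split (finite g_ab below)
    _, _, tau0 = _kirchhoff(lam0)
    sigma = np.einsum(
        "...a,...ia,...ja->...ij", tau0 / J[..., None], vec, vec
    )
    lam = _perturb_coincident(lam0)
    lb_a, S, tau = _kirchhoff(lam)

    # D_ab = d tau_a / d eps_b,  eps = ln lambda
    eye = np.eye(3)
    D_iso = 2.0 * p.mu * (
        lb_a[..., :, None] * eye
        - lb_a[..., :, None] / 3.0
        - lb_a[..., None, :] / 3.0
        + S[..., None] / 9.0
    )
    D = D_iso + (p.kappa * J**2)[..., None, None]

    lam2 = lam**2
    num = tau[..., :, None] * lam2[..., None, :] - tau[..., None, :] * lam2[..., :, None]
    den = lam2[..., :, None] - lam2[..., None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(np.abs(den) > 0.0, num / np.where(den == 0.0, 1.0, den), 0.0)

    Jc_diag = D - 2.0 * tau[..., :, None] * eye
    n = vec  # columns n[..., i, a]

    naa = np.einsum("...ia,...ja->...aij", n, n)  # n_a (x) n_a
    c = np.einsum("...ab,...aij,...bkl->...ijkl", Jc_diag, naa, naa)

    nab = np.einsum("...ia,...jb->...abij", n, n)  # n_a (x) n_b
    off = np.einsum("...ab,...abij,...abkl->...ijkl", g, nab, nab) + np.einsum(
        "...ab,...abij,...bakl->...ijkl", g, nab, nab
    )
    # the a == b entries of g are zero, so the full sum equals sum_{a != b}
    c = (c + off) / J[..., None, None, None, None]
    return c, sigma


# ---------------------------------------------------------------------------
# single-state public API
# ---------------------------------------------------------------------------

def strain_energy(kin: Kinematics, p: OgdenParameters) -> tuple[float, float]:
    """Isochoric and volumetric strain-energy densities (Pa).

    Both are non-negative, vanishing only at the undeformed reference
    (lb = (1,1,1) resp. J = 1).
    """
    lb = kin.lambda_bar_a
    psi_iso = (2.0 * p.mu / p.alpha**2) * (np.sum(lb**p.alpha) - 3.0)
    J = kin.J
    psi_vol = 0.25 * p.kappa * (J**2 - 1.0 - 2.0 * np.log(J))
    return float(psi_iso), float(psi_vol)


def cauchy_stress(kin: Kinematics, p: OgdenParameters) -> StressState:
    """Cauchy stress in spectral form.

    sigma = sum_a (sigma_iso_a + p_vol) n_a (x) n_a, with the isochoric
    principal values summing to zero (deviatoric) and the volumetric pressure
    p_vol = (kappa/2)(J - 1/J).
    """
    J = np.array(kin.J)
    lam = kin.lambda_a[None, :]
    sig_iso, p_vol = _principal_stresses(J[None], lam, p)
    sig_iso = sig_iso[0]
    p_vol = float(p_vol[0])
    sig_a = sig_iso + p_vol
    sigma = np.einsum("a,ia,ja->ij", sig_a, kin.n_hat, kin.n_hat)
    if not np.all(np.isfinite(sigma)):
        raise NumericalEvaluationError(
            f"non-finite Cauchy stress at principal stretches {kin.lambda_a}"
        )
    return StressState(sigma=sigma, sigma_iso_a=sig_iso, p_vol=p_vol)


def material_tangent(kin: Kinematics, p: OgdenParameters) -> np.ndarray:
    """Fourth-order spatial elasticity tensor c at the given state.

    Possesses minor and major symmetries; together with the geometric
    (initial-stress) term it is the consistent tangent of the
    updated-Lagrangian internal-force vector.  Coincident principal
    stretches are handled by a tiny spectral perturbation.
    """
    c, _ = _spatial_tangent_batch(kin.F[None], p)
    return c[0]


def first_piola_tangent(kin: Kinematics, p: OgdenParameters) -> np.ndarray:
    """Referential tangent A_iJkL = dP_iJ / dF_kL reconstructed from c.

    A_iJkL = delta_ik S_JL + J F^-T_Jj (c_ijkl) F^-T_Ll with S the second
    Piola-Kirchhoff stress; used as the bridge for finite-difference
    consistency checks of the spatial tangent.
    """
    c = material_tangent(kin, p)
    sigma = cauchy_stress(kin, p).sigma
    Finv = np.linalg.inv(kin.F)
    J = kin.J
    S = J * Finv @ sigma @ Finv.T
    A = np.einsum("ik,JL->iJkL", np.eye(3), S) + J * np.einsum(
        "Jj,ijkl,Ll->iJkL", Finv, c, Finv
    )
    return A


# ---------------------------------------------------------------------------
# homogeneous-deformation oracles
# ---------------------------------------------------------------------------

def _uniaxial_radial_stress(lam_r: float, lam_z: float, p: OgdenParameters) -> float:
    F = np.diag([lam_r, lam_r, lam_z])
    return float(_cauchy_batch(F[None], p)[0, 0, 0])


def homogeneous_uniaxial(lambda_z: float, p: OgdenParameters) -> float:
    """Nominal axial stress P (Pa) for homogeneous (slipping) uniaxial loading.

    Solves the lateral stretch lam_r from vanishing radial Cauchy stress
    (compressible case, 1-D bracketing root find) and returns
    P = sigma_zz * lam_r^2 (force per undeformed area).
    """
    if lambda_z <= 0.0:
        raise InvalidParameterError(f"stretch must be positive, got {lambda_z}")
    if lambda_z == 1.0:
        return 0.0
    # bracket around the incompressible guess lam_r = lambda_z^(-1/2)
    guess = lambda_z**-0.5
    lo, hi = 0.25 * guess, 4.0 * guess
    flo = _uniaxial_radial_stress(lo, lambda_z, p)
    fhi = _uniaxial_radial_stress(hi, lambda_z, p)
    for _ in range(8):
        if flo * fhi < 0.0:
            break
        lo *= 0.5
        hi *= 2.0
        flo = _uniaxial_radial_stress(lo, lambda_z, p)
        fhi = _uniaxial_radial_stress(hi, lambda_z, p)
    else:
        raise OracleFailureError(
            f"could not bracket lateral stretch for lambda_z={lambda_z}"
        )
    lam_r = brentq(
        _uniaxial_radial_stress, lo, hi, args=(lambda_z, p), xtol=1e-14, rtol=1e-14
    )
    F = np.diag([lam_r, lam_r, lambda_z])
    sigma_zz = float(_cauchy_batch(F[None], p)[0, 2, 2])
    return sigma_zz * lam_r**2


def homogeneous_uniaxial_incompressible(lambda_z: float, p: OgdenParameters) -> float:
    """Incompressible-limit closed form P = (2 mu/alpha)(lam^(a-1) - lam^(-a/2-1))."""
    a = p.alpha
    return (2.0 * p.mu / a) * (lambda_z ** (a - 1.0) - lambda_z ** (-a / 2.0 - 1.0))


def homogeneous_simple_shear(gamma, p: OgdenParameters):
    """Shear stress sigma_12 (Pa) for simple shear F = I + gamma e1 (x) e2.

    Odd in gamma; sigma_12 / gamma -> mu as gamma -> 0.  Accepts scalars or
    arrays of shear amounts.
    """
    g = np.atleast_1d(np.asarray(gamma, dtype=float))
    F = np.tile(np.eye(3), (g.size, 1, 1))
    F[:, 0, 1] = g
    tau = _cauchy_batch(F, p)[:, 0, 1]
    return tau if np.ndim(gamma) else float(tau[0])


def apparent_torsion_stress(gamma_outer, p: OgdenParameters, n_quad: int = 16):
    """Rheometer apparent shear stress tau = 2t/(pi r^3) for cylinder torsion.

    Treats each radius as locally simple-sheared with gamma(rho) =
    rho/r * gamma_outer (thin-shell reduction of the torsion test) and
    integrates the torque over the cross-section:

        tau_app = 4 * int_0^1 s^2 sigma_12(s * gamma_outer) ds.

    Independent of the specimen radius; reduces to mu * gamma_outer in the
    linear limit.  Odd in gamma_outer.
    """
    g = np.atleast_1d(np.asarray(gamma_outer, dtype=float))
    s, w = np.polynomial.legendre.leggauss(n_quad)
    s = 0.5 * (s + 1.0)  # map to (0, 1)
    w = 0.5 * w
    loc = g[:, None] * s[None, :]
    tau_loc = homogeneous_simple_shear(loc.ravel(), p).reshape(loc.shape)
    tau_app = 4.0 * np.einsum("gq,q,q->g", tau_loc, s**2, w)
    return tau_app if np.ndim(gamma_outer) else float(tau_app[0])
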