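"""Unit and property tests of the one-term Ogden constitutive model."""

import numpy as np
import pytest

from ogdenfit.constitutive import (
    InvalidParameterError,
    Kinematics,
    OgdenParameters,
    apparent_torsion_stress,
    bulk_modulus,
    cauchy_stress,
    first_piola_tangent,
    homogeneous_simple_shear,
    homogeneous_uniaxial,
    homogeneous_uniaxial_incompressible,
    material_tangent,
    strain_energy,
)


def random_deformation(rng, scale=0.2):
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            return F


# ---------------------------------------------------------------------- kappa

@pytest.mark.parametrize(
    "mu, nu, expected",
    [(300.0, 0.45, 2900.0), (300.0, 0.49, 14900.0), (1.0, 0.25, 5.0 / 3.0)],
)
def test_bulk_modulus_values(mu, nu, expected):
    assert bulk_modulus(mu, nu) == pytest.approx(expected, rel=1e-12)


def test_bulk_modulus_diverges_toward_incompressibility():
    nus = [0.4, 0.45, 0.49, 0.499]
    kappas = [bulk_modulus(100.0, nu) for nu in nus]
    assert np.all(np.diff(kappas) > 0)


@pytest.mark.parametrize("mu, nu", [(-1.0, 0.45), (100.0, 0.5), (100.0, 0.6)])
def test_invalid_parameters_rejected(mu, nu):
    with pytest.raises(InvalidParameterError):
        bulk_modulus(mu, nu)


def test_alpha_bounded_away_from_zero():
    with pytest.raises(InvalidParameterError):
        OgdenParameters(mu=100.0, alpha=0.05)


def test_parameter_roundtrip_checks_kappa():
    p = OgdenParameters(mu=300.0, alpha=-18.0, nu=0.45)
    q = OgdenParameters.from_dict(p.to_dict())
    assert q.kappa == pytest.approx(p.kappa)
    bad = p.to_dict()
    bad["kappa_Pa"] *= 1.5
    with pytest.raises(InvalidParameterError):
        OgdenParameters.from_dict(bad)


# --------------------------------------------------------------------- energy

def test_strain_energy_reference_state():
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    psi_iso, psi_vol = strain_energy(Kinematics(F=np.eye(3)), p)
    assert psi_iso == pytest.approx(0.0, abs=1e-12)
    assert psi_vol == pytest.approx(0.0, abs=1e-12)


def test_strain_energy_isochoric_closed_form():
    # lambda_bar = (1.2, 1/1.2, 1) at J = 1
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    F = np.diag([1.2, 1.0 / 1.2, 1.0])
    psi_iso, psi_vol = strain_energy(Kinematics(F=F), p)
    expected = (2 * 100 / 400.0) * (1.2**-20 + 1.2**20 + 1.0 - 3.0)
    assert psi_iso == pytest.approx(expected, rel=1e-12)
    assert psi_vol == pytest.approx(0.0, abs=1e-8)


def test_strain_energy_volumetric_closed_form():
    p = OgdenParameters(mu=300.0, alpha=-18.0, nu=0.45)
    kappa = p.kappa
    F = 1.1 ** (1.0 / 3.0) * np.eye(3)  # J = 1.1, lambda_bar = 1
    psi_iso, psi_vol = strain_energy(Kinematics(F=F), p)
    assert psi_vol == pytest.approx(
        kappa * 0.25 * (1.1**2 - 1 - 2 * np.log(1.1)), rel=1e-10
    )
    assert psi_iso == pytest.approx(0.0, abs=1e-10)


def test_strain_energy_nonnegative_random_states(rng):
    p = OgdenParameters(mu=150.0, alpha=-12.0, nu=0.49)
    for _ in range(50):
        psi_iso, psi_vol = strain_energy(Kinematics(F=random_deformation(rng)), p)
        assert psi_iso >= 0.0 and psi_vol >= 0.0


# --------------------------------------------------------------------- stress

def test_stress_free_reference():
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    s = cauchy_stress(Kinematics(F=np.eye(3)), p)
    assert np.allclose(s.sigma, 0.0, atol=1e-12)


def test_small_shear_modulus_limit():
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.49)
    gamma = 1e-4
    F = np.eye(3)
    F[0, 1] = gamma
    s = cauchy_stress(Kinematics(F=F), p)
    assert s.sigma[0, 1] / gamma == pytest.approx(100.0, rel=1e-3)


def test_stress_matches_energy_derivative(rng):
    """sigma = J^-1 dPsi/dF F^T checked by central differences."""
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)

    def psi(F):
        k = Kinematics(F=F)
        a, b = strain_energy(k, p)
        return a + b

    for _ in range(10):
        F = random_deformation(rng)
        dPsi = np.zeros((3, 3))
        h = 1e-6
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                dPsi[i, j] = (psi(Fp) - psi(Fm)) / (2 * h)
        sig_fd = dPsi @ F.T / np.linalg.det(F)
        sig = cauchy_stress(Kinematics(F=F), p).sigma
        assert np.max(np.abs(sig - sig_fd)) < 1e-5 * np.max(np.abs(sig))


def test_objectivity(rng):
    """sigma(QF) = Q sigma(F) Q^T for random rotations."""
    from scipy.stats import special_ortho_group

    p = OgdenParameters(mu=100.0, alpha=-15.0, nu=0.45)
    qrng = np.random.default_rng(42)
    for _ in range(100):
        F = random_deformation(rng)
        Q = special_ortho_group.rvs(3, random_state=qrng)
        s1 = cauchy_stress(Kinematics(F=Q @ F), p).sigma
        s2 = Q @ cauchy_stress(Kinematics(F=F), p).sigma @ Q.T
        assert np.max(np.abs(s1 - s2)) < 1e-10 * max(np.max(np.abs(s2)), 1.0)


def test_isochoric_stresses_are_deviatoric(rng):
    p = OgdenParameters(mu=200.0, alpha=-20.0, nu=0.45)
    for _ in range(1000):
        F = random_deformation(rng, scale=0.15)
        s = cauchy_stress(Kinematics(F=F), p)
        assert abs(s.sigma_iso_a.sum()) < 1e-8 * max(np.abs(s.sigma_iso_a).max(), 1.0)


def test_stress_symmetry(rng):
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.49)
    for _ in range(50):
        s = cauchy_stress(Kinematics(F=random_deformation(rng)), p).sigma
        assert np.max(np.abs(s - s.T)) < 1e-10 * np.max(np.abs(s))


# -------------------------------------------------------------------- tangent

def _fd_piola_tangent(F, p, h=1e-6):
    def piola(F):
        k = Kinematics(F=F)
        return k.J * cauchy_stress(k, p).sigma @ np.linalg.inv(F).T

    A = np.zeros((3, 3, 3, 3))
    for k in range(3):
        for L in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[k, L] += h
            Fm[k, L] -= h
            A[:, :, k, L] = (piola(Fp) - piola(Fm)) / (2 * h)
    return A


def test_tangent_linearizes_to_elastic_moduli():
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    c = material_tangent(Kinematics(F=np.eye(3)), p)
    assert c[0, 1, 0, 1] == pytest.approx(p.mu, rel=1e-6)
    assert (c[0, 0, 0, 0] + 2 * c[0, 0, 1, 1]) / 3 == pytest.approx(p.kappa, rel=1e-6)


def test_tangent_symmetries(rng):
    p = OgdenParameters(mu=100.0, alpha=-15.0, nu=0.49)
    for _ in range(5):
        c = material_tangent(Kinematics(F=random_deformation(rng)), p)
        scale = np.max(np.abs(c))
        assert np.max(np.abs(c - c.transpose(1, 0, 2, 3))) < 1e-8 * scale
        assert np.max(np.abs(c - c.transpose(0, 1, 3, 2))) < 1e-8 * scale
        assert np.max(np.abs(c - c.transpose(2, 3, 0, 1))) < 1e-8 * scale


@pytest.mark.parametrize(
    "F",
    [
        None,  # random, distinct stretches
        np.diag([1.1, 1.1, 0.9]),  # two coincident stretches
        1.05 * np.eye(3),  # three coincident stretches
    ],
)
def test_tangent_finite_difference_consistency(F, rng):
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    if F is None:
        F = random_deformation(rng)
    A = first_piola_tangent(Kinematics(F=F), p)
    A_fd = _fd_piola_tangent(F, p)
    assert np.max(np.abs(A - A_fd)) < 1e-5 * np.max(np.abs(A_fd))


# -------------------------------------------------------------------- oracles

def test_uniaxial_reference():
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    assert homogeneous_uniaxial(1.0, p) == 0.0


def test_uniaxial_matches_incompressible_limit():
    """Compressible solve at nu=0.4999 approaches the closed form."""
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.4999)
    closed = homogeneous_uniaxial_incompressible(0.85, p)
    assert closed == pytest.approx((2 * 100 / -20.0) * (0.85**-21 - 0.85**9), rel=1e-12)
    assert homogeneous_uniaxial(0.85, p) == pytest.approx(closed, rel=5e-3)
    assert homogeneous_uniaxial(1.15, p) == pytest.approx(
        homogeneous_uniaxial_incompressible(1.15, p), rel=5e-3
    )


def test_uniaxial_small_strain_youngs_modulus():
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    slope = (homogeneous_uniaxial(1.001, p) - homogeneous_uniaxial(0.999, p)) / 0.002
    assert slope == pytest.approx(2 * 100 * 1.45, rel=5e-3)


def test_compression_tension_asymmetry():
    """alpha < 0 makes compression much stiffer than tension."""
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.4999)
    assert abs(homogeneous_uniaxial(0.85, p)) > abs(homogeneous_uniaxial(1.15, p))


def test_simple_shear_odd_and_limit():
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    assert homogeneous_simple_shear(0.0, p) == 0.0
    assert homogeneous_simple_shear(0.2, p) == pytest.approx(
        -homogeneous_simple_shear(-0.2, p), rel=1e-12
    )
    assert homogeneous_simple_shear(1e-6, p) / 1e-6 == pytest.approx(100.0, rel=1e-4)


def test_simple_shear_spectral_oracle():
    """sigma_12 at gamma=0.3 against an independent eigen-decomposition."""
    gamma, mu, alpha = 0.3, 100.0, -20.0
    p = OgdenParameters(mu=mu, alpha=alpha, nu=0.45)
    # principal in-plane stretches of simple shear: lam = g/2 + sqrt(1+g^2/4)
    lam1 = gamma / 2 + np.sqrt(1 + gamma**2 / 4)
    lam2 = 1.0 / lam1
    beta = lambda lam: (2 * mu / alpha) * (lam**alpha - (lam1**alpha + lam2**alpha + 1) / 3)
    # eigenvectors of b in the shear plane
    F = np.eye(3)
    F[0, 1] = gamma
    b = F @ F.T
    w, v = np.linalg.eigh(b[:2, :2])
    sig12 = sum(
        beta(np.sqrt(wi)) * vi[0] * vi[1] for wi, vi in zip(w, v.T)
    )
    assert homogeneous_simple_shear(gamma, p) == pytest.approx(sig12, rel=1e-10)


def test_apparent_torsion_linear_limit_and_oddness():
    p = OgdenParameters(mu=100.0, alpha=-20.0, nu=0.45)
    assert apparent_torsion_stress(1e-5, p) / 1e-5 == pytest.approx(100.0, rel=1e-4)
    assert apparent_torsion_stress(0.3, p) == pytest.approx(
        -apparent_torsion_stress(-0.3, p), rel=1e-12
    )
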