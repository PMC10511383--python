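"""Synthetic rheometer recordings and cohorts with known ground truth.

The generator emulates the multi-modal testing protocol: three cycles of
compression/tension between stretches 0.85 and 1.15, followed by two
three-cycle torsion blocks to amounts of shear 0.15 and 0.3.  The
hyperelastic response of a chosen ground-truth parameter set is turned into
a cyclic signal with

* multiplicative hysteresis: loading branch (1 + h_c w) x signal, unloading
  branch (1 - h_c w) x signal with the window w = sin(pi xi) over the branch
  progress xi, so the loop closes at the reversal points and the branch
  average recovers the hyperelastic curve exactly - the averaging assumption
  of the preprocessing stage holds by construction on synthetic data;
* cycle-to-cycle softening (preconditioning): cycles 1 and 3 are scaled by
  the constant factors 1 and s; the transition happens smoothly across the
  (never extracted) second cycle so that both used cycles stay exact;
* additive i.i.d. Gaussian measurement noise on the recorded force/torque,
  specified as a stress-scale standard deviation (Pa) and/or a relative
  (multiplicative) fraction.

Driver signals are sampled on grids aligned with the 60-point resampling
grid of the preprocessing stage (an integer number of samples per grid
interval), which makes the noiseless round trip exact to floating-point
precision rather than to resampling accuracy.

Cohorts add region effects (multiplicative on mu), brain-level random
effects (log-normal on mu, additive on alpha) and specimen scatter, and
return a ground-truth table for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import (
    OgdenParameters,
    apparent_torsion_stress,
    homogeneous_uniaxial,
)
from .fe import SpecimenGeometry, simulate_axial_test
from .preprocess import MODES, RawRecording, SpecimenRecord
from .stats import GOVERNING_REGIONS

__all__ = ["SyntheticConfig", "CohortSpec", "simulate_raw_recording", "generate_cohort"]

#: protocol amplitudes: axial stretch window and the two torsion sweeps
LAMBDA_RANGE = (0.85, 1.15)
GAMMA_MAX = {"shear_015": 0.15, "shear_030": 0.30}

#: axial crosshead speed (m/s) used to lay out the time axis
LOADING_VELOCITY = 40e-6


@dataclass
class SyntheticConfig:
    """Ground truth and disturbance model for one synthetic specimen.

    ``hysteresis`` gives the per-cycle branch split h_c (h_1 > h_3 >= 0);
    ``softening`` scales the cycle-3 response (s = 1: no preconditioning).
    ``noise_std_pa`` is additive noise on the stress scale; ``noise_rel`` a
    multiplicative noise fraction.  ``forward`` chooses the curve generator:
    the homogeneous closed forms (fast, default) or the glued-end FE model.

    ``shear_scale`` scales the torsion responses relative to the axial one.
    At 1 (default) the three modes are exactly consistent with one
    parameter set; values < 1 emulate the systematic feature of measured
    brain-tissue data that the one-term model over-predicts the shear
    stresses relative to compression, so no single (mu, alpha) fits all
    modes exactly.
    """

    mu: float = 250.0
    alpha: float = -18.0
    nu: float = 0.45
    geometry: SpecimenGeometry = field(default_factory=SpecimenGeometry)
    hysteresis: tuple[float, float, float] = (0.25, 0.2, 0.15)
    softening: float = 0.85
    noise_std_pa: float = 2.0
    noise_rel: float = 0.0
    shear_scale: float = 1.0
    sampling_hz: float = 10.0
    n_cycles: int = 3
    forward: str = "homogeneous"
    fe_refinement: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.hysteresis):
            raise ValueError("hysteresis factors must be >= 0")
        if not 0.0 < self.softening <= 1.0:
            raise ValueError("softening must lie in (0, 1]")
        if self.noise_std_pa < 0 or self.noise_rel < 0:
            raise ValueError("noise levels must be >= 0")
        if self.shear_scale <= 0:
            raise ValueError("shear_scale must be > 0")
        if self.forward not in ("homogeneous", "fe"):
            raise ValueError(f"unknown forward model {self.forward!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def parameters(self) -> OgdenParameters:
        return OgdenParameters(mu=self.mu, alpha=self.alpha, nu=self.nu)

    def cycle_scale(self, cycle: int) -> float:
        """Softening factor of cycle c: linear from 1 (c=1) to s (c=3)."""
        return 1.0 + (self.softening - 1.0) * (cycle - 1) / max(self.n_cycles - 1, 1)


def _stress_at(cfg: SyntheticConfig, mode: str, absc: np.ndarray) -> np.ndarray:
    """Hyperelastic stress of the ground truth, exact at each abscissa.

    The homogeneous forward evaluates the closed forms at every (deduped)
    sample; the FE forward evaluates a 60-point glued curve and
    interpolates, which is accurate to the curve's resolution only.
    """
    p = cfg.parameters()
    if mode == "compression_tension":
        if cfg.forward == "fe":
            lams = np.linspace(LAMBDA_RANGE[0], LAMBDA_RANGE[1], 60)
            crv = simulate_axial_test(
                cfg.geometry, p, "glued", lams, refinement=cfg.fe_refinement
            )
            return np.interp(absc, crv.abscissa, crv.ordinate)
        uniq, inv = np.unique(absc, return_inverse=True)
        vals = np.array([homogeneous_uniaxial(l, p) for l in uniq])
        return vals[inv]
    return apparent_torsion_stress(absc, p)


def _triangle_driver(cfg: SyntheticConfig, mode: str):
    """Driver of one protocol row: lead-in ramp plus n full cycles.

    Axial: dz sweeps between (0.85 - 1) H and (1.15 - 1) H starting at 0;
    torsion: theta sweeps symmetrically to +/- gamma_max H / r.  Each full
    ramp carries an even multiple of 59 sample intervals so every node of
    the later 60-point resampling grid coincides with a sample; the
    multiplier approximates the requested sampling rate at the configured
    loading velocity.  Returns (time, driver, knot times).
    """
    H, r = cfg.geometry.height, cfg.geometry.radius
    if mode == "compression_tension":
        lo = (LAMBDA_RANGE[0] - 1.0) * H
        hi = (LAMBDA_RANGE[1] - 1.0) * H
        knots = np.array([0.0, lo] + [hi, lo] * cfg.n_cycles + [0.0])
        speed = LOADING_VELOCITY
        span = hi - lo
    else:
        amp = GAMMA_MAX[mode] * H / r
        knots = np.array([0.0, amp] + [-amp, amp] * cfg.n_cycles + [0.0])
        # comparable end rotation rate across the torsion blocks
        speed = LOADING_VELOCITY / H * amp / (GAMMA_MAX[mode] / 0.3)
        span = 2.0 * amp

    ramp_duration = span / speed
    oversample = max(1, int(round(ramp_duration * cfg.sampling_hz / 118.0)))
    per_ramp = 118 * oversample  # intervals per full ramp: 2 x oversample per grid gap

    seg_dur = np.abs(np.diff(knots)) / speed
    t_knots = np.concatenate([[0.0], np.cumsum(seg_dur)])
    t_parts, d_parts = [], []
    for i in range(len(knots) - 1):
        n_i = max(1, int(round(per_ramp * abs(knots[i + 1] - knots[i]) / span)))
        t_parts.append(np.linspace(t_knots[i], t_knots[i + 1], n_i + 1)[:-1])
        d_parts.append(np.linspace(knots[i], knots[i + 1], n_i + 1)[:-1])
    t = np.concatenate(t_parts + [t_knots[-1:]])
    d = np.concatenate(d_parts + [knots[-1:]])
    return t, d, t_knots


def simulate_raw_recording(
    cfg: SyntheticConfig, mode: str, rng: np.random.Generator | None = None
) -> RawRecording:
    """Cyclic raw recording of one loading mode with known ground truth.

    In the noiseless case the loading/unloading averages of cycles 1 and 3
    equal 1 x and ``softening`` x the hyperelastic signal exactly; the
    softening envelope moves between the two values across cycle 2.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    t, driver, t_knots = _triangle_driver(cfg, mode)

    if mode == "compression_tension":
        absc = (geom.height + driver) / geom.height
        to_raw = geom.cross_section  # stress -> force
    else:
        absc = geom.radius * driver / geom.height
        to_raw = np.pi * geom.radius**3 / 2.0  # stress -> torque

    stress = _stress_at(cfg, mode, absc)
    if mode != "compression_tension":
        stress = cfg.shear_scale * stress

    # hysteresis split (1 +/- h_c sin(pi xi)) per branch; the window closes
    # the loop at the reversals, so shared apex samples are unambiguous
    factor = np.ones_like(t)
    n_seg = len(t_knots) - 1
    seg = np.clip(np.searchsorted(t_knots, t, side="right") - 1, 0, n_seg - 1)
    for s in range(n_seg):
        mask = seg == s
        if not mask.any() or s == 0 or s == n_seg - 1:
            continue  # lead-in/out ramps carry no hysteresis split
        cyc = min((s - 1) // 2 + 1, cfg.n_cycles)
        h_sign = 1.0 if (s % 2 == 1) else -1.0
        h = cfg.hysteresis[min(cyc - 1, len(cfg.hysteresis) - 1)]
        xi = (t[mask] - t_knots[s]) / (t_knots[s + 1] - t_knots[s])
        factor[mask] = 1.0 + h_sign * h * np.sin(np.pi * xi)

    # softening envelope: 1 through cycle 1, linear in time across cycle 2,
    # ``softening`` from cycle 3 on (exact on the extracted cycles)
    if cfg.n_cycles >= 3:
        envelope = np.interp(
            t, [t_knots[3], t_knots[2 * cfg.n_cycles - 1]], [1.0, cfg.softening]
        )
    else:
        envelope = np.ones_like(t)

    clean = stress * factor * envelope
    noise = rng.normal(0.0, cfg.noise_std_pa, size=t.size)
    if cfg.noise_rel > 0.0:
        noise = noise + clean * rng.normal(0.0, cfg.noise_rel, size=t.size)
    response = (clean + noise) * to_raw
    return RawRecording(
        mode=mode, time=t, driver=driver, response=response, n_cycles=cfg.n_cycles
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a synthetic study with known regional structure.

    ``region_effects`` multiplies the base shear modulus per governing
    region; ``brain_sigma_log_mu`` and ``brain_sigma_alpha`` set the
    inter-individual random effects; ``specimen_sigma_log_mu`` the residual
    specimen scatter.  ``region_alpha`` optionally makes alpha
    region-specific (additive offsets); by default alpha is shared.
    """

    regions: tuple = GOVERNING_REGIONS
    n_brains: int = 7
    n_per_region_per_brain: int = 1
    mu_base: float = 250.0
    alpha_base: float = -18.0
    nu: float = 0.45
    region_effects: dict = field(default_factory=dict)
    region_alpha: dict = field(default_factory=dict)
    brain_sigma_log_mu: float = 0.25
    brain_sigma_alpha: float = 1.5
    specimen_sigma_log_mu: float = 0.2
    seed: int = 0
    base: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.region_effects.values()):
            raise ValueError("region effects are multiplicative and must be > 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


#: representative anatomical code per governing region (for cohort labels)
_ANATOMICAL_OF = {
    "Am": "Am", "BG": "Pu", "BS": "P", "C": "FC", "CB": "cWM",
    "CC": "CC", "CR": "CR", "Hi": "Hi", "M": "M",
}


def generate_cohort(spec: CohortSpec):
    """Full synthetic study: specimen records plus a ground-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per specimen
    with the exact (mu, alpha, nu) the recordings were generated from.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SpecimenRecord] = []
    truth_rows = []
    for b in range(1, spec.n_brains + 1):
        brain_mu = float(np.exp(rng.normal(0.0, spec.brain_sigma_log_mu)))
        brain_alpha = float(rng.normal(0.0, spec.brain_sigma_alpha))
        for region in spec.regions:
            for k in range(spec.n_per_region_per_brain):
                mu = (
                    spec.mu_base
                    * spec.region_effects.get(region, 1.0)
                    * brain_mu
                    * float(np.exp(rng.normal(0.0, spec.specimen_sigma_log_mu)))
                )
                alpha = spec.alpha_base + spec.region_alpha.get(region, 0.0) + brain_alpha
                sid = f"b{b}_{region}_{k}"
                cfg = SyntheticConfig(
                    mu=mu,
                    alpha=alpha,
                    nu=spec.nu,
                    geometry=spec.base.geometry,
                    hysteresis=spec.base.hysteresis,
                    softening=spec.base.softening,
                    noise_std_pa=spec.base.noise_std_pa,
                    noise_rel=spec.base.noise_rel,
                    shear_scale=spec.base.shear_scale,
                    sampling_hz=spec.base.sampling_hz,
                    forward=spec.base.forward,
                    fe_refinement=spec.base.fe_refinement,
                    seed=int(rng.integers(2**31 - 1)),
                )
                rec = SpecimenRecord(
                    specimen_id=sid,
                    brain_id=b,
                    anatomical_region=_ANATOMICAL_OF.get(region, region),
                    geometry=cfg.geometry,
                )
                sub_rng = np.random.default_rng(cfg.seed)
                for mode in MODES:
                    rec.raw[mode] = simulate_raw_recording(cfg, mode, rng=sub_rng)
                    rec.raw[mode].specimen_id = sid
                records.append(rec)
                truth_rows.append(
                    {
                        "specimen_id": sid,
                        "brain_id": b,
                        "governing_region": region,
                        "mu_true": mu,
                        "alpha_true": alpha,
                        "nu_true": spec.nu,
                        "softening": spec.base.softening,
                    }
                )
    return records, pd.DataFrame(truth_rows)
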