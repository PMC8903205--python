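"""Glottal aerodynamics and the wave-reflection airways.

The subglottal and supraglottal airways are modeled as concatenated
cylindrical sections whose length is half the distance sound travels in
one sample (c / (2 fs) = 0.3968 cm at 44.1 kHz), so forward and backward
pressure waves cross one section per half sample.  Scattering at area
junctions, per-section attenuation (standing in for viscous and wall
losses), an anechoic lung termination carrying the constant lung-pressure
source, and a low-frequency parallel inertance/resistance radiation load at
the mouth complete the waveguide.

The glottis couples the two tubes interactively: the flow solves the
quadratic junction equation combining the kinetic pressure loss
(rho/2)(ug/Ag)^2 with the characteristic impedances of the adjacent
sections.  Surface pressures follow a Bernoulli description up to the
minimum glottal diameter and a non-recovering jet above it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig, DEFAULT_CONFIG, KPA_TO_CGS

__all__ = [
    "Waveguide",
    "load_area_function",
    "glottal_flow",
    "surface_pressures",
    "radiation_filter_coeffs",
]


def load_area_function() -> np.ndarray:
    """Packaged 44-section /a/ supraglottal area function (cm^2)."""
    ref = importlib.resources.files("larynxsim.data") / "areafunction_aa.txt"
    rows = [line.split() for line in ref.read_text().splitlines()
            if line.strip() and not line.startswith("#")]
    return np.array([float(r[1]) for r in rows])


def radiation_filter_coeffs(mouth_area: float, cfg: SimConfig = DEFAULT_CONFIG):
    """First-order digital reflection filter of the mouth radiation load.

    The load is the parallel inertance/resistance low-frequency equivalent
    of the piston-in-baffle radiation impedance, normalized by the
    characteristic impedance of the terminal section and discretized with
    the bilinear transform at the junction update rate (2 fs).  The
    reflection coefficient tends to -1 at DC (open end) and rises toward 0
    at high frequency as radiation becomes efficient.

    Returns (b0, b1, a1) of  B[n] = b0 F[n] + b1 F[n-1] + a1 B[n-1].
    """
    r_star = 128.0 / (9.0 * np.pi ** 2)          # normalized resistance
    a_eff = np.sqrt(mouth_area / np.pi)          # piston radius
    t_l = 8.0 * a_eff / (3.0 * np.pi * cfg.c_air)  # inertance time constant
    dt_half = 1.0 / (2.0 * cfg.fs)
    A1 = (2.0 * t_l / dt_half) * (r_star - 1.0)
    B1 = (2.0 * t_l / dt_half) * (r_star + 1.0)
    den = B1 + r_star
    return (A1 - r_star) / den, -(A1 + r_star) / den, (B1 - r_star) / den


def glottal_flow(Ag: float, p_forward_sub: float, p_backward_supra: float,
                 Zs: float, Ze: float, rho: float) -> float:
    """Glottal volume velocity (cm^3/s) from the interactive junction.

    Solves (rho/2)(ug/Ag)^2 + (Zs + Ze) ug = 2(F_sub - B_supra) for the
    positive root; the flow is rectified at zero and vanishes as Ag -> 0.
    """
    if Ag <= 0.0:
        return 0.0
    c = 2.0 * (p_forward_sub - p_backward_supra)
    if c <= 0.0:
        return 0.0
    a = 0.5 * rho / Ag ** 2
    b = Zs + Ze
    return (-b + np.sqrt(b * b + 4.0 * a * c)) / (2.0 * a)


def surface_pressures(a_z: np.ndarray, ug: float, p_sub: float, p_supra: float,
                      rho: float, area_floor: float = 1.0e-6) -> np.ndarray:
    """Intraglottal pressure profile p(z) over the glottal area function.

    Below the minimum-diameter point the pressure follows an
    energy-conserving Bernoulli drop from the subglottal stagnation
    pressure; at and above the minimum a jet with no pressure recovery
    leaves the surface at the supraglottal pressure.  If the glottis is
    closed somewhere, rows below the lowest closed row see the upstream
    stagnation pressure and rows above see the supraglottal pressure.
    """
    a_z = np.asarray(a_z, dtype=float)
    p = np.empty_like(a_z)
    closed = a_z <= area_floor
    if closed.any():
        j_closed = int(np.argmax(closed))  # lowest closed row
        p[:j_closed] = p_sub
        p[j_closed:] = p_supra
        return p
    j_min = int(np.argmin(a_z))
    p[:] = p_supra
    if j_min > 0:
        p[:j_min] = p_sub - 0.5 * rho * (ug / a_z[:j_min]) ** 2
    return p


@dataclass
class Waveguide:
    """Wave-reflection subglottal + supraglottal airways.

    Forward waves travel toward the mouth.  ``f_sub[-1]`` is the forward
    wave incident on the glottis from below; ``b_sup[0]`` the backward wave
    incident from above.  One ``step(ug)`` advances a full audio sample
    (two half-sample scattering passes) and returns the radiated oral
    pressure sample.
    """

    cfg: SimConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    areas_sub: np.ndarray | None = None
    areas_sup: np.ndarray | None = None
    PL_cgs: float = 0.0

    def __post_init__(self):
        cfg = self.cfg
        if self.areas_sub is None:
            self.areas_sub = np.full(cfg.n_subglottal, cfg.trachea_area_cm2)
        if self.areas_sup is None:
            self.areas_sup = load_area_function()
        self.areas_sub = np.asarray(self.areas_sub, dtype=float)
        self.areas_sup = np.asarray(self.areas_sup, dtype=float)
        rho_c = cfg.rho_air * cfg.c_air
        self.Zs = rho_c / self.areas_sub[-1]
        self.Ze = rho_c / self.areas_sup[0]
        # interior junction reflection coefficients (pressure waves, toward mouth)
        self.r_sub = ((self.areas_sub[:-1] - self.areas_sub[1:])
                      / (self.areas_sub[:-1] + self.areas_sub[1:]))
        self.r_sup = ((self.areas_sup[:-1] - self.areas_sup[1:])
                      / (self.areas_sup[:-1] + self.areas_sup[1:]))
        self.f_sub = np.zeros(len(self.areas_sub))
        self.b_sub = np.zeros(len(self.areas_sub))
        self.f_sup = np.zeros(len(self.areas_sup))
        self.b_sup = np.zeros(len(self.areas_sup))
        self._rad = radiation_filter_coeffs(self.areas_sup[-1], cfg)
        self._f_mouth_prev = 0.0
        self._b_mouth_prev = 0.0

    @property
    def section_length(self) -> float:
        return self.cfg.c_air / (2.0 * self.cfg.fs)

    def set_lung_pressure(self, PL_kPa: float) -> None:
        self.PL_cgs = PL_kPa * KPA_TO_CGS

    def glottal_pressures(self, ug: float) -> tuple[float, float]:
        """Sub- and supraglottal pressures adjacent to the glottis."""
        p_sub = 2.0 * self.f_sub[-1] - self.Zs * ug
        p_supra = 2.0 * self.b_sup[0] + self.Ze * ug
        return p_sub, p_supra

    def _half_pass(self, ug: float) -> float:
        """One half-sample scattering/propagation pass; returns oral pressure."""
        att = self.cfg.section_attenuation
        f_sub, b_sub = self.f_sub * att, self.b_sub * att
        f_sup, b_sup = self.f_sup * att, self.b_sup * att

        # interior scattering, subglottal
        fa, bb = f_sub[:-1], b_sub[1:]
        r = self.r_sub
        new_f_sub = np.empty_like(f_sub)
        new_b_sub = np.empty_like(b_sub)
        new_f_sub[1:] = (1.0 + r) * fa - r * bb
        new_b_sub[:-1] = r * fa + (1.0 - r) * bb
        # interior scattering, supraglottal
        fa, bb = f_sup[:-1], b_sup[1:]
        r = self.r_sup
        new_f_sup = np.empty_like(f_sup)
        new_b_sup = np.empty_like(b_sup)
        new_f_sup[1:] = (1.0 + r) * fa - r * bb
        new_b_sup[:-1] = r * fa + (1.0 - r) * bb

        # lung termination: constant source + (near-)anechoic reflection
        new_f_sub[0] = (0.5 * self.PL_cgs
                        + self.cfg.lung_reflection * (b_sub[0] - 0.5 * self.PL_cgs))
        # glottal junction: waves leaving the glottis into each tube
        new_b_sub[-1] = f_sub[-1] - self.Zs * ug
        new_f_sup[0] = b_sup[0] + self.Ze * ug
        # mouth radiation
        b0, b1, a1 = self._rad
        f_mouth = f_sup[-1]
        b_mouth = b0 * f_mouth + b1 * self._f_mouth_prev + a1 * self._b_mouth_prev
        new_b_sup[-1] = b_mouth
        self._f_mouth_prev = f_mouth
        self._b_mouth_prev = b_mouth

        self.f_sub, self.b_sub = new_f_sub, new_b_sub
        self.f_sup, self.b_sup = new_f_sup, new_b_sup
        return f_mouth + b_mouth

    def step(self, ug: float) -> float:
        """Advance one audio sample; returns the radiated oral pressure."""
        self._half_pass(ug)
        return self._half_pass(ug)

    def total_energy(self) -> float:
        """Stored acoustic wave energy, up to a rho*c factor (passivity
        diagnostic).  Energy per section is (f^2 + b^2) * A; lossless
        scattering conserves this weighting exactly."""
        return float(np.sum((self.f_sub ** 2 + self.b_sub ** 2) * self.areas_sub)
                     + np.sum((self.f_sup ** 2 + self.b_sup ** 2) * self.areas_sup))
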