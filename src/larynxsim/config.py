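"""Simulation configuration.

All internal quantities are CGS (cm, g, s, dyn/cm^2).  Pressures cross the
user boundary in kPa and are converted with 1 kPa = 1e4 dyn/cm^2.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

KPA_TO_CGS = 1.0e4  # dyn/cm^2 per kPa


@dataclass
class SimConfig:
    # --- posture / geometry ---
    L0_cm: float = 1.6              # rest vocal fold length
    T0_cm: float = 0.7              # rest vocal fold thickness
    xi02_rest_cm: float = 0.06      # vocal-process half-width with no adductors
    k_LC: float = 1.0               # LCA/IA adduction coefficient
    k_TA: float = 0.2               # TA adduction coefficient
    xi02_min_cm: float = -0.02      # overlap bound (slight medial compression)

    # --- strain balance (anterior-posterior quasi-static force balance) ---
    area_SLLP_cm2: float = 0.03     # layer cross-section areas for the balance
    area_LIG_cm2: float = 0.05
    area_TA_cm2: float = 0.40
    eps_ct_anchor: float = 0.1875   # strain at full CT, zero TA  (L = 1.9 cm)
    eps_ta_anchor: float = -0.375   # strain at full TA, zero CT  (L = 1.0 cm)
    eps_bracket: tuple[float, float] = (-0.45, 0.45)
    strain_tol: float = 1.0e-6      # |F| tolerance as a fraction of force scale

    # --- active force-length factor (Gaussian in strain) ---
    eps_peak: float = 0.4
    fl_width: float = 0.6

    # --- tissue ---
    mu_gel: float = 5.0e3           # gel shear modulus, dyn/cm^2 (0.5 kPa)
    eta_gel: float = 1.0            # gel viscosity, dyn s/cm^2 (0.1 Pa s)
    density: float = 1.04           # tissue density, g/cm^3
    as_printed: bool = False        # literal (sign-uncorrected) linear stress term

    # --- fold mesh ---
    n_cols: int = 10                # columns of cells (medial -> lateral)
    n_rows: int = 6                 # rows of cells (inferior -> superior)
    n_slices: int = 15              # coronal slices (anterior -> posterior)
    depth_cm: float = 0.8           # mid-height lateral depth of the fold
    layer_cols: tuple[int, int, int] = (1, 2, 7)  # SLLP, ligament, muscle columns

    # --- vibration ---
    fs: float = 44100.0             # sampling rate, Hz (tissue and acoustics)
    penalty_factor: float = 50.0    # incompressibility penalty, multiple of mu
    collision_factor: float = 3.0   # collision spring, multiple of medial stiffness
    perturb_velocity: float = 1.0e-4  # seeded initial nodal velocity, cm/s
    abort_displacement_cm: float = 1.0
    seed: int = 1
    pressure_ramp_s: float = 0.010  # lung pressure onset ramp

    # --- aeroacoustics ---
    c_air: float = 35000.0          # speed of sound, cm/s
    rho_air: float = 1.14e-3        # air density, g/cm^3
    n_subglottal: int = 36
    n_supraglottal: int = 44
    section_attenuation: float = 0.996  # amplitude factor per section pass
    trachea_area_cm2: float = 2.5
    lung_reflection: float = 0.0    # anechoic lung termination

    # --- features ---
    R_cm: float = 30.0              # radiation distance for SPL
    Rm: float = 1.0                 # radiation resistance, normalized units
    # absolute SPL calibration: -10 log10 of the physical radiation
    # resistance (128 rho c / (9 pi^2 A) ~ 16 cgs at the packaged 3.6 cm^2
    # mouth section), converting the normalized Rm = 1 to physical units
    spl_offset_db: float = -12.0
    apen_m: int = 2
    apen_tau: int = 1
    apen_r_factor: float = 0.2
    apen_r_mode: str = "sd"         # "sd" (default) or "variance"
    apen_fs: float = 4410.0         # decimated rate for ApEn
    f0_min: float = 50.0
    f0_max: float = 600.0
    f0_conf_threshold: float = 0.3
    analysis_window_s: float = 0.2  # final window for f0 / spectral analysis
    steady_window_s: float = 0.1    # final window for postural means

    # --- sweep ---
    duration_s: float = 0.4
    grid_step_pct: int = 5
    osc_amp_floor: float = 1.0e-3   # minimal glottal-area p2p (cm^2) to count as oscillation
    osc_sustain_ratio: float = 0.95

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def hash(self) -> str:
        """Stable short hash of the configuration (used as sweep cache key)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key in ("layer_cols", "eps_bracket"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = self.to_dict()
        for key in ("layer_cols", "eps_bracket"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


DEFAULT_CONFIG = SimConfig()
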