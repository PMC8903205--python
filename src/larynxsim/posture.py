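"""Quasi-static vocal fold posturing.

Muscle activations set the prephonatory posture of the folds: the
anterior-posterior strain (hence length and thickness), the adduction
half-widths at the vocal process, and the medial-surface half-width field

    xi0(y, z) = (1 - y/L) [xi02 + (xi01 - xi02 - 4 xib z/T)(1 - z/T)]

with y from the anterior commissure (y = 0) to the vocal process (y = L)
and z from the inferior (z = 0) to the superior (z = T) surface.  All
lengths are cm.

The strain comes from a one-degree-of-freedom quasi-static force balance:
active cricothyroid force elongates the fold against the summed passive
layer forces, while active thyroarytenoid force pulls toward shortening.
The two free gains of the balance are fixed so that full CT (no TA) gives
L = 1.9 cm and full TA (no CT) gives L = 1.0 cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import SimConfig, DEFAULT_CONFIG
from .tissue import LayerParams, load_layer_params, passive_stress, force_length_factor

__all__ = [
    "ActivationState",
    "PosturalGeometry",
    "MedialSurfaceField",
    "compute_strain",
    "apply_posture_rules",
    "compute_adduction",
    "medial_surface",
    "posture_from_activation",
    "calibrate_gains",
]


class ConfigurationError(RuntimeError):
    """No strain root in the bracket - inconsistent balance configuration."""


@dataclass(frozen=True)
class ActivationState:
    """Control vector: five intrinsic muscle activations plus lung pressure.

    Activations are dimensionless fractions in [0, 1]; ``PL`` is in kPa.
    """

    aCT: float = 0.0
    aTA: float = 0.0
    aLC: float = 0.0
    aIA: float = 0.0
    aPCA: float = 0.0
    PL: float = 0.0

    def __post_init__(self):
        for name in ("aCT", "aTA", "aLC", "aIA", "aPCA"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.PL < 0.0:
            raise ValueError(f"PL = {self.PL} kPa must be >= 0")

    @classmethod
    def from_percent(cls, aCT=0.0, aTA=0.0, aLC=0.0, aIA=0.0, aPCA=0.0,
                     PL_kPa=0.0) -> "ActivationState":
        return cls(aCT=aCT / 100.0, aTA=aTA / 100.0, aLC=aLC / 100.0,
                   aIA=aIA / 100.0, aPCA=aPCA / 100.0, PL=PL_kPa)


@dataclass(frozen=True)
class PosturalGeometry:
    """Prephonatory posture: strain, length, thickness, adduction widths."""

    epsilon: float
    L: float
    T: float
    xi01: float
    xi02: float
    xib: float
    L0: float = 1.6
    T0: float = 0.7


@dataclass(frozen=True)
class MedialSurfaceField:
    """Half-width field xi0(y, z) sampled on a rectangular (y, z) grid."""

    y: np.ndarray      # anterior -> posterior sample positions, cm
    z: np.ndarray      # inferior -> superior sample positions, cm
    xi0: np.ndarray    # shape (len(y), len(z)), cm


def _passive_force(eps, layers: dict[str, LayerParams], cfg: SimConfig):
    """Net passive restoring force of the fold layers, relative to rest.

    P(eps) = sum_l A_l (sigma_l(eps) - sigma_l(0)); zero at rest, strictly
    increasing in eps, so it resists both elongation and shortening.
    """
    areas = {"SLLP": cfg.area_SLLP_cm2, "LIG": cfg.area_LIG_cm2,
             "TA": cfg.area_TA_cm2}
    total = 0.0
    for name, A in areas.items():
        lay = layers[name]
        total += A * (passive_stress(eps, lay, cfg.as_printed)
                      - passive_stress(0.0, lay, cfg.as_printed))
    return total


def calibrate_gains(layers: dict[str, LayerParams],
                    cfg: SimConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """Closed-form gains (dyn) of the strain balance from the two anchors.

    Full CT alone must produce the anchor elongation and full TA alone the
    anchor shortening, which fixes both gains uniquely:

        G_CT = P(eps_ct) / FL(eps_ct),   G_TA = -P(eps_ta) / FL(eps_ta)
    """
    fl = lambda e: force_length_factor(e, cfg.eps_peak, cfg.fl_width)
    g_ct = _passive_force(cfg.eps_ct_anchor, layers, cfg) / fl(cfg.eps_ct_anchor)
    g_ta = -_passive_force(cfg.eps_ta_anchor, layers, cfg) / fl(cfg.eps_ta_anchor)
    if g_ct <= 0 or g_ta <= 0:
        raise ConfigurationError("calibration produced non-positive gains")
    return g_ct, g_ta


def compute_strain(act: ActivationState, layers: dict[str, LayerParams] | None = None,
                   cfg: SimConfig = DEFAULT_CONFIG) -> float:
    """Vocal fold strain from the quasi-static CT-TA force balance.

    Root of ``F(eps) = aCT G_CT FL(eps) - aTA G_TA FL(eps) - P(eps)`` on the
    configured bracket.  Returns exactly 0 at rest (no active forces).
    """
    if layers is None:
        layers = load_layer_params()
    if act.aCT == 0.0 and act.aTA == 0.0:
        return 0.0
    g_ct, g_ta = calibrate_gains(layers, cfg)
    fl = lambda e: force_length_factor(e, cfg.eps_peak, cfg.fl_width)

    def F(eps):
        return (act.aCT * g_ct - act.aTA * g_ta) * fl(eps) - _passive_force(eps, layers, cfg)

    lo, hi = cfg.eps_bracket
    f_lo, f_hi = F(lo), F(hi)
    if f_lo * f_hi > 0:
        raise ConfigurationError(
            f"no strain root in bracket [{lo}, {hi}]: F({lo}) = {f_lo:.3g}, "
            f"F({hi}) = {f_hi:.3g}")
    scale = max(g_ct, g_ta)
    eps = brentq(F, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(F(eps)) < cfg.strain_tol * scale
    return float(eps)


def apply_posture_rules(epsilon: float, aTA: float, xi02: float,
                        cfg: SimConfig = DEFAULT_CONFIG) -> PosturalGeometry:
    """Posture from strain via the empirical posturing rules.

    L = L0(1+eps), T = T0/(1+eps) (isovolume, L*T = L0*T0),
    xi01 = xi02 + max(0, 0.1 T (1 - 1.5 aTA)), xib = 0.05 T (1 - aTA).
    """
    if epsilon <= -1.0:
        raise ValueError(f"invalid strain {epsilon} <= -1")
    if not 0.0 <= aTA <= 1.0:
        raise ValueError(f"aTA = {aTA} outside [0, 1]")
    L = cfg.L0_cm * (1.0 + epsilon)
    T = cfg.T0_cm / (1.0 + epsilon)
    xi01 = xi02 + max(0.0, 0.1 * T * (1.0 - 1.5 * aTA))
    xib = 0.05 * T * (1.0 - aTA)
    return PosturalGeometry(epsilon=epsilon, L=L, T=T, xi01=xi01, xi02=xi02,
                            xib=xib, L0=cfg.L0_cm, T0=cfg.T0_cm)


def compute_adduction(act: ActivationState, cfg: SimConfig = DEFAULT_CONFIG) -> float:
    """Vocal-process half-width xi02 (cm) from the adductor activations.

    Linear rule: the LCA/IA pair closes the posterior glottis, TA adducts
    slightly; clipped below at a small negative overlap bound.
    """
    adductor = 0.5 * (act.aLC + act.aIA)
    xi02 = cfg.xi02_rest_cm * (1.0 - cfg.k_LC * adductor - cfg.k_TA * act.aTA)
    return float(max(xi02, cfg.xi02_min_cm))


def medial_surface(geom: PosturalGeometry, y_samples, z_samples) -> MedialSurfaceField:
    """Evaluate the medial-surface half-width field on a (y, z) grid."""
    y = np.atleast_1d(np.asarray(y_samples, dtype=float))
    z = np.atleast_1d(np.asarray(z_samples, dtype=float))
    if y.min() < 0 or y.max() > geom.L + 1e-12:
        raise ValueError(f"y samples outside [0, L={geom.L}]")
    if z.min() < 0 or z.max() > geom.T + 1e-12:
        raise ValueError(f"z samples outside [0, T={geom.T}]")
    Y, Z = np.meshgrid(y, z, indexing="ij")
    bracket = (geom.xi02
               + (geom.xi01 - geom.xi02 - 4.0 * geom.xib * Z / geom.T)
               * (1.0 - Z / geom.T))
    xi0 = (1.0 - Y / geom.L) * bracket
    return MedialSurfaceField(y=y, z=z, xi0=xi0)


def posture_from_activation(act: ActivationState,
                            layers: dict[str, LayerParams] | None = None,
                            cfg: SimConfig = DEFAULT_CONFIG) -> PosturalGeometry:
    """Full posture pipeline: strain balance + adduction + posture rules."""
    if layers is None:
        layers = load_layer_params()
    eps = compute_strain(act, layers, cfg)
    xi02 = compute_adduction(act, cfg)
    return apply_posture_rules(eps, act.aTA, xi02, cfg)


def posture_table(grid_step_pct: int = 5, cfg: SimConfig = DEFAULT_CONFIG,
                  layers: dict[str, LayerParams] | None = None):
    """Posture-only sweep: one row per TA-CT grid point (no simulation).

    LCA/IA follow the sweep's constraint rule.  Returns a DataFrame with
    columns aCT_pct, aTA_pct, epsilon, L, T, xi01, xi02, xib.
    """
    import pandas as pd
    from .sweep import adduction_rule  # local import: avoid a cycle
    if layers is None:
        layers = load_layer_params()
    rows = []
    levels = np.arange(0, 101, grid_step_pct, dtype=float)
    for ct in levels:
        for ta in levels:
            aLC = adduction_rule(ct, ta)
            act = ActivationState.from_percent(aCT=ct, aTA=ta, aLC=aLC, aIA=aLC)
            g = posture_from_activation(act, layers, cfg)
            rows.append({"aCT_pct": ct, "aTA_pct": ta, "epsilon": g.epsilon,
                         "L": g.L, "T": g.T, "xi01": g.xi01, "xi02": g.xi02,
                         "xib": g.xib})
    return pd.DataFrame(rows)
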