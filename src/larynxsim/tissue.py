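"""Tissue constitutive law.

Each vocal fold layer (and each intrinsic laryngeal muscle) carries a
passive fiber stress along the anterior-posterior fiber direction, modeled
as a combined linear + exponential function of strain.  Muscles additionally
produce an active stress proportional to their activation, scaled by a
Gaussian force-length factor.  The fiber stress is converted to an
equivalent transverse shear modulus mu' for the fiber-gel vibration model;
the isotropic ground substance contributes a gel shear modulus mu and a
viscosity eta.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig, DEFAULT_CONFIG

__all__ = [
    "LayerParams",
    "TissueState",
    "load_layer_params",
    "passive_stress",
    "active_stress",
    "force_length_factor",
    "fiber_shear_modulus",
    "tissue_state_for_posture",
]

MUSCLES = ("CT", "LCA", "TA", "IA", "PCA")
FOLD_LAYERS = ("SLLP", "LIG", "TA")  # cover, ligament, body of the fold


class InvalidLayerError(ValueError):
    """Raised when an operation requires a muscle but got a passive layer."""


@dataclass(frozen=True)
class LayerParams:
    """Constitutive parameters for one tissue layer or muscle.

    Stresses are in dyn/cm^2; strains are dimensionless.  ``sigma_m`` is the
    maximum isometric active stress and is ``None`` for passive layers
    (ligament, SLLP).
    """

    name: str
    sigma0: float
    sigma2: float
    B: float
    eps1: float
    eps2: float
    sigma_m: float | None = None

    def __post_init__(self):
        if not self.eps1 < self.eps2:
            raise ValueError(f"{self.name}: require eps1 < eps2")

    @property
    def is_muscle(self) -> bool:
        return self.sigma_m is not None


def load_layer_params(overrides: dict | None = None) -> dict[str, LayerParams]:
    """Load the packaged per-layer parameter table.

    ``overrides`` maps layer name to a dict of field overrides, e.g.
    ``{"LIG": {"sigma0": 1e4}}``.
    """
    ref = importlib.resources.files("larynxsim.data") / "layer_params.tsv"
    layers: dict[str, LayerParams] = {}
    header: list[str] | None = None
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        name = row.pop("name")
        vals = {k: float(v) for k, v in row.items()}
        if np.isnan(vals.get("sigma_m", np.nan)):
            vals["sigma_m"] = None
        if overrides and name in overrides:
            vals.update(overrides[name])
        layers[name] = LayerParams(name=name, **vals)
    return layers


def passive_stress(epsilon, layer: LayerParams, as_printed: bool = False):
    """Passive fiber stress (dyn/cm^2) at strain ``epsilon``.

    The linear part uses the corrected positive-slope form
    ``-(sigma0/eps1)(eps - eps1)`` (equal to sigma0 at zero strain); the
    literal negative-slope rendering is available with ``as_printed=True``.
    The exponential bracket ``sigma2[e^{B(eps-eps2)} - 1 - B(eps-eps2)]`` is
    zeroed for ``eps <= eps2``, which keeps the law C^1 at eps2.
    """
    eps = np.asarray(epsilon, dtype=float)
    if as_printed:
        lin = -layer.sigma0 * (eps - layer.eps1)
    else:
        lin = -(layer.sigma0 / layer.eps1) * (eps - layer.eps1)
    d = eps - layer.eps2
    expo = np.where(d > 0.0,
                    layer.sigma2 * (np.exp(layer.B * np.clip(d, 0.0, None))
                                    - 1.0 - layer.B * np.clip(d, 0.0, None)),
                    0.0)
    out = lin + expo
    return float(out) if np.isscalar(epsilon) else out


def force_length_factor(epsilon, eps_peak: float = 0.4, width: float = 0.6):
    """Gaussian active force-length factor, peak 1 at ``eps_peak``."""
    eps = np.asarray(epsilon, dtype=float)
    out = np.exp(-(((eps - eps_peak) / width) ** 2))
    return float(out) if np.isscalar(epsilon) else out


def active_stress(a: float, epsilon: float, layer: LayerParams,
                  eps_peak: float = 0.4, width: float = 0.6) -> float:
    """Quasi-static active muscle stress a * sigma_m * FL(eps), dyn/cm^2."""
    if not layer.is_muscle:
        raise InvalidLayerError(f"{layer.name} has no active stress (not a muscle)")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activation {a} outside [0, 1]")
    return a * layer.sigma_m * force_length_factor(epsilon, eps_peak, width)


def fiber_shear_modulus(sigma_y):
    """Equivalent transverse shear modulus mu' of a tensioned fiber.

    A taut fiber's transverse restoring force per unit length per unit
    displacement equals its tension, so mu' = max(0, sigma_y); a slack
    (compressed) fiber carries no transverse stiffness.
    """
    arr = np.maximum(np.asarray(sigma_y, dtype=float), 0.0)
    return float(arr) if np.isscalar(sigma_y) else arr


@dataclass
class TissueState:
    """Per-layer stress state of the three fold layers at a given posture.

    ``sigma_y`` holds the passive fiber stress; ``sigma_fiber`` adds the
    active TA stress to the muscle layer (the tension carried by the fibers
    during vibration); ``mu_prime`` is the equivalent shear modulus.
    """

    sigma_y: dict[str, float]
    sigma_fiber: dict[str, float]
    mu_prime: dict[str, float]
    mu: float = DEFAULT_CONFIG.mu_gel
    eta: float = DEFAULT_CONFIG.eta_gel

    @classmethod
    def zeros(cls, mu: float = DEFAULT_CONFIG.mu_gel,
              eta: float = DEFAULT_CONFIG.eta_gel) -> "TissueState":
        z = {k: 0.0 for k in FOLD_LAYERS}
        return cls(sigma_y=dict(z), sigma_fiber=dict(z), mu_prime=dict(z),
                   mu=mu, eta=eta)


def tissue_state_for_posture(epsilon: float, aTA: float,
                             layers: dict[str, LayerParams],
                             cfg: SimConfig = DEFAULT_CONFIG) -> TissueState:
    """Evaluate the three fold layers' stress state at strain ``epsilon``.

    Passive stress from the constitutive law; the muscle (body) layer adds
    the active TA stress.  Negative net stresses carry no transverse
    stiffness (slack fibers).
    """
    sigma_y = {name: passive_stress(epsilon, layers[name], cfg.as_printed)
               for name in FOLD_LAYERS}
    sigma_fiber = dict(sigma_y)
    sigma_fiber["TA"] = sigma_y["TA"] + active_stress(
        aTA, epsilon, layers["TA"], cfg.eps_peak, cfg.fl_width)
    mu_prime = {name: fiber_shear_modulus(s) for name, s in sigma_fiber.items()}
    return TissueState(sigma_y=sigma_y, sigma_fiber=sigma_fiber,
                       mu_prime=mu_prime, mu=cfg.mu_gel, eta=cfg.eta_gel)
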