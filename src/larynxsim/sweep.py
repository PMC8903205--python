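"""The muscle-activation sweep experiment.

CT and TA activations are varied on a percent grid (default 0-100% in 5%
steps, 441 points).  At each point the lung pressure and the balanced
LCA/IA adduction follow the closed-form constraint rules

    PL  = 0.8 + 0.025 aCT + 0.01 aTA   [kPa]
    aLC = aIA = 30 + 0.3 aCT - 0.1 aTA [%]

chosen so that the phonation threshold pressure is exceeded across the
grid; PCA is held at 0%.  Each point runs the full posture -> tissue ->
vibration + acoustics pipeline for 0.4 s and extracts the acoustic and
postural features; the assembled map exports as tidy CSV and contour plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig, DEFAULT_CONFIG
from .posture import ActivationState
from .tissue import load_layer_params
from .vibration import simulate, VibroAcousticRecord
from .features import FeatureSet, extract_features

__all__ = [
    "lung_pressure_rule",
    "adduction_rule",
    "run_point",
    "run_sweep",
    "export_maps",
    "find_onset_threshold",
    "FeatureMap",
    "MAP_COLUMNS",
]

MAP_COLUMNS = ["aTA_pct", "aCT_pct", "PL_kPa", "aLC_pct", "status", "fo_Hz",
               "SPL_dB", "NSC", "ApEn", "L_cm", "sigma_SLLP", "sigma_lig",
               "sigma_mus"]


def _check_pct(name: str, v: float) -> None:
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"{name} = {v} outside [0, 100] %")


def lung_pressure_rule(aCT_pct: float, aTA_pct: float) -> float:
    """Lung pressure (kPa) from CT/TA activation in percent."""
    _check_pct("aCT", aCT_pct)
    _check_pct("aTA", aTA_pct)
    return 0.8 + 0.025 * aCT_pct + 0.01 * aTA_pct


def adduction_rule(aCT_pct: float, aTA_pct: float) -> float:
    """Balanced LCA/IA activation (percent) from CT/TA activation in percent."""
    _check_pct("aCT", aCT_pct)
    _check_pct("aTA", aTA_pct)
    return float(np.clip(30.0 + 0.3 * aCT_pct - 0.1 * aTA_pct, 0.0, 100.0))


def constrained_activation(aCT_pct: float, aTA_pct: float,
                           PL_kPa: float | None = None) -> ActivationState:
    """Activation state of one grid point under the constraint rules."""
    aLC = adduction_rule(aCT_pct, aTA_pct)
    PL = lung_pressure_rule(aCT_pct, aTA_pct) if PL_kPa is None else PL_kPa
    return ActivationState.from_percent(aCT=aCT_pct, aTA=aTA_pct, aLC=aLC,
                                        aIA=aLC, aPCA=0.0, PL_kPa=PL)


@dataclass
class PointResult:
    """Features + run status of one sweep grid point."""

    aCT_pct: float
    aTA_pct: float
    PL_kPa: float
    aLC_pct: float
    status: str                 # oscillating | non-oscillating | failed
    features: FeatureSet
    record: VibroAcousticRecord | None = None


def _oscillation_status(record: VibroAcousticRecord, cfg: SimConfig) -> str:
    """Self-sustainment: last-100-ms area amplitude >= 95% of the previous one."""
    if record.aborted:
        return "failed"
    dur = len(record.po) / record.fs
    a_prev = record.area_amplitude(dur - 0.2, dur - 0.1)
    a_last = record.area_amplitude(dur - 0.1, dur)
    if a_last >= cfg.osc_amp_floor and a_last >= cfg.osc_sustain_ratio * a_prev:
        return "oscillating"
    return "non-oscillating"


def run_point(aCT_pct: float, aTA_pct: float, cfg: SimConfig = DEFAULT_CONFIG,
              layers: dict | None = None, PL_kPa: float | None = None,
              keep_record: bool = False) -> PointResult:
    """Simulate one grid point and extract its features.

    Numerical failures are recorded as status ``failed`` with missing
    features; they never raise.
    """
    if layers is None:
        layers = load_layer_params()
    act = constrained_activation(aCT_pct, aTA_pct, PL_kPa)
    try:
        record = simulate(act, cfg, layers)
        status = _oscillation_status(record, cfg)
        feats = extract_features(record, cfg, oscillating=(status == "oscillating"))
    except Exception:
        return PointResult(aCT_pct=aCT_pct, aTA_pct=aTA_pct, PL_kPa=act.PL,
                           aLC_pct=act.aLC * 100.0, status="failed",
                           features=FeatureSet())
    return PointResult(aCT_pct=aCT_pct, aTA_pct=aTA_pct, PL_kPa=act.PL,
                       aLC_pct=act.aLC * 100.0, status=status, features=feats,
                       record=record if keep_record else None)


@dataclass
class FeatureMap:
    """Per-grid-point features over the TA-CT activation grid."""

    table: pd.DataFrame
    grid_step_pct: int
    config_hash: str
    seed: int
    duration_s: float

    def cell(self, aCT_pct: float, aTA_pct: float) -> pd.Series:
        m = ((self.table.aCT_pct == aCT_pct) & (self.table.aTA_pct == aTA_pct))
        return self.table[m].iloc[0]

    def oscillating(self) -> pd.DataFrame:
        return self.table[self.table.status == "oscillating"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_sweep(grid_step_pct: int = 5, cfg: SimConfig = DEFAULT_CONFIG,
              cache: dict | None = None, progress: bool = False,
              out_csv=None) -> FeatureMap:
    """Run the full TA-CT activation grid.

    ``cache`` (a dict) makes the sweep resumable: cells are keyed by
    (aCT, aTA, config hash) and reused when present.
    """
    if 100 % grid_step_pct != 0:
        raise ValueError(f"grid step {grid_step_pct} must divide 100")
    layers = load_layer_params()
    chash = cfg.hash()
    levels = np.arange(0, 101, grid_step_pct, dtype=float)
    rows = []
    for aCT in levels:
        for aTA in levels:
            key = (float(aCT), float(aTA), chash)
            if cache is not None and key in cache:
                res = cache[key]
            else:
                res = run_point(aCT, aTA, cfg, layers)
                if cache is not None:
                    cache[key] = res
            f = res.features
            rows.append({
                "aTA_pct": aTA, "aCT_pct": aCT, "PL_kPa": res.PL_kPa,
                "aLC_pct": res.aLC_pct, "status": res.status,
                "fo_Hz": f.fo if f.fo is not None else np.nan,
                "SPL_dB": f.SPL, "NSC": f.NSC, "ApEn": f.ApEn,
                "L_cm": f.L_mean, "sigma_SLLP": f.sigma_SLLP,
                "sigma_lig": f.sigma_lig, "sigma_mus": f.sigma_mus,
            })
            if progress:
                print(f"  point aCT={aCT:5.1f}% aTA={aTA:5.1f}%: {res.status}",
                      flush=True)
    table = pd.DataFrame(rows, columns=MAP_COLUMNS)
    fmap = FeatureMap(table=table, grid_step_pct=grid_step_pct,
                      config_hash=chash, seed=cfg.seed,
                      duration_s=cfg.duration_s)
    if out_csv is not None:
        fmap.to_csv(out_csv)
    return fmap


_MAP_FEATURES = {
    "PL_kPa": "lung pressure (kPa)",
    "aLC_pct": "LCA/IA activation (%)",
    "fo_Hz": "fundamental frequency (Hz)",
    "SPL_dB": "sound pressure level (dB)",
    "NSC": "normalized spectral centroid",
    "ApEn": "approximate entropy",
    "L_cm": "vocal fold length (cm)",
    "sigma_SLLP": "SLLP fiber stress (dyn/cm$^2$)",
    "sigma_lig": "ligament fiber stress (dyn/cm$^2$)",
    "sigma_mus": "muscle fiber stress (dyn/cm$^2$)",
}


def export_maps(fmap: FeatureMap, outdir, which: list[str] | None = None) -> list:
    """Write one contour plot + one tidy CSV per feature map.

    Axes are aTA (x) versus aCT (y) in percent; non-oscillating cells are
    left blank (NaN) in acoustic-feature maps.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(fmap.table) == 0:
        raise ValueError("empty feature map")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    which = list(_MAP_FEATURES) if which is None else which
    written = []
    tbl = fmap.table
    ta = np.sort(tbl.aTA_pct.unique())
    ct = np.sort(tbl.aCT_pct.unique())
    acoustic = {"fo_Hz", "SPL_dB", "NSC", "ApEn"}
    for feat in which:
        piv = tbl.pivot(index="aCT_pct", columns="aTA_pct", values=feat)
        if feat in acoustic:
            mask = tbl.pivot(index="aCT_pct", columns="aTA_pct",
                             values="status") != "oscillating"
            piv = piv.mask(mask)
        csv_path = outdir / f"map_{feat}.csv"
        sub = tbl[["aTA_pct", "aCT_pct", "status", feat]]
        sub.to_csv(csv_path, index=False)
        fig, ax = plt.subplots(figsize=(5, 4))
        vals = np.ma.masked_invalid(piv.values)
        if vals.count() >= 4:
            cs = ax.contourf(ta, ct, vals, levels=12, cmap="viridis")
            fig.colorbar(cs, ax=ax)
        ax.set_xlabel("TA activation (%)")
        ax.set_ylabel("CT activation (%)")
        ax.set_title(_MAP_FEATURES.get(feat, feat))
        png_path = outdir / f"map_{feat}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written.extend([csv_path, png_path])
    return written


def find_onset_threshold(aCT_pct: float, aTA_pct: float,
                         cfg: SimConfig = DEFAULT_CONFIG,
                         p_lo: float = 0.0, p_hi: float | None = None,
                         tol_kPa: float = 0.05,
                         duration: float = 0.2) -> float | None:
    """Phonation threshold pressure (kPa) at fixed posture, by bisection.

    Returns the lung pressure below which oscillation decays and above
    which it self-sustains, to ``tol_kPa``; ``None`` when even ``p_hi``
    does not sustain oscillation.
    """
    layers = load_layer_params()
    cfg = cfg.replace(duration_s=duration)
    if p_hi is None:
        p_hi = lung_pressure_rule(aCT_pct, aTA_pct)

    def oscillates(PL: float) -> bool:
        res = run_point(aCT_pct, aTA_pct, cfg, layers, PL_kPa=PL)
        return res.status == "oscillating"

    if not oscillates(p_hi):
        return None
    if oscillates(p_lo) and p_lo > 0.0:
        return p_lo
    lo, hi = p_lo, p_hi
    while hi - lo > tol_kPa:
        mid = 0.5 * (lo + hi)
        if oscillates(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
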