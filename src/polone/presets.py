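"""Packaged pause landscapes and condition presets.

The wild-type landscape places a cluster of strong pause sites between the
transcription start site and nucleotide 300 of the 5'ETS, a secondary cluster
spanning the 5.8S / early-25S boundary, and a flat baseline elsewhere.  All
dwell-time values are calibration choices: CRAC resolves relative occupancy,
not absolute dwell times, so tau is in arbitrary time units.

Presets
-------
``wt``
    The wild-type enzyme on the default landscape.
``superpol``
    The hyperactive variant: 5'ETS-cluster dwell times scaled down and the
    termination hazard scaled down, solved (at import of the preset) so that
    the closed-form steady state gives a per-million-normalized 5'ETS
    occupancy ratio WT/SuperPol of exactly 1.25 and a full-length production
    ratio SuperPol/WT of exactly 1.5.  ``preset_model("superpol")`` re-checks
    both ratios from ``steady_state`` every time it builds the model.
``wt-bmh21`` / ``superpol-bmh21``
    The same enzymes with the termination hazard multiplied at pause sites
    only — an intercalating drug acting preferentially on paused elongation
    complexes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize

from .annotation import RdnaAnnotation, default_annotation
from .model import PauseTerminationModel, steady_state

__all__ = [
    "PRESET_NAMES",
    "PRIMARY_CLUSTER",
    "PRIMARY_PAUSE_SITES",
    "SECONDARY_PAUSE_SITES",
    "default_tau",
    "pause_site_mask",
    "preset_model",
    "superpol_scaling",
]

# --- landscape constants (1-based positions) -------------------------------

BASE_TAU = 1.0
#: interval of the configured 5'ETS pause cluster (TSS .. nt 300)
PRIMARY_CLUSTER = (1, 300)
PRIMARY_PAUSE_SITES = (60, 90, 120, 150, 180, 215, 250, 285)
PRIMARY_PAUSE_TAU = 80.0
#: secondary cluster spanning the 5.8S / early-25S boundary
SECONDARY_PAUSE_SITES = (3000, 3100, 3200, 3300)
SECONDARY_PAUSE_TAU = 25.0
#: sites with tau above this are "pause sites" for hazard-targeting drugs
PAUSE_TAU_THRESHOLD = 10.0

KAPPA_WT = 9e-5
ALPHA = 1.0
#: hazard multiplier at pause sites under BMH-21 treatment
BMH21_KAPPA_FACTOR = 40.0

#: calibration targets recomputed by the preset self-check
SUPERPOL_FIVEETS_OCCUPANCY_RATIO = 1.25   # WT / SuperPol, normalized shares
SUPERPOL_FULL_LENGTH_RATIO = 1.5          # SuperPol / WT

PRESET_NAMES = ("wt", "superpol", "wt-bmh21", "superpol-bmh21")


def default_tau(unit_length: int | None = None,
                fiveets_scale: float = 1.0) -> np.ndarray:
    """Wild-type dwell-time landscape; ``fiveets_scale`` rescales the
    5'ETS-cluster pause sites (used by the SuperPol preset)."""
    if unit_length is None:
        unit_length = default_annotation().unit_length
    tau = np.full(unit_length, BASE_TAU)
    for pos in PRIMARY_PAUSE_SITES:
        tau[pos - 1] = PRIMARY_PAUSE_TAU * fiveets_scale
    for pos in SECONDARY_PAUSE_SITES:
        tau[pos - 1] = SECONDARY_PAUSE_TAU
    return tau


def pause_site_mask(tau: np.ndarray) -> np.ndarray:
    """Boolean mask of pause sites (tau above the pause threshold)."""
    return np.asarray(tau) > PAUSE_TAU_THRESHOLD


def _fiveets_share(tau: np.ndarray, kappa, annotation: RdnaAnnotation) -> float:
    ss = steady_state(PauseTerminationModel(tau, kappa, ALPHA))
    return ss.occupancy_share(annotation, "5'ETS")


@lru_cache(maxsize=1)
def superpol_scaling() -> tuple[float, float]:
    """Solve for the SuperPol preset's (5'ETS-cluster tau scale, kappa scale).

    Two equations in two unknowns (s, g), solved by damped Newton via
    scipy.optimize.root:

        share_WT / share_SP(s, g)  = 1.25   (normalized 5'ETS occupancy)
        F_SP(s, g) / F_WT          = 1.5    (full-length production)
    """
    annotation = default_annotation()
    tau_wt = default_tau(annotation.unit_length)
    ss_wt = steady_state(PauseTerminationModel(tau_wt, KAPPA_WT, ALPHA))
    share_wt = ss_wt.occupancy_share(annotation, "5'ETS")

    def residual(x):
        s, g = x
        tau = default_tau(annotation.unit_length, fiveets_scale=s)
        ss = steady_state(PauseTerminationModel(tau, g * KAPPA_WT, ALPHA))
        return [
            share_wt / ss.occupancy_share(annotation, "5'ETS")
            - SUPERPOL_FIVEETS_OCCUPANCY_RATIO,
            ss.full_length / ss_wt.full_length - SUPERPOL_FULL_LENGTH_RATIO,
        ]

    sol = optimize.root(residual, x0=[0.65, 0.4], tol=1e-12)
    if not sol.success:  # pragma: no cover - deterministic solve
        raise RuntimeError(f"SuperPol calibration failed: {sol.message}")
    s, g = sol.x
    if not (0 < s < 1 and 0 < g < 1):  # pragma: no cover
        raise RuntimeError(f"SuperPol calibration left (0,1): s={s}, g={g}")
    return float(s), float(g)


def _self_check_superpol(model: PauseTerminationModel,
                         annotation: RdnaAnnotation) -> None:
    ss_wt = steady_state(PauseTerminationModel(
        default_tau(annotation.unit_length), KAPPA_WT, ALPHA))
    ss_sp = steady_state(model)
    ratio_occ = (ss_wt.occupancy_share(annotation, "5'ETS")
                 / ss_sp.occupancy_share(annotation, "5'ETS"))
    ratio_fl = ss_sp.full_length / ss_wt.full_length
    if abs(ratio_occ - SUPERPOL_FIVEETS_OCCUPANCY_RATIO) > 1e-6 \
            or abs(ratio_fl - SUPERPOL_FULL_LENGTH_RATIO) > 1e-6:
        raise RuntimeError(
            f"SuperPol preset self-check failed: occupancy ratio {ratio_occ}, "
            f"full-length ratio {ratio_fl}")


def preset_model(name: str,
                 annotation: RdnaAnnotation | None = None) -> PauseTerminationModel:
    """Build a packaged condition preset by name (see module docstring)."""
    if annotation is None:
        annotation = default_annotation()
    name = name.lower()
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    treated = name.endswith("-bmh21")
    base = name.removesuffix("-bmh21")
    if base == "wt":
        tau = default_tau(annotation.unit_length)
        kappa_scalar = KAPPA_WT
    else:
        s, g = superpol_scaling()
        tau = default_tau(annotation.unit_length, fiveets_scale=s)
        kappa_scalar = g * KAPPA_WT
    model = PauseTerminationModel(tau, kappa_scalar, ALPHA)
    if base == "superpol":
        _self_check_superpol(model, annotation)
    if treated:
        kappa = np.full(tau.size, kappa_scalar)
        kappa[pause_site_mask(tau)] *= BMH21_KAPPA_FACTOR
        model = model.with_kappa(kappa)
    return model
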