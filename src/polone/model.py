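"""Single-molecule elongation model with pause-coupled premature termination.

A polymerase initiates at rate alpha, steps through sites x = 1..L, and dwells
at site x for an exponentially distributed time with mean tau(x).  While
dwelling it is exposed to a termination hazard kappa per unit dwell time, so
the probability of releasing (premature termination of transcription, PTT) at
site x is

    p(x) = 1 - exp(-kappa * tau(x)),

i.e. the longer the pause at a site, the more likely the release there.  The
hazard may be a scalar or a per-site array (a drug acting preferentially on
paused complexes multiplies the hazard at pause sites only).

Steady-state consequences (closed form):

    S(x) = prod_{y<x} (1 - p(y))       survival to site x, S(1) = 1
    J(x) = alpha * S(x)                flux arriving at x
    O(x) = J(x) * tau(x)               occupancy (residence-time weighted)
    A(x) = J(x) * p(x)                 abortive (PTT) rate at x
    F    = alpha * S(L+1)              full-length production rate

which satisfy the conservation law alpha = F + sum_x A(x) exactly
(telescoping of S(x) p(x) = S(x) - S(x+1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PauseTerminationModel", "SteadyState", "steady_state"]


@dataclass(frozen=True)
class PauseTerminationModel:
    """Per-site mean dwell times, termination hazard and initiation rate.

    Parameters
    ----------
    tau
        Mean dwell time per site, length L, all > 0 (arbitrary time units).
    kappa
        Termination hazard per dwell-time unit; scalar or per-site array,
        all >= 0.  kappa = 0 recovers a never-terminating polymerase.
    alpha
        Initiation rate (molecules per time unit), > 0.
    """

    tau: np.ndarray
    kappa: float | np.ndarray = 0.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 1 or tau.size == 0:
            raise ValueError("tau must be a non-empty 1-D array")
        if not np.all(tau > 0):
            raise ValueError("all dwell times tau(x) must be > 0")
        object.__setattr__(self, "tau", tau)
        kappa = np.asarray(self.kappa, dtype=float)
        if kappa.ndim == 0:
            kappa = float(kappa)
            if kappa < 0:
                raise ValueError("kappa must be >= 0")
        else:
            if kappa.shape != tau.shape:
                raise ValueError("per-site kappa must match tau in length")
            if not np.all(kappa >= 0):
                raise ValueError("kappa must be >= 0")
        object.__setattr__(self, "kappa", kappa)
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")

    @property
    def L(self) -> int:
        return self.tau.size

    @property
    def hazard(self) -> np.ndarray:
        """Per-site integrated hazard kappa(x) * tau(x)."""
        return np.asarray(self.kappa) * self.tau

    @property
    def p(self) -> np.ndarray:
        """Per-visit termination probability p(x) = 1 - exp(-kappa tau(x))."""
        return -np.expm1(-self.hazard)

    def with_kappa(self, kappa) -> "PauseTerminationModel":
        return PauseTerminationModel(self.tau, kappa, self.alpha)


@dataclass(frozen=True)
class SteadyState:
    """Closed-form steady state of a PauseTerminationModel (length-L arrays;
    index 0 = site 1).  ``survival_end`` is S(L+1)."""

    survival: np.ndarray      # S(x), probability of reaching site x
    flux: np.ndarray          # J(x) = alpha * S(x)
    occupancy: np.ndarray     # O(x) = J(x) * tau(x)
    abortive: np.ndarray      # A(x) = J(x) * p(x)
    full_length: float        # F = alpha * S(L+1)
    survival_end: float
    alpha: float

    @property
    def total_abortive(self) -> float:
        return float(self.abortive.sum())

    def occupancy_share(self, annotation, region: str) -> float:
        """Fraction of total occupancy falling in one annotated region
        (this is what a per-million normalized profile sums to, /1e6)."""
        reg = annotation[region]
        total = self.occupancy.sum()
        return float(self.occupancy[reg.start - 1 : reg.end].sum() / total)


def steady_state(model: PauseTerminationModel) -> SteadyState:
    """Evaluate survival, flux, occupancy, abortive and full-length rates.

    The conservation identity alpha = F + sum A(x) holds to float precision.
    """
    p = model.p
    # S over sites 1..L+1
    s_full = np.concatenate(([1.0], np.cumprod(1.0 - p)))
    survival = s_full[:-1]
    flux = model.alpha * survival
    occupancy = flux * model.tau
    abortive = flux * p
    return SteadyState(
        survival=survival,
        flux=flux,
        occupancy=occupancy,
        abortive=abortive,
        full_length=float(model.alpha * s_full[-1]),
        survival_end=float(s_full[-1]),
        alpha=float(model.alpha),
    )
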