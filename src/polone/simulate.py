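"""Stochastic twin of the steady-state model: molecule walks, CRAC-like read
emission with UMIs and PCR duplication, abortive-transcript spectra, and
slot-blot / northern-style probe intensity tables.

Each simulated molecule initiates at site 1 and walks site by site; at site x
it dwells for Exponential(mean tau(x)) time and terminates there with
probability p(x) = 1 - exp(-kappa(x) tau(x)).  The walk's termination site is
sampled exactly by inverting the discrete cumulative hazard
H(x) = sum_{y<=x} -ln(1 - p(y)) against a unit-exponential draw (a molecule
terminates at the first site where its accumulated hazard is exhausted, which
is the same law as the per-site Bernoulli walk).  Dwell times are aggregated
per site: the total dwell spent at x by the n(x) molecules that reached it is
a Gamma(n(x), tau(x)) draw, the sufficient statistic needed for read emission.

CRAC read 3' ends are sampled by dwell-time weighting (cross-linking captures
an enzyme in proportion to its residence time), so expected per-base coverage
is proportional to the steady-state occupancy O(x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import READ_COLUMNS, ProbeCatalog, RdnaAnnotation
from .model import PauseTerminationModel, SteadyState, steady_state

__all__ = [
    "SimulationConfig",
    "MoleculeOutcomes",
    "AbortiveSpectrum",
    "simulate_molecules",
    "emit_crac_reads",
    "emit_abortive_spectrum",
    "emit_probe_signals",
    "simulate_replicate",
    "simulate_condition",
]

FULL_LENGTH = -1  # sentinel in MoleculeOutcomes.terminated_at

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one condition.

    Defaults mirror the emulated experiment: three independent replicates,
    50,000 deduplicated CRAC events per replicate, fixed 30-nt reads, 5-nt
    UMIs (five random nucleotides in the 5' adaptor), and on average one
    extra PCR copy per unique fragment (Geometric-distributed).
    """

    n_molecules: int = 5000
    n_replicates: int = 3
    n_crac_events: int = 50000
    read_length: int | tuple[int, int] = 30
    pcr_duplication: float = 1.0
    umi_length: int = 5
    seed: int = 0
    condition: str = "WT"

    def __post_init__(self) -> None:
        if self.n_molecules <= 0 or self.n_replicates <= 0:
            raise ValueError("n_molecules and n_replicates must be positive")
        if self.pcr_duplication < 0:
            raise ValueError("pcr_duplication must be >= 0")
        if self.umi_length <= 0:
            raise ValueError("umi_length must be positive")

    def replicate_rng(self, replicate_index: int) -> np.random.Generator:
        """Independent, reproducible stream per replicate."""
        return np.random.default_rng([self.seed, replicate_index])


@dataclass(frozen=True)
class MoleculeOutcomes:
    """Per-molecule outcomes of one simulated replicate.

    ``terminated_at`` holds the 1-based termination site per molecule, or
    ``FULL_LENGTH`` (-1) for molecules that ran off the unit end.
    ``n_reached[x-1]`` counts molecules whose walk reached site x, and
    ``total_dwell[x-1]`` is their summed exponential dwell there.
    """

    terminated_at: np.ndarray
    n_reached: np.ndarray
    total_dwell: np.ndarray

    @property
    def n_molecules(self) -> int:
        return self.terminated_at.size

    @property
    def n_full_length(self) -> int:
        return int(np.count_nonzero(self.terminated_at == FULL_LENGTH))

    @property
    def full_length_fraction(self) -> float:
        return self.n_full_length / self.n_molecules


@dataclass(frozen=True)
class AbortiveSpectrum:
    """Histogram of abortive-transcript lengths (= termination sites)."""

    counts: np.ndarray          # length L; counts[x-1] = molecules released at x
    n_full_length: int

    @property
    def n_abortive(self) -> int:
        return int(self.counts.sum())

    @property
    def n_initiated(self) -> int:
        return self.n_abortive + self.n_full_length

    @property
    def proportions(self) -> np.ndarray:
        """counts / total abortive (empirical A(x)/sum A)."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    @property
    def dominant_mode(self) -> int:
        """1-based length with the highest abortive count."""
        if self.counts.sum() == 0:
            raise ValueError("empty spectrum has no mode")
        return int(np.argmax(self.counts)) + 1

    def to_frame(self) -> pd.DataFrame:
        keep = np.flatnonzero(self.counts)
        return pd.DataFrame(
            {"length_nt": keep + 1, "count": self.counts[keep].astype(int)}
        )


def simulate_molecules(model: PauseTerminationModel, n_molecules: int,
                       rng: np.random.Generator) -> MoleculeOutcomes:
    """Walk ``n_molecules`` molecules through the unit (see module docstring)."""
    hazard = np.asarray(model.kappa) * model.tau
    cum_hazard = np.cumsum(np.broadcast_to(hazard, model.tau.shape))
    draws = rng.exponential(size=n_molecules)
    idx = np.searchsorted(cum_hazard, draws, side="left")
    terminated_at = np.where(idx >= model.L, FULL_LENGTH, idx + 1)

    # molecules reaching site x: all except those terminated before x
    term_counts = np.bincount(idx.clip(max=model.L), minlength=model.L + 1)[: model.L]
    terminated_before = np.concatenate(([0], np.cumsum(term_counts[:-1])))
    n_reached = n_molecules - terminated_before

    # summed Exp(tau) dwell over n visitors is Gamma(n, tau)
    total_dwell = rng.gamma(shape=n_reached, scale=model.tau)
    total_dwell[n_reached == 0] = 0.0
    return MoleculeOutcomes(terminated_at, n_reached, total_dwell)


def _random_umis(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length))
    letters = _BASES[codes]
    return np.array(["".join(row) for row in letters.tolist()], dtype=object)


def emit_crac_reads(outcomes: MoleculeOutcomes, config: SimulationConfig,
                    rng: np.random.Generator,
                    replicate: str = "rep1") -> pd.DataFrame:
    """Sample CRAC events from the dwell-time landscape and emit a read table.

    Every event becomes a sense-strand read whose 3' end marks the polymerase
    position; each unique fragment then gains Geometric-distributed extra PCR
    copies carrying the same coordinates and UMI.
    """
    dwell = outcomes.total_dwell
    total = dwell.sum()
    if total <= 0:
        raise ValueError("no dwell time recorded; cannot sample CRAC events")
    ends = rng.choice(dwell.size, size=config.n_crac_events, p=dwell / total) + 1

    if isinstance(config.read_length, tuple):
        lo, hi = config.read_length
        lengths = rng.integers(lo, hi + 1, size=ends.size)
    else:
        lengths = np.full(ends.size, int(config.read_length))
    starts = np.maximum(1, ends - lengths + 1)
    umis = _random_umis(ends.size, config.umi_length, rng)

    if config.pcr_duplication > 0:
        m = config.pcr_duplication
        copies = rng.geometric(1.0 / (1.0 + m), size=ends.size)  # >= 1, mean 1+m
    else:
        copies = np.ones(ends.size, dtype=int)
    reads = pd.DataFrame(
        {
            "start": np.repeat(starts, copies),
            "end": np.repeat(ends, copies),
            "strand": "+",
            "umi": np.repeat(umis, copies),
            "replicate": replicate,
            "condition": config.condition,
        },
        columns=READ_COLUMNS,
    )
    return reads


def emit_abortive_spectrum(outcomes: MoleculeOutcomes) -> AbortiveSpectrum:
    """Histogram termination sites into an abortive-transcript length spectrum.

    Conservation is exact in counts: abortive + full-length = initiated.
    """
    L = outcomes.n_reached.size
    aborted = outcomes.terminated_at[outcomes.terminated_at != FULL_LENGTH]
    counts = np.bincount(aborted - 1, minlength=L)
    return AbortiveSpectrum(counts=counts, n_full_length=outcomes.n_full_length)


def simulate_replicate(model: PauseTerminationModel, config: SimulationConfig,
                       replicate_index: int) -> tuple[MoleculeOutcomes, pd.DataFrame]:
    """One replicate end to end: molecules, then the (duplicated) read table."""
    rng = config.replicate_rng(replicate_index)
    outcomes = simulate_molecules(model, config.n_molecules, rng)
    reads = emit_crac_reads(outcomes, config, rng,
                            replicate=f"rep{replicate_index + 1}")
    return outcomes, reads


def simulate_condition(model: PauseTerminationModel,
                       config: SimulationConfig) -> pd.DataFrame:
    """All replicates of one condition, concatenated into one read table."""
    frames = [simulate_replicate(model, config, k)[1]
              for k in range(config.n_replicates)]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Probe intensity tables (slot-blot TMA / northern densitometry stand-ins)
# ---------------------------------------------------------------------------

_5S_LEVEL = 100.0        # condition-independent loading-control intensity
_IGS2_LEVEL = 1e-3       # near-zero non-transcribed background


def emit_probe_signals(state: SteadyState | MoleculeOutcomes,
                       catalog: ProbeCatalog,
                       annotation: RdnaAnnotation,
                       noise_cv: float = 0.0,
                       n_replicates: int = 3,
                       rng: np.random.Generator | None = None,
                       condition: str = "WT",
                       scale: float = 1.0) -> pd.DataFrame:
    """Emit a densitometry table (condition, replicate, probe, intensity).

    Each Pol I probe's intensity is the occupancy-weighted nascent-RNA
    abundance summed over its target region (scaled by ``scale``); the two 5S
    probes get a condition-independent constant and IGS2 a near-zero
    background.  Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` is applied independently per (probe, replicate).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(state, MoleculeOutcomes):
        occupancy = state.total_dwell
    else:
        occupancy = state.occupancy
    if occupancy.size != annotation.unit_length:
        raise ValueError("occupancy length does not match annotation unit_length")

    rows = []
    for probe in catalog.probes:
        if probe.role == "control_5S":
            level = _5S_LEVEL
        elif probe.role == "background_IGS2":
            level = _IGS2_LEVEL
        else:
            try:
                reg = annotation[probe.target_region]
            except KeyError:
                raise ValueError(
                    f"probe {probe.name!r} targets unknown region "
                    f"{probe.target_region!r}"
                ) from None
            level = scale * float(occupancy[reg.start - 1 : reg.end].sum())
        for k in range(n_replicates):
            rows.append((condition, f"rep{k + 1}", probe.name, level))
    table = pd.DataFrame(rows, columns=["condition", "replicate", "probe",
                                        "intensity"])
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(table))
        table["intensity"] = table["intensity"] * noise
    return table
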