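"""Energetic cost of repeated landing attempts.

An aborted attempt commits the bird to a full landing circuit before it
can re-approach; the median circuit at the study colonies took 34 s
(range 11–58 s, n = 30).  At a literature flight power of ~144 W this
prices one loop at ~4.9 kJ, and one lesser sandeel of the size carried
to chicks (~29.4 kJ gross) covers roughly six attempts.  Flight power
and prey energy come from cited literature, not this analysis, so both
are configuration inputs rather than constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cliffwind.landing import AttemptDistribution


@dataclass(frozen=True)
class EnergeticsConfig:
    """Energetic constants: flight power (W), loop duration (s), prey energy (kJ)."""

    flight_power_w: float
    loop_duration_s: float = 34.0
    prey_energy_kj: float | None = None

    def __post_init__(self):
        if self.flight_power_w <= 0 or self.loop_duration_s <= 0:
            raise ValueError("flight power and loop duration must be > 0")
        if self.prey_energy_kj is not None and self.prey_energy_kj <= 0:
            raise ValueError("prey energy must be > 0")


def cost_per_attempt(flight_power: float, loop_duration: float = 34.0) -> float:
    """Energy of one landing loop in kJ: power (W) x duration (s) / 1000."""
    if flight_power <= 0 or loop_duration <= 0:
        raise ValueError("flight power and loop duration must be > 0")
    return flight_power * loop_duration / 1000.0


def expected_bout_cost(
    cost_kj: float,
    attempts: AttemptDistribution,
    quantiles: tuple = (0.5, 0.9, 0.95),
) -> tuple[float, dict]:
    """Expected cost of a landing bout and cost quantiles.

    A bout runs until the first success, so the attempt count is
    geometric and the expected cost is cost x 1/P.  Quantile costs are
    the geometric quantile attempt counts times the per-attempt cost.
    """
    if cost_kj <= 0:
        raise ValueError("cost per attempt must be > 0")
    expected = cost_kj * attempts.expected_attempts
    q = {p: cost_kj * attempts.quantile(p) for p in quantiles}
    return expected, q


def simulate_bout_costs(
    cost_kj: float, attempts: AttemptDistribution, n_bouts: int, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo bout costs (kJ): geometric attempt draws x cost."""
    rng = np.random.default_rng(seed)
    n = rng.geometric(attempts.P, size=int(n_bouts))
    return cost_kj * n


def attempts_per_prey_item(prey_energy_kj: float, cost_kj: float) -> float:
    """How many landing loops one prey item's gross energy pays for."""
    if prey_energy_kj <= 0 or cost_kj <= 0:
        raise ValueError("energies must be > 0")
    return prey_energy_kj / cost_kj
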