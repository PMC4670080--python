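"""Pulse-migration schedules.

A :class:`MigrationSchedule` is the demographic hypothesis object: for each
generation before present ``t`` (``t = 1`` is the sampled generation,
``t = T0`` the founding) and each source population, the fraction of the
admixed population replaced by new migrants from that source at that
generation.  The founding generation is fully specified (its fractions sum
to one); the sampled generation receives no migrants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["MigrationSchedule", "ScheduleValidationError"]

_EPS = 1e-9


class ScheduleValidationError(ValueError):
    """Raised when migration fractions violate the schedule invariants."""


@dataclass(frozen=True)
class MigrationSchedule:
    """Per-generation, per-source replacement fractions.

    Parameters
    ----------
    populations
        Ordered source-population labels (e.g. ``("EUR", "NAT", "AFR")``).
    rates
        Array of shape ``(T0 + 1, n_pops)``; ``rates[t, p]`` is the
        replacement fraction from source ``p`` at generation ``t`` before
        present.  Rows 0 and 1 must be zero.
    """

    populations: tuple[str, ...]
    rates: np.ndarray

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "populations", tuple(self.populations))
        if rates.ndim != 2 or rates.shape[1] != len(self.populations):
            raise ScheduleValidationError(
                f"rates shape {rates.shape} does not match {len(self.populations)} populations"
            )
        if rates.shape[0] < 3:
            raise ScheduleValidationError("founding must be at generation T0 >= 2")
        if np.any(rates < -_EPS) or np.any(rates > 1 + _EPS):
            raise ScheduleValidationError("migration fractions must lie in [0, 1]")
        if np.any(np.abs(rates[:2]) > _EPS):
            raise ScheduleValidationError(
                "no migration at generations 0 and 1 (the sampled generation)"
            )
        totals = rates.sum(axis=1)
        if abs(totals[-1] - 1.0) > 1e-6:
            raise ScheduleValidationError(
                f"founding generation fractions must sum to 1 (got {totals[-1]:.8f})"
            )
        if np.any(totals[:-1] > 1 + 1e-6):
            raise ScheduleValidationError("per-generation replacement fractions exceed 1")

    # ------------------------------------------------------------------
    @classmethod
    def from_pulses(
        cls,
        populations: tuple[str, ...] | list[str],
        founding_time: int,
        founding_fractions: Mapping[str, float],
        pulses: list[tuple[int, str, float]] | None = None,
    ) -> "MigrationSchedule":
        """Build from a founding event plus discrete pulses.

        ``pulses`` is a list of ``(generation, population, fraction)``;
        pulses at the same generation are summed.
        """
        populations = tuple(populations)
        T0 = int(founding_time)
        rates = np.zeros((T0 + 1, len(populations)))
        for pop, frac in founding_fractions.items():
            rates[T0, populations.index(pop)] += frac
        for t, pop, m in pulses or []:
            if not 1 < t < T0:
                raise ScheduleValidationError(
                    f"pulse at generation {t} outside (1, founding={T0})"
                )
            rates[int(t), populations.index(pop)] += m
        return cls(populations, rates)

    # ------------------------------------------------------------------
    @property
    def founding_time(self) -> int:
        return self.rates.shape[0] - 1

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    def total_inflow(self) -> np.ndarray:
        """Total replacement fraction per generation, shape ``(T0 + 1,)``."""
        return self.rates.sum(axis=1)

    def survival(self) -> np.ndarray:
        """``surv[t] = prod_{1 < s < t} (1 - M(s))``: the probability that a
        lineage sampled at generation 1 is not replaced by any migration
        event more recent than generation ``t``.  Shape ``(T0 + 1,)``."""
        M = self.total_inflow()
        surv = np.ones(self.founding_time + 1)
        for t in range(3, self.founding_time + 1):
            surv[t] = surv[t - 1] * (1.0 - M[t - 1])
        return surv

    def entry_weights(self) -> np.ndarray:
        """``a[t, p]``: probability that a sampled lineage's most recent
        migrant ancestor entered at generation ``t`` from source ``p``.

        ``a[t, p] = m_p(t) * prod_{1 < s < t} (1 - M(s))``.
        """
        T0 = self.founding_time
        M = self.total_inflow()
        a = np.zeros_like(self.rates)
        surv = 1.0
        for t in range(2, T0 + 1):
            a[t] = self.rates[t] * surv
            surv *= 1.0 - M[t]
        return a

    def proportions(self) -> dict[str, float]:
        """Schedule-implied final genome fractions per source population."""
        totals = self.entry_weights().sum(axis=0)
        return dict(zip(self.populations, totals.tolist()))

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        entries = {}
        for t in range(2, self.founding_time):
            for p, pop in enumerate(self.populations):
                if self.rates[t, p] > 0:
                    entries.setdefault(str(t), {})[pop] = float(self.rates[t, p])
        founding = {
            pop: float(self.rates[-1, p]) for p, pop in enumerate(self.populations)
        }
        return {
            "populations": list(self.populations),
            "founding_time": self.founding_time,
            "founding_fractions": founding,
            "pulses": entries,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MigrationSchedule":
        pulses = [
            (int(t), pop, m)
            for t, by_pop in d.get("pulses", {}).items()
            for pop, m in by_pop.items()
        ]
        return cls.from_pulses(
            tuple(d["populations"]),
            d["founding_time"],
            d["founding_fractions"],
            pulses,
        )
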