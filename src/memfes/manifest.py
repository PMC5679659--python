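"""Experiment manifest arithmetic: run counts and aggregate simulation time.

The study design this mirrors: five membrane systems simulated unbiased with
the protein in two states (apo, cholesterol-bound), seven repeats each — 70
unbiased runs of 400 ns, 28 microseconds total — plus 51-54 biased replicas
per system (17-18 windows times three biased CVs).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Manifest:
    """Campaign bookkeeping; all counts are positive integers."""

    n_systems: int = 5
    n_states: int = 2
    n_repeats: int = 7
    run_length_ns: float = 400.0
    n_windows: int = 17
    n_biased_cvs: int = 3
    biased_length_ns: float = 200.0

    def __post_init__(self):
        for name in ("n_systems", "n_states", "n_repeats", "n_windows",
                     "n_biased_cvs"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer")

    @property
    def n_unbiased(self) -> int:
        return count_unbiased(self.n_systems, self.n_states, self.n_repeats)

    @property
    def n_replicas(self) -> int:
        return self.n_windows * self.n_biased_cvs

    @property
    def unbiased_time_us(self) -> float:
        return total_time(self.n_unbiased, self.run_length_ns)


def count_unbiased(n_systems: int, n_states: int, n_repeats: int) -> int:
    """Number of unbiased runs: systems x protein states x repeats."""
    for v in (n_systems, n_states, n_repeats):
        if v <= 0:
            raise ValueError("counts must be positive")
    return n_systems * n_states * n_repeats


def total_time(count: int, length_ns: float) -> float:
    """Aggregate simulation time in microseconds."""
    if count < 0 or length_ns < 0:
        raise ValueError("count and length must be non-negative")
    return count * length_ns / 1000.0
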