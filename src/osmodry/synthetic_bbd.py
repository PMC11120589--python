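"""Synthetic Box-Behnken experiments with a known quadratic ground truth.

A 3-factor, 3-level Box-Behnken design places 12 runs at the edge midpoints
of the factor cube (coded +/-1 on two factors, 0 on the third) plus
replicated center points -- 15 runs with the default 3 center replicates.
Responses are simulated from a full quadratic surface on the *coded*
factors,

    y = b0 + sum_i bi xi + sum_i bii xi^2 + sum_{i<j} bij xi xj + N(0, sd),

so the sign of each linear coefficient directly encodes the ground-truth
direction of that factor's effect; this is what sensitivity-recovery tests
check against.  The default surface bundle mimics the reference beetroot
experiment qualitatively: the dehydration indices, minerals and betaine
increase with temperature and time, the antioxidant IC50s and acidity
decrease, so the synthetic optimum sits at the high-temperature /
long-time corner just as in the real data.  Noise standard deviations are
set to roughly the replicate scatter of the reference table's center runs
(about 1-4% of each response's range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import FACTORS, DesignTable

__all__ = [
    "SurfaceSpec",
    "DEFAULT_LEVELS",
    "bbd_design",
    "coded_design",
    "simulate_responses",
    "default_surfaces",
]

#: Physical factor levels (low, mid, high) of the reference experiment.
DEFAULT_LEVELS: dict[str, tuple[float, float, float]] = {
    "T": (20.0, 40.0, 60.0),
    "Conc": (60.0, 70.0, 80.0),
    "t": (1.0, 3.0, 5.0),
}

# interaction order used throughout: (T*Conc, T*t, Conc*t)
_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class SurfaceSpec:
    """A quadratic response surface on coded factors, plus Gaussian noise."""

    name: str
    beta0: float
    linear: tuple[float, float, float]
    quadratic: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interaction: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def value(self, coded: np.ndarray) -> np.ndarray:
        """Noise-free surface value at coded factor settings (n, 3)."""
        x = np.atleast_2d(np.asarray(coded, dtype=float))
        y = (self.beta0
             + x @ np.asarray(self.linear, dtype=float)
             + (x * x) @ np.asarray(self.quadratic, dtype=float))
        for coef, (i, j) in zip(self.interaction, _PAIRS):
            y = y + coef * x[:, i] * x[:, j]
        return y


def coded_design(center_replicates: int = 3) -> np.ndarray:
    """Coded 3-factor Box-Behnken matrix: 12 edge midpoints + center rows."""
    if center_replicates < 1:
        raise ValueError("need at least one center replicate")
    rows = []
    for i, j in _PAIRS:
        for si in (-1.0, 1.0):
            for sj in (-1.0, 1.0):
                row = [0.0, 0.0, 0.0]
                row[i], row[j] = si, sj
                rows.append(row)
    rows.extend([[0.0, 0.0, 0.0]] * center_replicates)
    return np.asarray(rows)


def bbd_design(levels: Mapping[str, tuple[float, float, float]] | None = None,
               center_replicates: int = 3) -> pd.DataFrame:
    """Design skeleton: run ids plus physical factor settings, no responses.

    ``levels`` maps each factor to its (low, mid, high) physical values,
    which must be strictly increasing; coded -1/0/+1 map onto them (the
    spacing may be asymmetric).
    """
    levels = dict(levels) if levels is not None else dict(DEFAULT_LEVELS)
    if list(levels) != FACTORS:
        raise ValueError(f"levels must define exactly the factors {FACTORS}")
    for name, (lo, mid, hi) in levels.items():
        if not lo < mid < hi:
            raise ValueError(f"levels of {name!r} must be strictly increasing")
    coded = coded_design(center_replicates)
    physical = np.empty_like(coded)
    for col, name in enumerate(FACTORS):
        lo, mid, hi = levels[name]
        x = coded[:, col]
        physical[:, col] = np.where(x < 0, mid + x * (mid - lo), mid + x * (hi - mid))
    frame = pd.DataFrame(physical, columns=FACTORS)
    frame.insert(0, "run", np.arange(1, len(frame) + 1))
    return frame


def simulate_responses(design: pd.DataFrame, specs: Sequence[SurfaceSpec],
                       seed: int = 0) -> DesignTable:
    """Evaluate each surface on the design and add seeded Gaussian noise.

    ``design`` is a skeleton from :func:`bbd_design` (or any frame with
    ``run`` and factor columns).  The same seed always yields a bitwise
    identical table.  Simulated values are floored at zero, matching the
    non-negativity of the physical responses.
    """
    if not specs:
        raise ValueError("need at least one surface spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate response names in surface specs")
    # recover coded settings from the physical design: -1/0/+1 per column
    coded = np.empty((len(design), len(FACTORS)))
    for col, name in enumerate(FACTORS):
        x = design[name].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        mid = np.median(np.unique(x))
        coded[:, col] = np.where(x < mid, (x - mid) / (mid - lo),
                                 (x - mid) / (hi - mid))
    rng = np.random.default_rng(seed)
    out = design[["run", *FACTORS]].copy()
    for spec in specs:
        y = spec.value(coded)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
        out[spec.name] = np.clip(y, 0.0, None)
    return DesignTable(out)


def default_surfaces() -> list[SurfaceSpec]:
    """Surface bundle qualitatively mimicking the reference experiment.

    Benefit responses rise with temperature and time, the IC50s and acidity
    fall, and concentration plays a weaker mixed role; magnitudes and noise
    levels are on the scale of the reference table.
    """
    return [
        SurfaceSpec("DMC", 31.0, (6.0, 2.0, 10.0), (0.0, -1.0, 1.0), (0.5, 1.0, 0.5), 1.0),
        SurfaceSpec("WL", 0.55, (0.07, 0.03, 0.11), (-0.02, -0.01, -0.04), (0.0, 0.01, 0.0), 0.01),
        SurfaceSpec("SG", 0.020, (0.006, 0.002, 0.010), (0.0, 0.0, 0.002), (0.0, 0.002, 0.0), 0.002),
        SurfaceSpec("Mg", 340.0, (30.0, 40.0, 80.0), (0.0, 0.0, -20.0), (0.0, 0.0, 0.0), 20.0),
        SurfaceSpec("K", 13000.0, (900.0, 900.0, 3500.0), (0.0, 0.0, 0.0), (400.0, 0.0, 0.0), 300.0),
        SurfaceSpec("Na", 4500.0, (350.0, 450.0, 1300.0), (0.0, 0.0, 0.0), (0.0, 0.0, 100.0), 100.0),
        SurfaceSpec("Ca", 800.0, (250.0, 100.0, 350.0), (0.0, 0.0, 0.0), (50.0, 80.0, 0.0), 30.0),
        SurfaceSpec("DPPH", 4.9, (-0.9, -0.2, -1.0), (0.3, 0.3, 0.3), (0.0, 0.0, 0.0), 0.15),
        SurfaceSpec("ABTS", 1.4, (-0.30, -0.05, -0.35), (0.15, 0.10, 0.20), (0.0, 0.0, 0.0), 0.06),
        SurfaceSpec("flavonoids", 110.0, (5.0, -3.0, -10.0), (0.0, 0.0, 5.0), (0.0, 8.0, 0.0), 5.0),
        SurfaceSpec("phenols", 430.0, (60.0, -10.0, 30.0), (0.0, -20.0, 0.0), (0.0, 40.0, 0.0), 25.0),
        SurfaceSpec("acidity", 1.30, (-0.05, 0.02, -0.10), (0.0, 0.0, 0.0), (0.0, -0.02, 0.0), 0.05),
        SurfaceSpec("betaine", 2200.0, (350.0, 200.0, 800.0), (0.0, 0.0, 0.0), (0.0, 120.0, 0.0), 50.0),
    ]
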