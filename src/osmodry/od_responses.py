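"""Osmotic-dehydration response indices from gravimetric mass balances.

A run's mass balance consists of the fresh and post-dehydration sample
masses and the water / dry-matter mass fractions at both states.  From it
the three standard indices follow:

dry matter content
    ``DMC = 100 * m_d / m`` with the denominator either the post-process
    (measured) mass -- the usual gravimetric convention and the default --
    or the fresh mass.
water loss
    ``WL = (m_i * z_i - m_f * z_f) / m_i`` in g water per g fresh sample.
solid gain
    ``SG = (m_f * s_f - m_i * s_i) / m_i`` in g solids per g fresh sample.

Because water and dry-matter fractions sum to one at both states,
``WL - SG = (m_i - m_f) / m_i`` is an algebraic identity; the
:func:`mass_balance_check` helper verifies it as a data-consistency probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "MassBalance",
    "compute_dmc",
    "compute_wl",
    "compute_sg",
    "mass_balance_check",
    "append_indices",
]

@dataclass(frozen=True)
class MassBalance:
    """Masses (g) and mass fractions (g/g) of one dehydration run.

    ``m_i``/``m_f``: fresh and post-process sample mass; ``m_d``: dry-matter
    mass; ``z_i``/``z_f``: water fractions and ``s_i``/``s_f``: dry-matter
    fractions of the fresh and processed sample.  A physically consistent
    balance has ``z + s == 1`` at both states; that is deliberately not
    enforced here so that :func:`mass_balance_check` can flag corrupted
    records instead of refusing to represent them.
    """

    m_i: float
    m_f: float
    m_d: float
    z_i: float
    z_f: float
    s_i: float
    s_f: float

    def __post_init__(self) -> None:
        for name in ("m_i", "m_f", "m_d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"mass {name} must be positive")
        for name in ("z_i", "z_f", "s_i", "s_f"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"mass fraction {name} must lie in [0, 1], got {value}")


def compute_dmc(b: MassBalance, basis: Literal["fresh", "measured"] = "measured") -> float:
    """Dry matter content in percent.

    ``basis="measured"`` (default) divides by the post-process mass, the
    oven-drying convention under which the reference table's values for
    dehydrated samples are consistent; ``basis="fresh"`` divides by the
    fresh mass.
    """
    if basis == "measured":
        denom = b.m_f
    elif basis == "fresh":
        denom = b.m_i
    else:
        raise ValueError(f"basis must be 'fresh' or 'measured', got {basis!r}")
    return 100.0 * b.m_d / denom


def compute_wl(b: MassBalance) -> float:
    """Water loss in g per g fresh sample."""
    return (b.m_i * b.z_i - b.m_f * b.z_f) / b.m_i


def compute_sg(b: MassBalance) -> float:
    """Solid gain in g per g fresh sample."""
    return (b.m_f * b.s_f - b.m_i * b.s_i) / b.m_i


class MassBalanceCheck(NamedTuple):
    ok: bool
    residual: float


def mass_balance_check(b: MassBalance, tol: float = 1e-9) -> MassBalanceCheck:
    """Verify ``WL - SG == (m_i - m_f) / m_i`` within ``tol``.

    The identity holds exactly whenever the water and dry-matter fractions
    sum to one at both states, so a violation flags inconsistent inputs.
    Returns the flag together with the signed residual.
    """
    residual = (compute_wl(b) - compute_sg(b)) - (b.m_i - b.m_f) / b.m_i
    return MassBalanceCheck(bool(abs(residual) <= tol), float(residual))


def append_indices(frame: pd.DataFrame,
                   basis: Literal["fresh", "measured"] = "measured") -> pd.DataFrame:
    """Batch entry point: append DMC, WL and SG columns to mass-balance rows.

    ``frame`` needs the :class:`MassBalance` field names as columns; a copy
    with three extra columns is returned.
    """
    out = frame.copy()
    dmc, wl, sg = [], [], []
    for _, row in frame.iterrows():
        b = MassBalance(**{f: float(row[f]) for f in
                           ("m_i", "m_f", "m_d", "z_i", "z_f", "s_i", "s_f")})
        dmc.append(compute_dmc(b, basis=basis))
        wl.append(compute_wl(b))
        sg.append(compute_sg(b))
    out["DMC"] = np.asarray(dmc)
    out["WL"] = np.asarray(wl)
    out["SG"] = np.asarray(sg)
    return out
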