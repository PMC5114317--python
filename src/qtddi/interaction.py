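"""Ion-channel block by single drugs and by two-drug combinations.

Single-drug block is the equilibrium Hill model

    E(C) = C**n / (IC50**n + C**n),          0 <= E <= 1,

with E the fractional inhibition of a current at free concentration C (µM).

Two co-administered blockers are combined per channel by one of three
interaction models, all of which assume neither synergy nor antagonism:

* capped sum      E(A,B) = min(E(A) + E(B), 1)
* Bliss           E(A,B) = E(A) + E(B) - E(A)·E(B)
                  (independent action at distinct sites)
* Loewe           E(A,B) = (E(A) + E(B) - 2·E(A)·E(B)) / (1 - E(A)·E(B))
                  (dose addition: one site, one mechanism)

For fractions in (0, 1) the models are strictly ordered
Loewe <= Bliss <= capped sum, and all three reduce to E(A) when E(B) = 0.
Loewe at E(A) = E(B) = 1 has a 0/0 form and is defined as 1 by continuity.

Only two-drug combinations are supported: the Loewe expression above is a
two-drug formula and no n-drug generalisation is attempted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "HillParams",
    "ChannelInhibitionVector",
    "InteractionModel",
    "hill_inhibition",
    "combine_sum",
    "combine_bliss",
    "combine_loewe",
    "combine_channels",
    "load_drug_table",
    "block_from_concentration",
]

#: The four currents the pipeline perturbs, in fixed order.
CHANNELS = ("IKr", "IKs", "INa", "ICaL")


class InteractionModel(enum.Enum):
    """Two-drug combination rule for per-channel inhibition fractions."""

    SUM = "sum"
    BLISS = "bliss"
    LOEWE = "loewe"


@dataclass(frozen=True)
class HillParams:
    """Equilibrium concentration-block parameters for one drug on one channel.

    Parameters
    ----------
    ic50 : float
        Half-maximal inhibitory concentration, µM. Must be positive.
    hill_n : float
        Hill exponent (dimensionless), positive. 1.0 corresponds to
        one-to-one binding.
    """

    ic50: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ic50) and self.ic50 > 0):
            raise ValueError(f"ic50 must be finite and > 0, got {self.ic50!r}")
        if not (math.isfinite(self.hill_n) and self.hill_n > 0):
            raise ValueError(f"hill_n must be finite and > 0, got {self.hill_n!r}")


def _check_fraction(e: float, name: str) -> float:
    e = float(e)
    if not math.isfinite(e) or e < 0.0 or e > 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {e!r}")
    return e


@dataclass(frozen=True)
class ChannelInhibitionVector:
    """Fractional block of each of the four target currents.

    Every entry is clamped-checked to [0, 1]; the channel set is fixed to
    (IKr, IKs, INa, ICaL).
    """

    IKr: float = 0.0
    IKs: float = 0.0
    INa: float = 0.0
    ICaL: float = 0.0

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            _check_fraction(getattr(self, ch), ch)

    def as_array(self) -> np.ndarray:
        """Fractions in fixed CHANNELS order."""
        return np.array([getattr(self, ch) for ch in CHANNELS], dtype=float)

    @classmethod
    def from_mapping(cls, d: Mapping[str, float]) -> "ChannelInhibitionVector":
        unknown = set(d) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}; expected subset of {CHANNELS}")
        return cls(**{ch: float(d.get(ch, 0.0)) for ch in CHANNELS})

    def is_zero(self) -> bool:
        return all(getattr(self, ch) == 0.0 for ch in CHANNELS)


def hill_inhibition(conc_um: float, params: HillParams) -> float:
    """Fractional current block at concentration ``conc_um`` (µM).

    Strictly increasing in concentration, 0 at zero drug, and exactly 0.5
    at the IC50. Result is always in [0, 1].
    """
    c = float(conc_um)
    if not math.isfinite(c) or c < 0:
        raise ValueError(f"concentration must be finite and >= 0 µM, got {conc_um!r}")
    if c == 0.0:
        return 0.0
    # (c/ic50)**n form avoids overflow for large c with large n
    ratio = (c / params.ic50) ** params.hill_n
    return float(ratio / (1.0 + ratio))


def combine_sum(e_a: float, e_b: float) -> float:
    """Arithmetic sum of the two block fractions, capped at full block (1)."""
    e_a = _check_fraction(e_a, "e_a")
    e_b = _check_fraction(e_b, "e_b")
    return min(e_a + e_b, 1.0)


def combine_bliss(e_a: float, e_b: float) -> float:
    """Bliss independence: E(A) + E(B) - E(A)·E(B)."""
    e_a = _check_fraction(e_a, "e_a")
    e_b = _check_fraction(e_b, "e_b")
    return min(e_a + e_b - e_a * e_b, 1.0)


def combine_loewe(e_a: float, e_b: float) -> float:
    """Loewe additivity: (E(A) + E(B) - 2·E(A)·E(B)) / (1 - E(A)·E(B)).

    At E(A) = E(B) = 1 the expression is 0/0; the limit along any path in
    [0,1]² is 1, so 1.0 is returned (documented special case).
    """
    e_a = _check_fraction(e_a, "e_a")
    e_b = _check_fraction(e_b, "e_b")
    prod = e_a * e_b
    if prod == 1.0:
        return 1.0
    value = (e_a + e_b - 2.0 * prod) / (1.0 - prod)
    # floating rounding can overshoot the closed interval by an ulp
    return min(max(value, 0.0), 1.0)


_COMBINERS = {
    InteractionModel.SUM: combine_sum,
    InteractionModel.BLISS: combine_bliss,
    InteractionModel.LOEWE: combine_loewe,
}


def combine_channels(
    a: ChannelInhibitionVector,
    b: ChannelInhibitionVector,
    model: InteractionModel,
) -> ChannelInhibitionVector:
    """Element-wise combination of two drugs' block vectors under ``model``."""
    if not isinstance(model, InteractionModel):
        model = InteractionModel(model)
    fn = _COMBINERS[model]
    return ChannelInhibitionVector(
        **{ch: fn(getattr(a, ch), getattr(b, ch)) for ch in CHANNELS}
    )


def load_drug_table(path) -> dict[str, dict[str, HillParams]]:
    """Read per-drug, per-channel Hill parameters from CSV.

    Expected columns: ``drug``, ``channel`` (one of IKr/IKs/INa/ICaL),
    ``ic50_uM``, ``hill_n``. A missing (drug, channel) row means the drug
    does not block that current (E = 0).
    """
    df = pd.read_csv(path)
    required = {"drug", "channel", "ic50_uM", "hill_n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table {path} missing columns {sorted(missing)}")
    table: dict[str, dict[str, HillParams]] = {}
    for _, row in df.iterrows():
        ch = str(row["channel"])
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r} in drug table (expected one of {CHANNELS})")
        table.setdefault(str(row["drug"]), {})[ch] = HillParams(
            ic50=float(row["ic50_uM"]), hill_n=float(row["hill_n"])
        )
    return table


def block_from_concentration(
    conc_um: float, channel_params: Mapping[str, HillParams]
) -> ChannelInhibitionVector:
    """Per-channel block vector for one drug at one free concentration (µM)."""
    return ChannelInhibitionVector.from_mapping(
        {ch: hill_inhibition(conc_um, p) for ch, p in channel_params.items()}
    )
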