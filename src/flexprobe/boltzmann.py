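"""Boltzmann population free energies from state-label series.

The free-energy difference between bound-like (BL) and non-bound-like (NBL)
interface conformations is estimated from their equilibrium populations:

    n_BL / n_NBL = exp(−ΔG_BL / k_B T)

so ΔG_BL = −ln(n_BL / n_NBL), in units of k_B T (T = 300 K by default).
ΔG_open is related to ΔG_BL by a residue/ligand-specific sign convention:
for a residue whose bound-like state is *open* (Asn66 with either ligand,
Ile126 with PD-L2) the two are identical; for Ile126 with PD-L1 the
bound-like state is *closed*, so ΔG_open = −ΔG_BL.

Replicate simulations are aggregated by averaging ΔG values (not population
ratios): the mean and sample standard deviation over replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .conformational_states import MacrostateSeries, StateLabelSeries

__all__ = [
    "PopulationCounts",
    "FreeEnergyEstimate",
    "populations",
    "delta_g_bl",
    "dg_open_from_dg_bl",
    "population_ratio_from_dg",
    "aggregate_replicates",
    "KBT_300K_KCAL_PER_MOL",
]

#: k_B · 300 K in kcal/mol, for optional unit conversion of ΔG values.
KBT_300K_KCAL_PER_MOL = 0.5961

_EXCLUDED_LABEL = "unassigned"


@dataclass(frozen=True)
class PopulationCounts:
    """Frame counts in the bound-like / non-bound-like states."""

    n_bl: int
    n_nbl: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.n_bl, self.n_nbl, self.n_excluded) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_bl + self.n_nbl + self.n_excluded


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG value in k_BT with its replicate spread.

    ``convention`` records whether the value is a ΔG_BL (bound-like relative
    to non-bound-like) or a ΔG_open (open relative to closed).
    """

    dg_kbt: float
    sd_kbt: float = 0.0
    n_replicates: int = 1
    temperature_K: float = 300.0
    convention: str = "BL"

    def __post_init__(self) -> None:
        if self.sd_kbt < 0:
            raise ValueError("sd_kbt must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.convention not in ("BL", "open"):
            raise ValueError("convention must be 'BL' or 'open'")

    @property
    def dg_kcal_per_mol(self) -> float:
        return self.dg_kbt * KBT_300K_KCAL_PER_MOL * (self.temperature_K / 300.0)


def _label_list(series) -> Sequence[str]:
    if isinstance(series, (StateLabelSeries, MacrostateSeries)):
        return series.labels
    return list(series)


def populations(series, bl_state: str) -> PopulationCounts:
    """Count bound-like vs non-bound-like frames in a label series.

    ``bl_state`` names the label counted as bound-like — ``"open"`` or
    ``"closed"`` for a binary residue series, or a macrostate label such as
    ``"BL_PDL1"``.  Frames labelled ``"unassigned"`` are excluded; every
    other label counts as non-bound-like.
    """
    labels = _label_list(series)
    n_bl = sum(1 for l in labels if l == bl_state)
    n_excl = sum(1 for l in labels if l == _EXCLUDED_LABEL) if bl_state != _EXCLUDED_LABEL else 0
    n_nbl = len(labels) - n_bl - n_excl
    return PopulationCounts(n_bl=n_bl, n_nbl=n_nbl, n_excluded=n_excl)


def delta_g_bl(
    pop: PopulationCounts, temperature_K: float = 300.0
) -> FreeEnergyEstimate:
    """ΔG_BL = −ln(n_BL / n_NBL) in k_BT, from one replicate's counts.

    If either count is zero a Jeffreys-style pseudocount of 0.5 is added to
    both (with a warning) so the estimate stays finite; an error is raised
    only when both counts are zero.
    """
    n_bl, n_nbl = float(pop.n_bl), float(pop.n_nbl)
    if n_bl == 0 and n_nbl == 0:
        raise ValueError("cannot estimate ΔG: both state counts are zero")
    if n_bl == 0 or n_nbl == 0:
        warnings.warn(
            "one state never observed; applying 0.5 pseudocount to both counts",
            stacklevel=2,
        )
        n_bl += 0.5
        n_nbl += 0.5
    return FreeEnergyEstimate(
        dg_kbt=-math.log(n_bl / n_nbl),
        sd_kbt=0.0,
        n_replicates=1,
        temperature_K=temperature_K,
        convention="BL",
    )


def _open_sign(residue: str, ligand_convention: str) -> float:
    """Sign relating ΔG_open to ΔG_BL for a residue/ligand pairing."""
    res = residue.strip().lower()
    lig = ligand_convention.strip().upper().replace("_", "-")
    if res.startswith("asn") or lig == "ASN66":
        return 1.0
    if res.startswith("ile"):
        if lig == "PD-L1":
            return -1.0  # bound-like Ile126 is closed with PD-L1
        if lig == "PD-L2":
            return 1.0
        raise ValueError(f"unknown ligand convention {ligand_convention!r}")
    raise ValueError(f"unknown residue convention {residue!r}")


def dg_open_from_dg_bl(
    est: FreeEnergyEstimate, residue: str, ligand_convention: str
) -> FreeEnergyEstimate:
    """Convert between the ΔG_BL and ΔG_open conventions.

    Asn66 (both ligands) and Ile126/PD-L2 have open bound-like states, so the
    value is unchanged; Ile126/PD-L1 has a closed bound-like state, so the
    sign flips.  The conversion is an involution: applying it twice returns
    the original estimate.
    """
    sign = _open_sign(residue, ligand_convention)
    new_convention = "open" if est.convention == "BL" else "BL"
    return replace(est, dg_kbt=sign * est.dg_kbt, convention=new_convention)


def population_ratio_from_dg(dg_kbt: float, direction: str = "BL") -> float:
    """Bound-like : non-bound-like population ratio implied by a ΔG.

    ``direction="BL"``: ``dg_kbt`` is a ΔG_BL and the ratio is
    ``exp(−ΔG_BL)``.  ``direction="open"``: ``dg_kbt`` is a ΔG_open for a
    residue whose bound-like state is closed (Ile126/PD-L1 sense), so the
    ratio is ``exp(+ΔG_open)``.
    """
    if not math.isfinite(dg_kbt):
        raise ValueError("dg_kbt must be finite")
    if direction == "BL":
        return math.exp(-dg_kbt)
    if direction == "open":
        return math.exp(dg_kbt)
    raise ValueError("direction must be 'BL' or 'open'")


def aggregate_replicates(
    estimates: Iterable[FreeEnergyEstimate],
) -> FreeEnergyEstimate:
    """Mean and sample SD of ΔG across replicate estimates.

    ΔG values (not population ratios) are averaged; the SD uses the n−1
    denominator and is 0 for a single replicate.
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("need at least one estimate")
    conventions = {e.convention for e in ests}
    if len(conventions) > 1:
        raise ValueError(f"mixed conventions: {sorted(conventions)}")
    temps = {e.temperature_K for e in ests}
    if len(temps) > 1:
        raise ValueError(f"mixed temperatures: {sorted(temps)}")
    values = np.array([e.dg_kbt for e in ests])
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return FreeEnergyEstimate(
        dg_kbt=float(values.mean()),
        sd_kbt=sd,
        n_replicates=len(values),
        temperature_K=ests[0].temperature_K,
        convention=ests[0].convention,
    )
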