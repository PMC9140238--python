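"""Equilibrium competitive binding of a limiting protein to classes of genomic sites.

The model describes a silencing protein such as Sir3 partitioning between a
high-affinity primary class of sites (e.g. telomeric/HM nucleosomes plus their
recruiting factor) and one or more lower-affinity secondary classes scattered
through the genome.  Each class ``i`` is characterised by an association
constant ``Ka_i`` (uM^-1) and a site concentration ``B_i`` (uM):

    P + B_i  <=>  PB_i,      Ka_i = [PB_i] / ([P][B_i])

With the protein limiting ([P] << [B_i]) the fraction of total protein bound
to class ``i`` is

    f_i = Ka_i * B_i / (1 + sum_j Ka_j * B_j)

and in the abundant-site limit (all B equal and Ka*B >> 1) this collapses to
``f_i = Ka_i / sum_j Ka_j``, which depends only on affinity ratios.  A
mutation of the binding surface that lowers the primary affinity more than
the secondary one therefore redistributes the protein from primary to
secondary sites — the mechanism proposed for Sir3 relocalisation and the
incidental gene repression that extends chronological lifespan.

All concentrations are in uM and association constants in uM^-1; convert
before calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SiteClass",
    "BindingSystem",
    "OccupancyFractions",
    "fractional_binding",
    "fractional_binding_limit",
    "exact_occupancy",
    "redistribution_change",
]


@dataclass(frozen=True)
class SiteClass:
    """One class of binding sites: an affinity and a site concentration."""

    label: str
    Ka: float  # association constant, uM^-1
    B: float  # site concentration, uM

    def __post_init__(self) -> None:
        if self.Ka < 0:
            raise ValueError(f"site class {self.label!r}: Ka must be >= 0, got {self.Ka}")
        if self.B < 0:
            raise ValueError(f"site class {self.label!r}: B must be >= 0, got {self.B}")


@dataclass(frozen=True)
class BindingSystem:
    """A limiting protein at concentration ``P`` competing over site classes."""

    classes: tuple[SiteClass, ...]
    P: float = 0.0  # free-protein concentration in the limiting regime, uM

    def __post_init__(self) -> None:
        if self.P < 0:
            raise ValueError(f"P must be >= 0, got {self.P}")
        if len(self.classes) == 0:
            raise ValueError("at least one site class is required")


@dataclass(frozen=True)
class OccupancyFractions:
    """Fractions of total protein free and bound to each class."""

    labels: tuple[str, ...]
    f_bound: tuple[float, ...]
    f_free: float
    # populated by the exact mass-balance solver only
    P_free: float | None = None
    bound: tuple[float, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        d = {f"f_{lab}": f for lab, f in zip(self.labels, self.f_bound)}
        d["f_free"] = self.f_free
        return d


def fractional_binding(system: BindingSystem) -> OccupancyFractions:
    """Fraction of limiting protein bound to each site class.

    Valid when the protein is scarce relative to every site class, so that
    free site concentrations equal their totals:

        f_i    = Ka_i * B_i / (1 + sum_j Ka_j * B_j)
        f_free = 1 / (1 + sum_j Ka_j * B_j)
    """
    ka = np.array([c.Ka for c in system.classes], dtype=float)
    b = np.array([c.B for c in system.classes], dtype=float)
    denom = 1.0 + float(np.sum(ka * b))
    f = ka * b / denom
    return OccupancyFractions(
        labels=tuple(c.label for c in system.classes),
        f_bound=tuple(float(x) for x in f),
        f_free=1.0 / denom,
    )


def fractional_binding_limit(Ka1: float, Ka2: float) -> tuple[float, float]:
    """Bound fractions in the abundant-site limit (equal B, Ka*B >> 1).

    Returns ``(Ka1/(Ka1+Ka2), Ka2/(Ka1+Ka2))`` — the partition of the protein
    between primary and secondary classes set purely by the affinity ratio.
    """
    if Ka1 < 0 or Ka2 < 0:
        raise ValueError("association constants must be >= 0")
    total = Ka1 + Ka2
    if total == 0:
        raise ValueError("Ka1 + Ka2 must be > 0 in the abundant-site limit")
    return Ka1 / total, Ka2 / total


def exact_occupancy(P_tot: float, classes: Sequence[SiteClass]) -> OccupancyFractions:
    """Exact mass-balance solution, without the limiting-protein approximation.

    Solves for free protein ``P`` from the conservation equations

        P_tot  = P * (1 + sum_i Ka_i * B_i,free)
        B_i,free = B_i,tot / (1 + Ka_i * P)

    The right-hand side of the first equation is strictly increasing in P, so
    the root is bracketed in [0, P_tot] and found with Brent's method to
    relative tolerance 1e-12.  Serves as the reference against which the
    limiting-regime formulas can be checked.
    """
    if P_tot < 0:
        raise ValueError("P_tot must be >= 0")
    classes = tuple(classes)
    if not classes:
        raise ValueError("at least one site class is required")
    ka = np.array([c.Ka for c in classes], dtype=float)
    btot = np.array([c.B for c in classes], dtype=float)
    labels = tuple(c.label for c in classes)

    if P_tot == 0 or float(np.sum(ka * btot)) == 0:
        p_free = P_tot
        bound = np.zeros_like(ka)
    else:

        def residual(p: float) -> float:
            b_free = btot / (1.0 + ka * p)
            return p * (1.0 + float(np.sum(ka * b_free))) - P_tot

        # residual(0) = -P_tot < 0, residual(P_tot) >= 0: root is bracketed
        p_free = brentq(residual, 0.0, P_tot, xtol=1e-300, rtol=1e-12, maxiter=200)
        b_free = btot / (1.0 + ka * p_free)
        bound = ka * p_free * b_free

    return OccupancyFractions(
        labels=labels,
        f_bound=tuple(float(x) for x in bound / P_tot) if P_tot > 0 else (0.0,) * len(classes),
        f_free=float(p_free / P_tot) if P_tot > 0 else 1.0,
        P_free=float(p_free),
        bound=tuple(float(x) for x in bound),
    )


def redistribution_change(
    wt: tuple[float, float], mut: tuple[float, float]
) -> tuple[float | None, float | None]:
    """Percent change in primary/secondary bound fractions, WT -> mutant.

    Uses the abundant-site limit, so only the Ka ratios matter.  Returns
    ``(delta_primary_pct, delta_secondary_pct)`` where each entry is
    ``100 * (f_mut - f_wt) / f_wt``, or ``None`` when the WT fraction is zero
    and the relative change is undefined.
    """
    f_wt = fractional_binding_limit(*wt)
    f_mut = fractional_binding_limit(*mut)
    out: list[float | None] = []
    for fw, fm in zip(f_wt, f_mut):
        out.append(None if fw == 0 else 100.0 * (fm - fw) / fw)
    return out[0], out[1]
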