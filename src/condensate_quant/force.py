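"""Worm-like-chain force-extension analysis and condensate energetics.

Optical-trap stretch-relax cycles on a single tethered DNA report how
much work a condensing protein stores in the compacted state: the area
between the force-extension curve with protein and the bare-DNA curve is
the mechanical energy needed to strip the protein-stabilized structure,
and the extension deficit at a reference force measures how much DNA is
sequestered. Units follow trap conventions: extension in um, force in
pN, thermal energy kBT in pN*nm (4.114 at 25 C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

#: thermal energy at 25 C, pN*nm
KBT_PN_NM = 4.114
#: contour length per base pair of B-form DNA, nm
NM_PER_BP = 0.34
#: pN*um per kBT at 25 C
PN_UM_PER_KBT = KBT_PN_NM * 1e-3


@dataclass
class WLCParams:
    """Worm-like-chain parameters: Lp (nm), L0 (um), kBT (pN*nm)."""

    persistence_length_Lp: float = 50.0
    contour_length_L0: float = 16.5
    kBT: float = KBT_PN_NM
    #: optional enthalpic stretch modulus (pN); None disables the correction
    stretch_modulus_pN: float | None = None

    def __post_init__(self):
        if min(self.persistence_length_Lp, self.contour_length_L0, self.kBT) <= 0:
            raise ValueError("WLC parameters must be positive")


@dataclass
class ForceExtensionCurve:
    """One stretch or relax pass: extension (um, strictly increasing), force (pN)."""

    extension: np.ndarray
    force: np.ndarray
    direction: Literal["stretch", "relax"] = "stretch"
    cycle_index: int = 0

    def __post_init__(self):
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape:
            raise ValueError("extension and force must have equal length")
        if self.extension.size >= 2 and np.any(np.diff(self.extension) <= 0):
            raise ValueError("extension must be strictly increasing within a pass")


@dataclass
class EnergyEstimate:
    """Area between curves and the implied energy per compacted base pair."""

    area_pN_um: float
    compacted_bp: float
    energy_kBT_per_bp: float
    extension_range_um: tuple[float, float] = (0.0, 0.0)


def wlc_force(params: WLCParams, extension) -> np.ndarray:
    """Marko-Siggia interpolation force (pN) at the given extension (um).

    F = (kBT/Lp) * [ 1/(4(1-x/L0)^2) - 1/4 + x/L0 ], with an optional
    enthalpic correction replacing x/L0 by x/L0 - F/S when a stretch
    modulus S is set (solved by fixed-point iteration).
    """
    x = np.asarray(extension, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0) or np.any(x >= params.contour_length_L0):
        raise ValueError("extension must satisfy 0 <= x < L0")
    prefactor = params.kBT / params.persistence_length_Lp  # pN

    def ms(rel):
        return prefactor * (0.25 / (1 - rel) ** 2 - 0.25 + rel)

    rel = x / params.contour_length_L0
    f = ms(rel)
    if params.stretch_modulus_pN is not None:
        for _ in range(100):
            f_new = ms(np.clip(rel - f / params.stretch_modulus_pN, 0, 1 - 1e-9))
            if np.max(np.abs(f_new - f)) < 1e-12:
                f = f_new
                break
            f = f_new
    return float(f[0]) if scalar else f


def pn_um_to_kbt(area_pN_um: float, kBT: float = KBT_PN_NM) -> float:
    """Convert mechanical work in pN*um to units of kBT."""
    return area_pN_um / (kBT * 1e-3)


def kbt_to_pn_um(energy_kbt: float, kBT: float = KBT_PN_NM) -> float:
    return energy_kbt * kBT * 1e-3


def energy_between_curves(
    bare: ForceExtensionCurve,
    hp1: ForceExtensionCurve,
    compacted_bp: float,
    kBT: float = KBT_PN_NM,
) -> EnergyEstimate:
    """Integrate the force gap between the protein and bare curves.

    Both curves are linearly interpolated onto the union of their
    extension grids restricted to the overlapping range, the difference
    (F_protein - F_bare) is trapezoid-integrated in pN*um, converted to
    kBT, and divided by the number of compacted base pairs.
    """
    if compacted_bp <= 0:
        raise ValueError("compacted_bp must be positive")
    lo = max(bare.extension.min(), hp1.extension.min())
    hi = min(bare.extension.max(), hp1.extension.max())
    if lo >= hi:
        raise ValueError("curves have disjoint extension ranges")
    grid = np.union1d(bare.extension, hp1.extension)
    grid = grid[(grid >= lo) & (grid <= hi)]
    f_bare = np.interp(grid, bare.extension, bare.force)
    f_hp1 = np.interp(grid, hp1.extension, hp1.force)
    area = float(np.trapezoid(f_hp1 - f_bare, grid))
    energy_per_bp = pn_um_to_kbt(area, kBT) / compacted_bp
    return EnergyEstimate(
        area_pN_um=area,
        compacted_bp=compacted_bp,
        energy_kBT_per_bp=energy_per_bp,
        extension_range_um=(float(lo), float(hi)),
    )


def compacted_length_from_deficit(
    bare: ForceExtensionCurve,
    hp1: ForceExtensionCurve,
    at_force: float,
    total_bp: int,
) -> float:
    """Base pairs sequestered, from the extension deficit at a query force.

    The deficit dx = x_bare(F) - x_protein(F) is converted to base pairs
    using the bare curve's extension per base pair at that force,
    dx / (x_bare(F) / total_bp): sequestered DNA is removed from the
    tether at the same fractional extension as the rest of the molecule.
    """
    for curve in (bare, hp1):
        if not (curve.force.min() <= at_force <= curve.force.max()):
            raise ValueError("query force outside the measured range")
    x_bare = float(np.interp(at_force, bare.force, bare.extension))
    x_hp1 = float(np.interp(at_force, hp1.force, hp1.extension))
    deficit = x_bare - x_hp1
    return deficit / (x_bare / total_bp)


def binding_site_size(end_to_end_nm: float, nm_per_bp: float = NM_PER_BP) -> int:
    """Minimal DNA binding-site size (bp) of a protein with the given span.

    Divides the protein dimer's end-to-end distance by the DNA rise per
    base pair (0.34 nm/bp) and rounds to the nearest base pair.
    """
    if end_to_end_nm <= 0 or nm_per_bp <= 0:
        raise ValueError("inputs must be positive")
    return int(round(end_to_end_nm / nm_per_bp))


def binding_sites_per_molecule(dna_bp: float, site_bp: float) -> float:
    """Estimated valency: binding sites offered by a DNA of given length."""
    if dna_bp <= 0 or site_bp <= 0:
        raise ValueError("inputs must be positive")
    return dna_bp / site_bp


def find_ruptures(curve: ForceExtensionCurve, drop_pN: float = 2.0) -> np.ndarray:
    """Indices where force drops by more than ``drop_pN`` in one grid step.

    Sudden force drops during a stretch mark rupture of a
    protein-stabilized DNA structure; they are flagged, not modeled.
    """
    if curve.force.size < 2:
        return np.array([], dtype=int)
    return np.flatnonzero(np.diff(curve.force) < -drop_pN)
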