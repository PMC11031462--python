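"""ICL-like phakic IOL designs: completion of partial data and a surrogate table.

A posterior-chamber phakic IOL (the implantable collamer lens, ICL, being the
modelled example) is a thin meniscus lens — convex front surface, concave back
surface, both radii positive in our convention — immersed in aqueous humour
(n_A = 1.336) on both sides.  Its labelled power is the equivalent (Gullstrand)
power of the thick lens in aqueous.

Manufacturer listings are typically incomplete: negative-power designs come
with front radius, back radius and central thickness (from which the material
index can be back-calculated), while positive-power designs omit the back
radius (which can then be back-calculated from the labelled power and the
recovered index).  This module implements both completions, a parameterized
surrogate family covering the full 58-step ICL power schedule
-17.0 (0.5) -3.0 and 3.0 (0.5) 17.0 dpt, and CSV ingest/emit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .paraxial import ThickLensSpec, equivalent_power, principal_planes

__all__ = [
    "N_AQUEOUS",
    "N_PIOL_DEFAULT",
    "PIOLDesign",
    "DesignTable",
    "power_schedule",
    "back_calc_index",
    "back_calc_back_radius",
    "synth_design_table",
    "read_design_csv",
    "write_design_csv",
]

#: Refractive index of aqueous humour (Liou-Brennan schematic eye).
N_AQUEOUS = 1.336

#: Collamer index recovered from the complete negative-power design data.
N_PIOL_DEFAULT = 1.4490

#: Power-label/equivalent-power agreement required of every design (dpt).
POWER_TOL = 1e-6

_CSV_COLUMNS = ["power_dpt", "r_front_mm", "r_back_mm", "thickness_mm", "n_lens"]


@dataclass(frozen=True)
class PIOLDesign:
    """One phakic-IOL design step.

    ``power_label`` is the labelled equivalent power in dpt; ``r_front`` and
    ``r_back`` are the front/back surface radii in mm (both positive for the
    meniscus geometry), ``thickness`` the central thickness in mm and
    ``n_lens`` the material index.
    """

    power_label: float
    r_front: float
    r_back: float
    thickness: float
    n_lens: float = N_PIOL_DEFAULT

    def __post_init__(self) -> None:
        if self.r_front <= 0 or self.r_back <= 0:
            raise DesignError(
                f"design {self.power_label} dpt: meniscus radii must be positive "
                f"(got r_front={self.r_front}, r_back={self.r_back})"
            )
        if self.thickness <= 0:
            raise DesignError(f"design {self.power_label} dpt: non-positive thickness")
        err = abs(self.equivalent_power() - self.power_label)
        if err > POWER_TOL:
            raise DesignError(
                f"design {self.power_label} dpt: equivalent power deviates from "
                f"label by {err:.3g} dpt"
            )

    def as_thick_lens(self, n_ambient: float = N_AQUEOUS) -> ThickLensSpec:
        """The design as a thick lens immersed in ``n_ambient`` on both sides."""
        return ThickLensSpec(
            r_front=self.r_front,
            r_back=self.r_back,
            thickness=self.thickness,
            n_lens=self.n_lens,
            n_before=n_ambient,
            n_after=n_ambient,
        )

    def equivalent_power(self, n_ambient: float = N_AQUEOUS) -> float:
        return equivalent_power(self.as_thick_lens(n_ambient))

    def principal_planes(self, n_ambient: float = N_AQUEOUS) -> tuple[float, float]:
        return principal_planes(self.as_thick_lens(n_ambient))


@dataclass(frozen=True)
class DesignTable:
    """An ordered collection of designs, one per labelled power step."""

    designs: tuple[PIOLDesign, ...]
    provenance: str = "synthetic"  # "synthetic" | "loaded"

    def __post_init__(self) -> None:
        powers = [d.power_label for d in self.designs]
        if len(set(powers)) != len(powers):
            raise DesignError("duplicate power labels in design table")
        object.__setattr__(self, "designs", tuple(sorted(self.designs, key=lambda d: d.power_label)))

    def __iter__(self) -> Iterator[PIOLDesign]:
        return iter(self.designs)

    def __len__(self) -> int:
        return len(self.designs)

    def __getitem__(self, power: float) -> PIOLDesign:
        for d in self.designs:
            if abs(d.power_label - power) < 1e-9:
                return d
        raise KeyError(f"no design with power {power} dpt")

    @property
    def powers(self) -> np.ndarray:
        return np.array([d.power_label for d in self.designs])


def power_schedule() -> np.ndarray:
    """The 58-step labelled power schedule: -17.0 (0.5) -3.0 and 3.0 (0.5) 17.0 dpt."""
    neg = np.arange(-34, -5, 1) / 2.0
    pos = np.arange(6, 35, 1) / 2.0
    return np.concatenate([neg, pos])


def back_calc_index(
    r_front: float,
    r_back: float,
    thickness: float,
    power_label: float,
    n_ambient: float = N_AQUEOUS,
) -> float:
    """Recover the lens material index from a fully specified geometry.

    The Gullstrand equation with both surfaces against the same ambient medium
    is quadratic in the index n: with k1 = 1000 (1/r_front - 1/r_back) and
    k2 = 1000 t / (r_front r_back),

        (k1 + k2) n^2 - (k1 n_a + 2 k2 n_a + P) n + k2 n_a^2 = 0.

    The physical root (n > n_ambient) is returned; re-substitution reproduces
    the labelled power to 1e-9 dpt.
    """
    if r_front <= 0 or r_back <= 0 or thickness < 0:
        raise DesignError("back_calc_index requires a meniscus geometry")
    k1 = 1000.0 * (1.0 / r_front - 1.0 / r_back)
    k2 = 1000.0 * thickness / (r_front * r_back)
    a = k1 + k2
    b = -(k1 * n_ambient + 2.0 * k2 * n_ambient + power_label)
    c = k2 * n_ambient**2
    if a == 0.0:
        if b == 0.0:
            raise DesignError("degenerate geometry: index indeterminate")
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise DesignError("no real index solves the Gullstrand equation")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    physical = [n for n in roots if n > n_ambient]
    if not physical:
        raise DesignError(
            f"no physical index (> {n_ambient}) for power {power_label} dpt"
        )
    # With two admissible roots keep the one closest to common lens materials.
    n = min(physical)
    check = equivalent_power(
        ThickLensSpec(r_front, r_back, thickness, n, n_ambient, n_ambient)
    )
    if abs(check - power_label) > 1e-9:
        raise DesignError("index back-calculation failed to reproduce the label")
    return n


def back_calc_back_radius(
    power_label: float,
    n_lens: float,
    r_front: float,
    thickness: float,
    n_ambient: float = N_AQUEOUS,
) -> float:
    """Solve the Gullstrand equation for the missing back-surface radius (mm).

    P = P1 + P2 (1 - (t/n) P1) gives P2 in closed form, then
    r_back = 1000 (n_ambient - n_lens) / P2.  A non-positive resulting radius
    (flat or non-meniscus back surface) raises :class:`DesignError`.
    """
    if r_front <= 0:
        raise DesignError("front radius must be positive")
    p1 = 1000.0 * (n_lens - n_ambient) / r_front
    factor = 1.0 - (thickness / 1000.0 / n_lens) * p1
    if factor == 0.0:
        raise DesignError("degenerate geometry: front focus at the back surface")
    p2 = (power_label - p1) / factor
    if p2 == 0.0:
        raise DesignError(
            f"power {power_label} dpt with r_front {r_front} mm needs a flat "
            "back surface (non-meniscus)"
        )
    r_back = 1000.0 * (n_ambient - n_lens) / p2
    if r_back <= 0:
        raise DesignError(
            f"power {power_label} dpt with r_front {r_front} mm yields a "
            f"non-meniscus back radius ({r_back:.3f} mm)"
        )
    return r_back


@dataclass(frozen=True)
class ScheduleParams:
    """Parameters of the surrogate design family.

    The published patent figures were not digitized; this family preserves the
    qualitative design behaviour instead: negative lenses stay thin
    (``t_negative``), positive lenses thicken affinely from ``t_pos_low`` at
    +3 dpt to ``t_pos_high`` at +17 dpt, and the front radius falls smoothly
    (affinely) with power from ``r_front_at_minus17`` to ``r_front_at_plus17``
    within the 6-12 mm band.
    """

    n_lens: float = N_PIOL_DEFAULT
    t_negative: float = 0.2
    t_pos_low: float = 0.2
    t_pos_high: float = 0.6
    r_front_at_minus17: float = 12.0
    r_front_at_plus17: float = 6.0

    def r_front(self, power: float) -> float:
        lo, hi = self.r_front_at_minus17, self.r_front_at_plus17
        return lo + (hi - lo) * (power + 17.0) / 34.0

    def thickness(self, power: float) -> float:
        if power < 0:
            return self.t_negative
        return self.t_pos_low + (self.t_pos_high - self.t_pos_low) * (power - 3.0) / 14.0


def synth_design_table(params: ScheduleParams | None = None) -> DesignTable:
    """Generate the 58-step surrogate design table.

    Every step's back radius comes from :func:`back_calc_back_radius`, so the
    labelled power is reproduced by construction.  A schedule producing a
    non-meniscus geometry raises :class:`DesignError` naming the offending
    power step.
    """
    params = params or ScheduleParams()
    designs = []
    for p in power_schedule():
        r_front = params.r_front(p)
        t = params.thickness(p)
        try:
            r_back = back_calc_back_radius(p, params.n_lens, r_front, t)
            designs.append(
                PIOLDesign(
                    power_label=float(p),
                    r_front=r_front,
                    r_back=r_back,
                    thickness=t,
                    n_lens=params.n_lens,
                )
            )
        except DesignError as exc:
            raise DesignError(f"surrogate schedule fails at {p} dpt: {exc}") from exc
    return DesignTable(tuple(designs), provenance="synthetic")


def write_design_csv(table: DesignTable, path: str | Path) -> None:
    """Write a design table to CSV (header row, '.' decimal, full precision)."""
    frame = pd.DataFrame(
        {
            "power_dpt": [d.power_label for d in table],
            "r_front_mm": [d.r_front for d in table],
            "r_back_mm": [d.r_back for d in table],
            "thickness_mm": [d.thickness for d in table],
            "n_lens": [d.n_lens for d in table],
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g")


def read_design_csv(path: str | Path) -> DesignTable:
    """Load a design table, completing missing columns where derivable.

    Required columns: ``power_dpt``, ``r_front_mm``, ``thickness_mm``.
    Missing ``n_lens`` entries are back-calculated from rows that are fully
    specified (``r_back_mm`` present); missing ``r_back_mm`` entries are then
    completed from the labelled power and the (mean recovered) index.  Rows
    lacking both routes raise :class:`DesignError` with the row number.
    """
    frame = pd.read_csv(path)
    missing = [c for c in ("power_dpt", "r_front_mm", "thickness_mm") if c not in frame]
    if missing:
        raise DesignError(f"design CSV lacks required columns {missing}")
    if "r_back_mm" not in frame:
        frame["r_back_mm"] = np.nan
    if "n_lens" not in frame:
        frame["n_lens"] = np.nan

    # Pass 1: recover the index from fully specified rows.
    recovered: list[float] = []
    for i, row in frame.iterrows():
        if np.isfinite(row["n_lens"]):
            continue
        if np.isfinite(row["r_back_mm"]):
            try:
                recovered.append(
                    back_calc_index(
                        row["r_front_mm"],
                        row["r_back_mm"],
                        row["thickness_mm"],
                        row["power_dpt"],
                    )
                )
            except DesignError as exc:
                raise DesignError(f"row {i}: {exc}") from exc
    consensus = float(np.mean(recovered)) if recovered else np.nan

    designs = []
    for i, row in frame.iterrows():
        n_lens = row["n_lens"]
        if not np.isfinite(n_lens):
            if np.isfinite(row["r_back_mm"]):
                n_lens = back_calc_index(
                    row["r_front_mm"], row["r_back_mm"], row["thickness_mm"], row["power_dpt"]
                )
            elif np.isfinite(consensus):
                n_lens = consensus
            else:
                raise DesignError(
                    f"row {i}: neither n_lens nor r_back_mm given and no "
                    "complete row to recover the index from"
                )
        r_back = row["r_back_mm"]
        if not np.isfinite(r_back):
            r_back = back_calc_back_radius(
                row["power_dpt"], n_lens, row["r_front_mm"], row["thickness_mm"]
            )
        try:
            designs.append(
                PIOLDesign(
                    power_label=float(row["power_dpt"]),
                    r_front=float(row["r_front_mm"]),
                    r_back=float(r_back),
                    thickness=float(row["thickness_mm"]),
                    n_lens=float(n_lens),
                )
            )
        except DesignError as exc:
            raise DesignError(f"row {i}: {exc}") from exc
    return DesignTable(tuple(designs), provenance="loaded")
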