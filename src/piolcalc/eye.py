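"""Phakic model eye: refraction correction REF and magnification change dM.

The postoperative eye is fully corrected by the implanted phakic IOL: a plane
wave (object at infinity) refracted by the cornea and the PIOL produces the
vergence V_SLPOS just behind the PIOL back surface plane.  Tracing V_SLPOS
backwards through the preoperative eye (cornea only, no PIOL) out to the
spectacle plane yields the spectacle-plane refraction correction REF that the
implant replaces.

Four model scenarios combine thick/thin treatments of cornea and PIOL:

* A - thick cornea (front/back radii + central thickness, n_C = 1.376),
      thick PIOL (design geometry, back vertex at SLPOS);
* B - thin cornea (keratometric power PC = (n_K - 1)/RC_a at the front
      vertex, aqueous behind), thick PIOL;
* C - thick cornea, thin PIOL of the labelled equivalent power at SLPOS;
* D - thin cornea, thin PIOL.

SLPOS, the axial position of the PIOL back surface (thick model) or of the
thin-lens plane, sits ACD - vault behind the corneal front vertex
(equivalently AQD - vault behind the corneal back vertex).

The relative change in lateral magnification when the spectacle correction is
replaced by the PIOL correction is taken from the per-surface vergence ratios

    dM = 100 * (prod(V_po)/prod(V'_po) * prod(V'_pr)/prod(V_pr) - 1)

over refracting surfaces only (translations drop out).  For an object at
infinity the incoming vergence at the first surface is zero both pre- and
postoperatively; this shared factor is cancelled symbolically, which equals
the finite-object-distance limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence, Union

from .design import DesignTable, PIOLDesign
from .errors import GeometryError, OpticsError
from .paraxial import (
    Element,
    Gap,
    RefractiveSurface,
    ThinLens,
    Vergence,
    propagate,
    refract,
    trace,
    translate,
)

__all__ = [
    "EyeBiometry",
    "ScenarioConfig",
    "CorrectionResult",
    "MagnificationTrace",
    "build_system",
    "solve_ref",
    "resubstitute_ref",
    "delta_m",
    "delta_m_finite_object",
    "magnification_trace",
    "scan_power_range",
]

Scenario = Literal["A", "B", "C", "D"]

#: Keratometer index used to convert the front radius to keratometric power.
N_KERATOMETER = 1.3375


@dataclass(frozen=True)
class EyeBiometry:
    """One eye's anterior-segment geometry (all lengths in mm).

    ``aqd`` runs from the corneal endothelium to the crystalline lens front
    apex; the anterior chamber depth is the derived identity
    ``acd = aqd + cct``.  ``pc`` is the keratometric corneal power
    (n_K - 1)/RC_a in dpt.
    """

    rc_a: float
    rc_p: float
    cct: float
    aqd: float
    lt: float

    def __post_init__(self) -> None:
        for name in ("rc_a", "rc_p", "cct", "aqd", "lt"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"biometry field {name} must be positive")

    @property
    def acd(self) -> float:
        return self.aqd + self.cct

    @property
    def pc(self) -> float:
        return 1000.0 * (N_KERATOMETER - 1.0) / self.rc_a


@dataclass(frozen=True)
class ScenarioConfig:
    """Model scenario plus the geometric and optical constants.

    ``vault`` is the clearance between the PIOL back surface and the
    crystalline lens front apex; ``vd`` the spectacle back vertex distance.
    Defaults follow the cohort-simulation conventions (vault 0.4 mm,
    VD 12 mm); clinical refractions may use other vertex distances.
    """

    scenario: Scenario = "A"
    vault: float = 0.4
    vd: float = 12.0
    n_c: float = 1.376
    n_k: float = N_KERATOMETER
    n_a: float = 1.336

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.vault < 0:
            raise GeometryError("negative vault")
        if self.vd <= 0:
            raise GeometryError("vertex distance must be positive")

    @property
    def thick_cornea(self) -> bool:
        return self.scenario in ("A", "C")

    @property
    def thick_piol(self) -> bool:
        return self.scenario in ("A", "B")


@dataclass(frozen=True)
class CorrectionResult:
    """REF (dpt), dM (%) and the intermediates for one eye x design x scenario."""

    ref: float
    delta_m: float
    slpos: float
    v_slpos: Vergence
    scenario: Scenario


@dataclass(frozen=True)
class MagnificationTrace:
    """Per-refraction (V, V') pairs for the pre- and postoperative systems."""

    pre: tuple[tuple[Vergence, Vergence], ...]
    post: tuple[tuple[Vergence, Vergence], ...]


def _cornea_elements(eye: EyeBiometry, cfg: ScenarioConfig) -> list[Element]:
    """Corneal element chain from air to aqueous, starting at the front vertex."""
    if cfg.thick_cornea:
        return [
            RefractiveSurface(eye.rc_a, 1.0, cfg.n_c),
            Gap(eye.cct, cfg.n_c),
            RefractiveSurface(eye.rc_p, cfg.n_c, cfg.n_a),
        ]
    # Thin cornea: a single keratometric surface at the front vertex with
    # aqueous directly behind, so ACD-referenced distances stay meaningful.
    pc = 1000.0 * (cfg.n_k - 1.0) / eye.rc_a
    return [ThinLens(pc, 1.0, cfg.n_a)]


def build_system(
    eye: EyeBiometry,
    piol: Union[PIOLDesign, float],
    cfg: ScenarioConfig,
    phase: Literal["pre", "post"] = "post",
) -> list[Element]:
    """Assemble the ordered element chain for one phase of one scenario.

    The postoperative chain runs from the corneal front vertex to SLPOS (the
    exit plane just behind the PIOL).  The preoperative chain runs from the
    spectacle plane (a zero-power placeholder thin lens at -VD, replaced by
    the solved correction) to the corneal exit; :func:`solve_ref` appends the
    remaining aqueous gap to SLPOS.

    Thick-PIOL scenarios (A, B) require a :class:`PIOLDesign`; thin-PIOL
    scenarios (C, D) a bare equivalent power in dpt.
    """
    slpos = eye.acd - cfg.vault
    if phase == "pre":
        return [
            ThinLens(0.0, 1.0),
            Gap(cfg.vd, 1.0),
            *_cornea_elements(eye, cfg),
        ]

    elements = _cornea_elements(eye, cfg)
    if cfg.thick_piol:
        if not isinstance(piol, PIOLDesign):
            raise TypeError(f"scenario {cfg.scenario} needs a PIOLDesign, got {piol!r}")
        # Gap from the corneal exit to the PIOL front vertex.
        if cfg.thick_cornea:
            gap = eye.aqd - cfg.vault - piol.thickness
        else:
            gap = slpos - piol.thickness
        if gap < 0:
            raise GeometryError(
                f"PIOL front vertex ahead of the corneal exit: AQD {eye.aqd} mm, "
                f"vault {cfg.vault} mm, PIOLT {piol.thickness} mm"
            )
        elements += [
            Gap(gap, cfg.n_a),
            RefractiveSurface(piol.r_front, cfg.n_a, piol.n_lens),
            Gap(piol.thickness, piol.n_lens),
            RefractiveSurface(piol.r_back, piol.n_lens, cfg.n_a),
        ]
    else:
        power = piol.power_label if isinstance(piol, PIOLDesign) else float(piol)
        gap = eye.aqd - cfg.vault if cfg.thick_cornea else slpos
        if gap < 0:
            raise GeometryError("SLPOS lies ahead of the corneal exit")
        elements += [Gap(gap, cfg.n_a), ThinLens(power, cfg.n_a)]
    return elements


def _propagate_chain(v: Vergence, elements: Sequence[Element]) -> Vergence:
    for el in elements:
        if isinstance(el, Gap):
            v = translate(v, el.distance)
        else:
            v = refract(v, el.power, el.n_after)
    return v


def _invert_chain(v: Vergence, elements: Sequence[Element]) -> Vergence:
    """Trace a vergence backwards (exit to entrance) through a chain."""
    for el in reversed(elements):
        if isinstance(el, Gap):
            v = translate(v, -el.distance)
        else:
            v = Vergence(v.value - el.power, el.n_before)
    return v


def solve_ref(
    eye: EyeBiometry,
    piol: Union[PIOLDesign, float],
    cfg: ScenarioConfig,
    with_delta_m: bool = True,
) -> CorrectionResult:
    """Compute the spectacle-plane refraction correction for one implant.

    Forward-propagates a plane wave through the postoperative system to
    V_SLPOS, then inverts the preoperative chain (cornea, vertex gap) from
    SLPOS back to the spectacle plane; the emerging vergence is REF, exactly
    (closed form, no iteration).
    """
    slpos = eye.acd - cfg.vault
    post = build_system(eye, piol, cfg, "post")
    v_slpos = _propagate_chain(Vergence(0.0, 1.0), post)

    # Preoperative chain from SLPOS backwards: aqueous gap to the corneal
    # exit, the cornea, then VD of air to the spectacle plane.
    cornea = _cornea_elements(eye, cfg)
    gap_to_cornea = eye.aqd - cfg.vault if cfg.thick_cornea else slpos
    v = translate(v_slpos, -gap_to_cornea)
    v = _invert_chain(v, cornea)
    v = translate(v, -cfg.vd)
    ref = v.value

    dm = math.nan
    if with_delta_m:
        # REF = 0 means pre- and postoperative correction states coincide;
        # the product formula degenerates (0/0) but its limit is zero change.
        dm = 0.0 if ref == 0.0 else _delta_m_from_ref(eye, piol, cfg, ref)
    return CorrectionResult(ref=ref, delta_m=dm, slpos=slpos, v_slpos=v_slpos, scenario=cfg.scenario)


def resubstitute_ref(eye: EyeBiometry, cfg: ScenarioConfig, ref: float) -> Vergence:
    """Forward-propagate a spectacle correction to the SLPOS plane.

    Pushes a plane wave through [thin spectacle lens of power ``ref`` at -VD,
    cornea, aqueous gap] out to SLPOS.  For a solved correction this must
    reproduce ``CorrectionResult.v_slpos`` exactly (self-consistency check).
    """
    chain: list[Element] = [
        ThinLens(ref, 1.0),
        Gap(cfg.vd, 1.0),
        *_cornea_elements(eye, cfg),
        Gap(eye.aqd - cfg.vault if cfg.thick_cornea else eye.acd - cfg.vault, cfg.n_a),
    ]
    return _propagate_chain(Vergence(0.0, 1.0), chain)


def magnification_trace(
    eye: EyeBiometry,
    piol: Union[PIOLDesign, float],
    cfg: ScenarioConfig,
    ref: float,
    object_vergence: float = 0.0,
) -> MagnificationTrace:
    """Record the (V, V') pair at every refracting surface pre and post.

    The preoperative chain carries a thin spectacle lens of power ``ref`` at
    the spectacle plane; both chains start from the same object vergence at
    their first surface (zero for an object at infinity).
    """
    pre = [
        ThinLens(ref, 1.0),
        Gap(cfg.vd, 1.0),
        *_cornea_elements(eye, cfg),
    ]
    post = build_system(eye, piol, cfg, "post")
    v0_pre = Vergence(object_vergence, 1.0)
    # Post chain first surface sits VD further along; identical incoming
    # vergence only holds exactly for the object at infinity.
    v0_post = (
        Vergence(object_vergence, 1.0)
        if object_vergence == 0.0
        else translate(Vergence(object_vergence, 1.0), cfg.vd)
    )
    return MagnificationTrace(pre=tuple(trace(v0_pre, pre)), post=tuple(trace(v0_post, post)))


def _delta_m_from_ref(
    eye: EyeBiometry,
    piol: Union[PIOLDesign, float],
    cfg: ScenarioConfig,
    ref: float,
) -> float:
    tr = magnification_trace(eye, piol, cfg, ref)
    # The first-surface incoming vergence is zero in both chains (object at
    # infinity); its ratio tends to one and is cancelled symbolically.
    ratio = 1.0
    for v, v_out in tr.post:
        if v_out.value == 0.0:
            raise OpticsError("zero outgoing vergence in the postoperative chain")
        ratio /= v_out.value
    for v, _ in tr.post[1:]:
        ratio *= v.value
    for v, v_out in tr.pre:
        ratio *= v_out.value
    for v, _ in tr.pre[1:]:
        if v.value == 0.0:
            raise OpticsError("zero incoming vergence in the preoperative chain")
        ratio /= v.value
    return 100.0 * (ratio - 1.0)


def delta_m(
    eye: EyeBiometry,
    piol: Union[PIOLDesign, float],
    cfg: ScenarioConfig,
) -> float:
    """Relative lateral-magnification change in percent (positive = gain)."""
    return solve_ref(eye, piol, cfg).delta_m


def delta_m_finite_object(
    eye: EyeBiometry,
    piol: Union[PIOLDesign, float],
    cfg: ScenarioConfig,
    object_distance_m: float = 1.0e6,
) -> float:
    """dM evaluated at a large finite object distance (limit oracle).

    The object sits ``object_distance_m`` in front of the spectacle plane, so
    no vergence in either chain is exactly zero and the raw product formula
    applies without cancellation.
    """
    ref = solve_ref(eye, piol, cfg, with_delta_m=False).ref
    v_obj = -1.0 / object_distance_m
    tr = magnification_trace(eye, piol, cfg, ref, object_vergence=v_obj)
    ratio = 1.0
    for v, v_out in tr.post:
        ratio *= v.value / v_out.value
    for v, v_out in tr.pre:
        ratio *= v_out.value / v.value
    return 100.0 * (ratio - 1.0)


def scan_power_range(
    eye: EyeBiometry,
    table: DesignTable,
    cfg: ScenarioConfig,
) -> list[CorrectionResult]:
    """REF and dM across every design step, ordered by labelled power."""
    results = []
    for design in table:
        piol: Union[PIOLDesign, float] = design if cfg.thick_piol else design.power_label
        results.append(solve_ref(eye, piol, cfg))
    return results
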