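"""Paraxial (Gaussian) optics primitives on the vergence representation.

Sign convention
---------------
Light travels from left to right.  Axial distances are positive towards the
right; a surface radius is positive when its centre of curvature lies to the
right of the vertex (i.e. the surface is convex towards the incoming light).
Vergence is positive for converging wavefronts.  Geometry is expressed in
millimetres at the API surface and converted to metres only inside the
arithmetic; optical powers are always in dioptres (dpt).

Two equivalent propagation machineries are provided:

* vergence algebra (:func:`refract`, :func:`translate`), the working
  representation used by the eye model, and
* 2x2 ray-transfer matrices in the reduced-angle convention
  (:func:`system_matrix`), which serve as an independent oracle: both must
  agree to numerical precision for any valid element chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .errors import GeometryError, OpticsError

__all__ = [
    "FLAT",
    "Vergence",
    "RefractiveSurface",
    "ThinLens",
    "Gap",
    "ThickLensSpec",
    "SystemMatrix",
    "surface_power",
    "refract",
    "translate",
    "equivalent_power",
    "principal_planes",
    "system_matrix",
    "propagate",
    "trace",
]


class _Flat:
    """Sentinel for a planar refracting surface (power 0 at any index step)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "FLAT"


#: Sentinel radius marking a flat (planar) surface.
FLAT = _Flat()

Radius = Union[float, _Flat]


@dataclass(frozen=True)
class Vergence:
    """A wavefront curvature in dpt together with the medium it lives in.

    ``value`` is the reduced curvature n/l (l in metres, signed distance from
    the wavefront to its focus); ``medium_index`` is the refractive index of
    the medium the wavefront currently travels in.
    """

    value: float
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise OpticsError(f"non-finite vergence value {self.value!r}")
        if self.medium_index < 1.0:
            raise OpticsError(
                f"refractive index {self.medium_index} below 1.0 (vacuum)"
            )


@dataclass(frozen=True)
class RefractiveSurface:
    """A single refracting interface between two media.

    ``radius`` is in mm (or :data:`FLAT`); ``axial_position`` locates the
    vertex relative to an arbitrary stated reference, in mm, and is carried
    as bookkeeping only — propagation uses explicit :class:`Gap` elements.
    """

    radius: Radius
    n_before: float
    n_after: float
    axial_position: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.radius, _Flat) and self.radius == 0.0:
            raise OpticsError("zero surface radius; use FLAT for a planar surface")
        if self.n_before < 1.0 or self.n_after < 1.0:
            raise OpticsError("refractive indices must be >= 1")

    @property
    def power(self) -> float:
        """Surface power in dpt."""
        return surface_power(self.n_before, self.n_after, self.radius)


@dataclass(frozen=True)
class ThinLens:
    """An ideal thin element of given power (dpt).

    Usually immersed in a single medium (``n_after`` defaults to
    ``n_before``); a thin *surface* separating two media — e.g. the
    keratometric cornea with air in front and aqueous behind — sets both.
    """

    power: float
    n_before: float = 1.0
    n_after: float | None = None

    def __post_init__(self) -> None:
        if self.n_after is None:
            object.__setattr__(self, "n_after", self.n_before)
        if self.n_before < 1.0 or self.n_after < 1.0:
            raise OpticsError("refractive indices must be >= 1")


@dataclass(frozen=True)
class Gap:
    """Homogeneous propagation over ``distance`` mm in a medium of index ``n``."""

    distance: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise GeometryError(f"negative gap of {self.distance} mm")
        if self.n < 1.0:
            raise OpticsError(f"gap index {self.n} below 1.0")


Element = Union[RefractiveSurface, ThinLens, Gap]


@dataclass(frozen=True)
class ThickLensSpec:
    """A homogeneous thick lens with two spherical surfaces.

    Radii in mm, central thickness in mm.  ``n_before``/``n_after`` are the
    ambient media in front of and behind the lens.
    """

    r_front: Radius
    r_back: Radius
    thickness: float
    n_lens: float
    n_before: float = 1.0
    n_after: float = 1.0

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise OpticsError("negative lens thickness")
        if self.n_lens <= max(self.n_before, self.n_after):
            raise OpticsError(
                "lens index must exceed the ambient media for the lenses modelled here"
            )

    @property
    def front_power(self) -> float:
        return surface_power(self.n_before, self.n_lens, self.r_front)

    @property
    def back_power(self) -> float:
        return surface_power(self.n_lens, self.n_after, self.r_back)

    def elements(self) -> list[Element]:
        """The lens as an ordered element chain (front surface, gap, back surface)."""
        return [
            RefractiveSurface(self.r_front, self.n_before, self.n_lens),
            Gap(self.thickness, self.n_lens),
            RefractiveSurface(self.r_back, self.n_lens, self.n_after),
        ]


def surface_power(n_before: float, n_after: float, radius: Radius) -> float:
    """Power of a single refracting surface in dpt.

    ``radius`` in mm; a :data:`FLAT` surface has zero power regardless of the
    index step.
    """
    if isinstance(radius, _Flat):
        return 0.0
    if radius == 0.0:
        raise OpticsError("zero surface radius; use FLAT for a planar surface")
    return 1000.0 * (n_after - n_before) / radius


def refract(v: Vergence, power: float, n_after: float) -> Vergence:
    """Refract a vergence at a surface of the given power (dpt).

    Vergence addition: V' = V + P, with the wavefront continuing in the
    medium of index ``n_after``.  Exactly invertible by ``refract(v', -P,
    n_before)``.
    """
    return Vergence(v.value + power, n_after)


def translate(v: Vergence, distance_mm: float) -> Vergence:
    """Transfer a vergence over ``distance_mm`` of its own medium.

    V' = V / (1 - (d/n) V) with d in metres.  Raises :class:`OpticsError` if
    the wavefront comes to a focus exactly at the target plane.  Negative
    distances perform the exact inverse transfer.
    """
    d = distance_mm / 1000.0 / v.medium_index
    denom = 1.0 - d * v.value
    if denom == 0.0:
        raise OpticsError(
            f"vergence {v.value} dpt focuses exactly at the target plane "
            f"({distance_mm} mm away)"
        )
    return Vergence(v.value / denom, v.medium_index)


# ---------------------------------------------------------------------------
# Ray-transfer matrices (reduced-angle convention): the oracle machinery.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SystemMatrix:
    """2x2 paraxial ray-transfer matrix acting on (y, n*u) column vectors.

    In the reduced-angle convention every elementary matrix — and hence every
    product — has unit determinant.  ``b`` carries units of metres, ``c`` of
    dpt; ``a`` and ``d`` are dimensionless.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        det = self.a * self.d - self.b * self.c
        if abs(det - 1.0) > 1e-9:
            raise OpticsError(f"system matrix determinant {det} != 1")

    def __matmul__(self, other: "SystemMatrix") -> "SystemMatrix":
        return SystemMatrix(
            self.a * other.a + self.b * other.c,
            self.a * other.b + self.b * other.d,
            self.c * other.a + self.d * other.c,
            self.c * other.b + self.d * other.d,
        )

    @classmethod
    def identity(cls) -> "SystemMatrix":
        return cls(1.0, 0.0, 0.0, 1.0)

    @classmethod
    def refraction(cls, power_dpt: float) -> "SystemMatrix":
        return cls(1.0, 0.0, -power_dpt, 1.0)

    @classmethod
    def translation(cls, distance_mm: float, n: float) -> "SystemMatrix":
        return cls(1.0, distance_mm / 1000.0 / n, 0.0, 1.0)

    @property
    def equivalent_power(self) -> float:
        """Equivalent power of the system in dpt (the -C entry)."""
        return -self.c

    def propagate_vergence(self, v: Vergence, n_after: float) -> Vergence:
        """Map an input vergence through the system.

        With rays (y, n*u) and V = -n*u/y, the bilinear map is
        V' = (D V - C) / (A - B V).
        """
        denom = self.a - self.b * v.value
        if denom == 0.0:
            raise OpticsError("vergence focuses inside the system aperture plane")
        return Vergence((self.d * v.value - self.c) / denom, n_after)


def _element_matrix(el: Element) -> SystemMatrix:
    if isinstance(el, Gap):
        return SystemMatrix.translation(el.distance, el.n)
    if isinstance(el, ThinLens):
        return SystemMatrix.refraction(el.power)
    return SystemMatrix.refraction(el.power)


def _check_media(elements: Sequence[Element]) -> None:
    n_current: float | None = None
    for i, el in enumerate(elements):
        if isinstance(el, Gap):
            n_in = n_out = el.n
        else:
            n_in, n_out = el.n_before, el.n_after
        if n_current is not None and abs(n_in - n_current) > 1e-12:
            raise GeometryError(
                f"element {i}: medium index {n_in} does not match the "
                f"preceding element's exit medium {n_current}"
            )
        n_current = n_out


def system_matrix(elements: Iterable[Element]) -> SystemMatrix:
    """Compose the ray-transfer matrix of an ordered element chain.

    Elements are listed in the order light meets them; adjacent elements must
    agree on the medium between them.  An empty chain gives the identity.
    """
    elements = list(elements)
    _check_media(elements)
    m = SystemMatrix.identity()
    for el in elements:
        m = _element_matrix(el) @ m
    return m


def propagate(v: Vergence, elements: Iterable[Element]) -> Vergence:
    """Push a vergence through an element chain with refract/translate."""
    elements = list(elements)
    _check_media(elements)
    for el in elements:
        if isinstance(el, Gap):
            v = translate(v, el.distance)
        elif isinstance(el, ThinLens):
            v = refract(v, el.power, el.n_after)
        else:
            v = refract(v, el.power, el.n_after)
    return v


def trace(v: Vergence, elements: Iterable[Element]) -> list[tuple[Vergence, Vergence]]:
    """Propagate and record the (incoming, outgoing) vergence at each surface.

    Gaps advance the wavefront but contribute no pair; the returned list has
    one entry per refracting element, in order.
    """
    elements = list(elements)
    _check_media(elements)
    pairs: list[tuple[Vergence, Vergence]] = []
    for el in elements:
        if isinstance(el, Gap):
            v = translate(v, el.distance)
        else:
            v_out = refract(v, el.power, el.n_after)
            pairs.append((v, v_out))
            v = v_out
    return pairs


# ---------------------------------------------------------------------------
# Thick-lens reductions.
# ---------------------------------------------------------------------------


def equivalent_power(lens: ThickLensSpec) -> float:
    """Equivalent power of a thick lens by the Gullstrand formula (dpt).

    P = P1 + P2 - (t/n) P1 P2 with the reduced thickness t/n in metres.  The
    thin-lens limit t -> 0 recovers P1 + P2.
    """
    p1 = lens.front_power
    p2 = lens.back_power
    t_m = lens.thickness / 1000.0
    return p1 + p2 - (t_m / lens.n_lens) * p1 * p2


def principal_planes(lens: ThickLensSpec) -> tuple[float, float]:
    """Principal-plane offsets of a thick lens, in mm.

    Returns ``(front_offset, back_offset)``: the object-side principal plane
    lies ``front_offset`` mm to the right of the front vertex, the image-side
    principal plane ``back_offset`` mm to the right of the back vertex.  A
    thin lens of the equivalent power straddling these planes reproduces the
    lens's ray-transfer matrix exactly.
    """
    p = equivalent_power(lens)
    if p == 0.0:
        raise OpticsError("principal planes undefined for an afocal lens")
    p1 = lens.front_power
    p2 = lens.back_power
    t = lens.thickness
    front = lens.n_before * t * p2 / (lens.n_lens * p)
    back = -lens.n_after * t * p1 / (lens.n_lens * p)
    return front, back
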