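"""Synthetic biometry cohorts and preprocessing of anterior-segment OCT exports.

The Monte-Carlo study needs a cohort of anterior-segment biometry records
(corneal front/back radii, central corneal thickness, aqueous depth, lens
thickness).  The source population is characterised only by its descriptive
statistics (means, SDs, quantiles), so :func:`sample_cohort` regenerates a
cohort from a truncated multivariate normal with those marginals; the
published summary statistics are the generator defaults.

For real swept-source OCT exports (Casia-style CSV), :func:`preprocess`
applies the study's selection rules: meridian averaging, random one-eye-per-
patient selection, duplicate removal, and the manufacturer's aqueous-depth
floor of 2.8 mm for posterior-chamber phakic IOL implantation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CohortError
from .eye import EyeBiometry

__all__ = [
    "TABLE_STATS",
    "RawCasiaRecord",
    "CohortSpec",
    "average_meridians",
    "preprocess",
    "sample_cohort",
    "mean_eye",
    "cohort_frame",
    "read_biometry_csv",
    "write_cohort_csv",
]

#: Descriptive statistics of the reference population (N = 2365 eyes after
#: preprocessing): mean and SD per parameter.  These are the generator
#: defaults for synthetic cohorts.
TABLE_STATS: dict[str, tuple[float, float]] = {
    "rc_a": (7.7633, 0.2854),
    "rc_p": (6.5751, 0.2473),
    "cct": (0.5434, 0.0366),
    "aqd": (3.1256, 0.2381),
    "lt": (3.9217, 0.2024),
}

_PARAMS = list(TABLE_STATS)

#: Minimum aqueous depth (mm) recommended for phakic IOL implantation.
AQD_MIN_DEFAULT = 2.8


def _default_correlation() -> np.ndarray:
    """Physiologically plausible default correlations.

    The population correlations are not published; the front and back corneal
    radii are strongly coupled (0.9) and deeper chambers go with thinner
    crystalline lenses (-0.3).  The optical responses are near-deterministic
    functions of the predictors, so the regression results of interest are
    insensitive to this choice.
    """
    corr = np.eye(len(_PARAMS))
    i = {p: k for k, p in enumerate(_PARAMS)}
    corr[i["rc_a"], i["rc_p"]] = corr[i["rc_p"], i["rc_a"]] = 0.9
    corr[i["aqd"], i["lt"]] = corr[i["lt"], i["aqd"]] = -0.3
    return corr


@dataclass(frozen=True)
class RawCasiaRecord:
    """One raw tomographer measurement (meridional radii still separate)."""

    patient_id: str
    eye_side: str  # "R" | "L"
    rc1_a: float
    rc2_a: float
    rc1_p: float
    rc2_p: float
    cct: float
    aqd: float
    lt: float
    a1_a: float = 0.0
    a2_a: float = 90.0
    a1_p: float = 0.0
    a2_p: float = 90.0


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    ``means``/``sds`` map parameter name -> value (defaults: the reference
    population statistics); ``correlation`` is the 5x5 matrix over
    (rc_a, rc_p, cct, aqd, lt).  Draws are truncated at +-3 SD per parameter
    and rejected below ``aqd_min``; ACD is set to AQD + CCT exactly.
    """

    n_eyes: int = 1000
    means: dict[str, float] = field(
        default_factory=lambda: {p: m for p, (m, _) in TABLE_STATS.items()}
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {p: s for p, (_, s) in TABLE_STATS.items()}
    )
    correlation: np.ndarray = field(default_factory=_default_correlation)
    aqd_min: float = AQD_MIN_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise CohortError("n_eyes must be >= 1")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (len(_PARAMS), len(_PARAMS)):
            raise CohortError(f"correlation matrix must be {len(_PARAMS)}x{len(_PARAMS)}")
        if not np.allclose(corr, corr.T):
            raise CohortError("correlation matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(corr) <= 0):
            raise CohortError("correlation matrix must be positive definite")


def average_meridians(rec: RawCasiaRecord) -> EyeBiometry:
    """Collapse flat/steep meridian radii to their arithmetic means.

    RC = (RC1 + RC2)/2 for front and back surface; ACD is recomputed as
    AQD + CCT and the keratometric power is derived downstream.
    """
    if min(rec.rc1_a, rec.rc2_a, rec.rc1_p, rec.rc2_p) <= 0:
        raise CohortError(
            f"record {rec.patient_id}/{rec.eye_side}: non-positive meridian radius"
        )
    return EyeBiometry(
        rc_a=0.5 * (rec.rc1_a + rec.rc2_a),
        rc_p=0.5 * (rec.rc1_p + rec.rc2_p),
        cct=rec.cct,
        aqd=rec.aqd,
        lt=rec.lt,
    )


def preprocess(
    records: Iterable[RawCasiaRecord],
    seed: int = 0,
    aqd_min: float = AQD_MIN_DEFAULT,
) -> tuple[list[EyeBiometry], dict[str, int]]:
    """Apply the study selection rules to raw records.

    Per patient+side, repeat measurements reduce to the first occurrence; per
    patient, one eye is kept by a seeded uniform choice; eyes with
    AQD < ``aqd_min`` (inclusive threshold: 2.8 mm is retained) are removed.
    Returns the surviving eyes plus an audit log counting each filter's
    removals.
    """
    rng = np.random.default_rng(seed)
    audit = {"input": 0, "duplicates": 0, "fellow_eyes": 0, "aqd_filtered": 0, "rejected": 0, "kept": 0}

    by_patient: dict[str, dict[str, RawCasiaRecord]] = {}
    for rec in records:
        audit["input"] += 1
        if not rec.patient_id or not rec.eye_side:
            audit["rejected"] += 1
            continue
        sides = by_patient.setdefault(rec.patient_id, {})
        if rec.eye_side in sides:
            audit["duplicates"] += 1
            continue
        sides[rec.eye_side] = rec

    eyes: list[EyeBiometry] = []
    for patient_id in sorted(by_patient):
        sides = by_patient[patient_id]
        keys = sorted(sides)
        if len(keys) > 1:
            keep = keys[rng.integers(len(keys))]
            audit["fellow_eyes"] += len(keys) - 1
        else:
            keep = keys[0]
        rec = sides[keep]
        if rec.aqd < aqd_min:
            audit["aqd_filtered"] += 1
            continue
        try:
            eyes.append(average_meridians(rec))
        except CohortError:
            audit["rejected"] += 1
    audit["kept"] = len(eyes)
    return eyes, audit


def sample_cohort(spec: CohortSpec) -> list[EyeBiometry]:
    """Draw a synthetic cohort of eyes from the truncated-normal generator.

    Sampling is by rejection: multivariate-normal draws are kept when every
    parameter lies within +-3 SD of its mean and AQD >= ``aqd_min``.  The
    synthetic generator yields one eye per notional patient directly, so the
    one-eye/deduplication logic of :func:`preprocess` does not apply here.
    Identical spec and seed reproduce the cohort exactly.
    """
    rng = np.random.default_rng(spec.seed)
    mu = np.array([spec.means[p] for p in _PARAMS])
    sd = np.array([spec.sds[p] for p in _PARAMS])
    cov = np.asarray(spec.correlation) * np.outer(sd, sd)
    i_aqd = _PARAMS.index("aqd")

    if np.all(sd == 0):  # degenerate spec: the cohort is n copies of the mean eye
        if mu[i_aqd] < spec.aqd_min:
            raise CohortError("degenerate spec: mean AQD below the AQD floor")
        return [EyeBiometry(*mu) for _ in range(spec.n_eyes)]

    eyes: list[EyeBiometry] = []
    while len(eyes) < spec.n_eyes:
        batch = max(spec.n_eyes - len(eyes), 128)
        draws = rng.multivariate_normal(mu, cov, size=batch)
        in_band = np.all(np.abs(draws - mu) <= 3.0 * sd + 1e-12, axis=1)
        ok = in_band & (draws[:, i_aqd] >= spec.aqd_min)
        for row in draws[ok]:
            eyes.append(
                EyeBiometry(
                    rc_a=row[0], rc_p=row[1], cct=row[2], aqd=row[3], lt=row[4]
                )
            )
            if len(eyes) == spec.n_eyes:
                break
    return eyes


def mean_eye() -> EyeBiometry:
    """The reference-population mean eye (generator means, zero spread)."""
    return EyeBiometry(**{p: m for p, (m, _) in TABLE_STATS.items()})


def cohort_frame(eyes: Sequence[EyeBiometry]) -> pd.DataFrame:
    """Tabulate a cohort with the derived quantities (ACD, PC) included."""
    return pd.DataFrame(
        {
            "rc_a_mm": [e.rc_a for e in eyes],
            "rc_p_mm": [e.rc_p for e in eyes],
            "cct_mm": [e.cct for e in eyes],
            "aqd_mm": [e.aqd for e in eyes],
            "acd_mm": [e.acd for e in eyes],
            "lt_mm": [e.lt for e in eyes],
            "pc_dpt": [e.pc for e in eyes],
        }
    )


def write_cohort_csv(eyes: Sequence[EyeBiometry], path: str | Path) -> None:
    cohort_frame(eyes).to_csv(path, index=False, float_format="%.10g")


def read_biometry_csv(path: str | Path) -> list[RawCasiaRecord]:
    """Ingest a raw biometry CSV (one row per measurement).

    Expected columns: patient_id, eye, RC1a_mm, RC2a_mm, RC1p_mm, RC2p_mm,
    CCT_mm, AQD_mm, LT_mm.
    """
    frame = pd.read_csv(path)
    required = [
        "patient_id", "eye", "RC1a_mm", "RC2a_mm", "RC1p_mm", "RC2p_mm",
        "CCT_mm", "AQD_mm", "LT_mm",
    ]
    missing = [c for c in required if c not in frame]
    if missing:
        raise CohortError(f"biometry CSV lacks columns {missing}")
    return [
        RawCasiaRecord(
            patient_id=str(row["patient_id"]),
            eye_side=str(row["eye"]),
            rc1_a=row["RC1a_mm"],
            rc2_a=row["RC2a_mm"],
            rc1_p=row["RC1p_mm"],
            rc2_p=row["RC2p_mm"],
            cct=row["CCT_mm"],
            aqd=row["AQD_mm"],
            lt=row["LT_mm"],
        )
        for _, row in frame.iterrows()
    ]
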