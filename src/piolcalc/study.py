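"""Monte-Carlo prediction study: simulate REF/dM grids and fit stepwise models.

For each eye in a cohort and each of the 58 design power steps, the exact
vergence calculation gives REF and dM (scenarios A or B, thick-lens PIOL).
Bidirectional stepwise ordinary least squares then looks for compact
prediction formulas usable without a full vergence calculation: terms are
added when their coefficient p-value is at most ``p_enter`` (0.01) and
removed when it reaches ``p_remove`` (0.1), starting from a constant model
and restricted to linear and squared candidate terms (no interactions).

Reported performance statistics are in-sample: residual RMSE, adjusted R**2,
and the F statistic of the final model against the constant model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortSpec, sample_cohort
from .design import DesignTable, ScheduleParams, synth_design_table
from .errors import FitError
from .eye import EyeBiometry, ScenarioConfig, scan_power_range
from .paraxial import OpticsError

__all__ = [
    "Response",
    "RegressionSpec",
    "ModelReport",
    "build_grid",
    "stepwise_fit",
    "ols_fit",
    "evaluate",
    "run_study",
]

Response = Literal["REF", "dM"]

#: Candidate predictors per scenario (a thin-lens cornea is summarised by its
#: keratometric power PC, so the separate corneal geometry drops out).
CANDIDATES = {
    "A": ["RC_a", "RC_p", "CCT", "ACD", "LT", "PIOLP"],
    "B": ["PC", "ACD", "LT", "PIOLP"],
}


@dataclass(frozen=True)
class RegressionSpec:
    """Stepwise-selection settings."""

    scenario: Literal["A", "B"] = "A"
    max_degree: int = 2
    p_enter: float = 0.01
    p_remove: float = 0.1

    def __post_init__(self) -> None:
        if self.max_degree not in (1, 2):
            raise FitError("max_degree must be 1 or 2")
        if not self.p_enter < self.p_remove:
            raise FitError("p_enter must be below p_remove")

    @property
    def candidate_terms(self) -> list[str]:
        base = CANDIDATES[self.scenario]
        if self.max_degree == 1:
            return list(base)
        return list(base) + [f"{c}^2" for c in base]


@dataclass(frozen=True)
class ModelReport:
    """A fitted prediction model with its in-sample performance."""

    response: str
    scenario: str
    degree: int
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    rmse: float
    adj_r2: float
    f_stat: float
    f_pvalue: float
    n_rows: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "scenario": self.scenario,
            "degree": self.degree,
            "terms": [
                {"name": t, "coef": self.coefficients[t], "p": self.p_values[t]}
                for t in ("const", *self.terms)
            ],
            "rmse": self.rmse,
            "adj_r2": self.adj_r2,
            "f": self.f_stat,
            "f_p": self.f_pvalue,
            "seed": self.seed,
            "n_rows": self.n_rows,
        }


def build_grid(
    eyes: Sequence[EyeBiometry],
    table: DesignTable,
    cfg: ScenarioConfig,
) -> pd.DataFrame:
    """Evaluate REF and dM for every eye x power step of one scenario.

    Returns one row per combination with the eye predictors (RC_a, RC_p, CCT,
    PC, ACD, LT), the labelled power PIOLP, and the responses REF (dpt) and
    dM (%).  Rows whose optical calculation fails (focal singularity,
    impossible geometry) are dropped and counted in ``frame.attrs['dropped']``.
    """
    if cfg.scenario not in ("A", "B"):
        raise FitError("the prediction study uses the thick-PIOL scenarios A and B")
    rows = []
    dropped = 0
    for eye in eyes:
        try:
            results = scan_power_range(eye, table, cfg)
        except OpticsError:
            dropped += len(table)
            continue
        for res, design in zip(results, table):
            rows.append(
                (
                    eye.rc_a, eye.rc_p, eye.cct, eye.pc, eye.acd, eye.lt,
                    design.power_label, res.ref, res.delta_m,
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=["RC_a", "RC_p", "CCT", "PC", "ACD", "LT", "PIOLP", "REF", "dM"],
    )
    frame.attrs["scenario"] = cfg.scenario
    frame.attrs["dropped"] = dropped
    return frame


def _design_matrix(grid: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t.endswith("^2"):
            cols.append(grid[t[:-2]].to_numpy() ** 2)
        else:
            cols.append(grid[t].to_numpy())
    x = np.column_stack(cols) if cols else np.empty((len(grid), 0))
    return sm.add_constant(x, has_constant="add")


def _fit_ols(grid: pd.DataFrame, response: str, terms: Sequence[str]):
    x = _design_matrix(grid, terms)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise FitError(f"collinear design matrix for terms {list(terms)}")
    return sm.OLS(grid[response].to_numpy(), x).fit()


def stepwise_fit(
    grid: pd.DataFrame,
    response: Response,
    spec: RegressionSpec,
) -> ModelReport:
    """Bidirectional stepwise OLS starting from the constant model.

    Each iteration adds the excluded candidate with the smallest coefficient
    p-value if it is at most ``p_enter`` (lexicographic candidate order breaks
    exact ties), then removes included terms whose p-value has risen to
    ``p_remove`` or above, until the selection is stable.  Coefficient
    p-values are two-sided t-tests from the ordinary-least-squares fit.
    """
    candidates = spec.candidate_terms
    if len(grid) <= len(candidates) + 2:
        raise FitError("not enough rows for stepwise selection")
    selected: list[str] = []
    while True:
        changed = False
        # forward step
        best_term, best_p = None, np.inf
        for term in candidates:
            if term in selected:
                continue
            try:
                fit = _fit_ols(grid, response, selected + [term])
            except FitError:
                continue
            p = fit.pvalues[-1]
            if p < best_p:
                best_term, best_p = term, p
        if best_term is not None and best_p <= spec.p_enter:
            selected.append(best_term)
            changed = True
        # backward step: drop the worst offender, one at a time
        while selected:
            fit = _fit_ols(grid, response, selected)
            pvals = fit.pvalues[1:]  # skip intercept
            worst = int(np.argmax(pvals))
            if pvals[worst] >= spec.p_remove:
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break
    return ols_fit(grid, response, selected, scenario=spec.scenario, degree=spec.max_degree)


def ols_fit(
    grid: pd.DataFrame,
    response: Response,
    terms: Sequence[str],
    scenario: str | None = None,
    degree: int | None = None,
    seed: int | None = None,
) -> ModelReport:
    """Ordinary least squares on a fixed term set, with performance record."""
    fit = _fit_ols(grid, response, terms)
    names = ["const", *terms]
    resid = fit.resid
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ModelReport(
        response=response,
        scenario=scenario or str(grid.attrs.get("scenario", "")),
        degree=degree if degree is not None else (2 if any(t.endswith("^2") for t in terms) else 1),
        terms=tuple(terms),
        coefficients=dict(zip(names, map(float, fit.params))),
        p_values=dict(zip(names, map(float, fit.pvalues))),
        rmse=rmse,
        adj_r2=float(fit.rsquared_adj) if terms else 0.0,
        f_stat=float(fit.fvalue) if terms else float("nan"),
        f_pvalue=float(fit.f_pvalue) if terms else float("nan"),
        n_rows=len(grid),
        seed=seed,
    )


def evaluate(report: ModelReport, grid: pd.DataFrame) -> dict[str, float]:
    """Re-compute in-sample performance of a fitted model on a grid."""
    x = _design_matrix(grid, report.terms)
    beta = np.array([report.coefficients[t] for t in ("const", *report.terms)])
    resid = grid[report.response].to_numpy() - x @ beta
    n, k = len(grid), len(report.terms)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((grid[report.response] - grid[report.response].mean()) ** 2))
    r2 = 1.0 - sse / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return {
        "rmse": float(np.sqrt(sse / n)),
        "r2": r2,
        "adj_r2": adj_r2,
    }


def run_study(
    cohort_spec: CohortSpec | None = None,
    design_params: ScheduleParams | None = None,
    vault: float = 0.4,
    vd: float = 12.0,
) -> list[ModelReport]:
    """Full study: scenarios {A, B} x responses {REF, dM} x degrees {1, 2}.

    Returns eight stepwise-selected model reports, each stamped with the
    cohort seed.  Rerunning with the same spec reproduces the bundle exactly.
    """
    cohort_spec = cohort_spec or CohortSpec()
    eyes = sample_cohort(cohort_spec)
    table = synth_design_table(design_params)
    reports = []
    for scenario in ("A", "B"):
        cfg = ScenarioConfig(scenario=scenario, vault=vault, vd=vd)
        grid = build_grid(eyes, table, cfg)
        for response in ("REF", "dM"):
            for degree in (1, 2):
                spec = RegressionSpec(scenario=scenario, max_degree=degree)
                report = stepwise_fit(grid, response, spec)
                reports.append(replace(report, seed=cohort_spec.seed))
    return reports


def reports_to_json(reports: Sequence[ModelReport], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))
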