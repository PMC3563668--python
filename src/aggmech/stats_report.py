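"""Condition-level statistics, liquid-analogy predictions and study reports.

Aggregate-level measurements (surface tension sigma, visco-capillary
velocity v, contact angle theta, rugosity) are summarised per condition as
mean ± 95% confidence interval of the mean, compared across conditions with
Student's t-tests, combined into viscosity/fluidity, and fed to the
tension decomposition: given a designated uniform-cortex condition (whose
sigma equals J/2) the report solves for (Gamma_cm, Gamma_cc, J) and the
contractility/adhesion split of sigma.

The liquid analogy also makes a qualitative prediction: of two tissues
brought in contact, the one with the higher surface tension is engulfed by
the one with the lower (:func:`predict_envelopment`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dith_core import TensionSet, decompose_tst, solve_tensions
from .fusion_kinetics import fluidity_from, viscosity_from

__all__ = [
    "Summary",
    "ConditionSummary",
    "StudyReport",
    "summarize",
    "compare",
    "predict_envelopment",
    "build_report",
]


@dataclass(frozen=True)
class Summary:
    """Mean, half-width of the 95% CI of the mean, and sample size."""

    mean: float
    sem95: float
    n: int
    single: bool = False  # n == 1: CI undefined, reported as 0


@dataclass
class ConditionSummary:
    """Per-condition measurement table row (units as in the field tables)."""

    label: str
    sigma: Summary | None = None        # mN/m
    v: Summary | None = None            # µm/min
    eta: float | None = None            # Pa·s
    fluidity: float | None = None       # (Pa·s)^-1
    theta: Summary | None = None        # degrees
    roughness: Summary | None = None    # µm


@dataclass
class StudyReport:
    conditions: list[ConditionSummary]
    table: pd.DataFrame
    tensions: TensionSet | None = None
    decomposition: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "conditions": json.loads(self.table.to_json(orient="index")),
            "tensions": None,
            "decomposition": self.decomposition,
            "diagnostics": self.diagnostics,
        }
        if self.tensions is not None:
            payload["tensions"] = {
                "Gamma_cm_mN_per_m": self.tensions.Gamma_cm,
                "Gamma_cc_mN_per_m": self.tensions.Gamma_cc,
                "J_mN_per_m": self.tensions.J,
            }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, directory: str | Path, stem: str = "report") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / f"{stem}.csv")
        (directory / f"{stem}.json").write_text(self.to_json())


def summarize(values) -> Summary:
    """Mean and 95% t-interval half-width of the mean.

    A single value is legal (preliminary experiments are often n = 1) and
    yields sem95 = 0 with the ``single`` flag set.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    n = int(arr.size)
    mean = float(arr.mean())
    if n == 1:
        return Summary(mean=mean, sem95=0.0, n=1, single=True)
    sem = float(arr.std(ddof=1)) / math.sqrt(n)
    return Summary(mean=mean, sem95=float(stats.t.ppf(0.975, n - 1)) * sem, n=n)


def compare(group_a, group_b, *, equal_var: bool = False) -> float:
    """Two-sample Student's t-test p-value (Welch by default).

    ``equal_var=True`` selects the pooled-variance variant.  Either group
    with n < 2 raises.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2 for a t-test")
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def predict_envelopment(
    sigma_a: float,
    sigma_b: float,
    ci_a: float = 0.0,
    ci_b: float = 0.0,
    labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Predicted arrangement of two tissues from their surface tensions.

    The higher-tension (more cohesive) tissue is predicted internal, the
    lower-tension one enveloping it.  When the supplied confidence
    intervals overlap the tensions cannot be ranked and "no sorting" is
    predicted, with an ambiguity flag.
    """
    if sigma_a < 0 or sigma_b < 0:
        raise ValueError("surface tensions must be non-negative")
    overlap = abs(sigma_a - sigma_b) <= (ci_a + ci_b)
    if sigma_a == sigma_b or overlap:
        return {
            "outcome": "no sorting",
            "internal": None,
            "external": None,
            "ambiguous": overlap and sigma_a != sigma_b,
        }
    internal, external = (labels[0], labels[1]) if sigma_a > sigma_b else (labels[1], labels[0])
    return {
        "outcome": "envelopment",
        "internal": internal,
        "external": external,
        "ambiguous": False,
    }


def build_report(
    per_condition: dict[str, dict],
    uniform_label: str | None = None,
    wt_label: str | None = None,
) -> StudyReport:
    """Assemble the study-style summary table and the tension decomposition.

    ``per_condition`` maps a condition label to raw measurement lists:
    keys among ``sigma`` (mN/m), ``v`` (µm/min), ``theta`` (degrees),
    ``roughness`` (µm).  Viscosity and fluidity are derived per condition
    from the mean sigma and mean v.  When ``uniform_label`` names a
    uniform-cortex condition (and a wild-type condition with both sigma and
    theta exists), the cortical tensions (Gamma_cm, Gamma_cc, J) are solved
    and sigma is decomposed into contractility and adhesion fractions;
    otherwise that section is skipped with a warning.
    """
    if not per_condition:
        raise ValueError("no conditions supplied")
    conditions: list[ConditionSummary] = []
    diagnostics: dict = {}
    for label, data in per_condition.items():
        row = ConditionSummary(label=label)
        for key in ("sigma", "v", "theta", "roughness"):
            vals = data.get(key)
            if vals is not None and len(vals) > 0:
                setattr(row, key, summarize(vals))
        if row.sigma is not None and row.v is not None and row.v.mean > 0:
            row.eta = viscosity_from(row.sigma.mean, row.v.mean)
            row.fluidity = fluidity_from(row.sigma.mean, row.v.mean)
        conditions.append(row)

    records = {}
    for c in conditions:
        rec = {}
        for key, unit in (
            ("sigma", "mN/m"), ("v", "um/min"),
            ("theta", "deg"), ("roughness", "um"),
        ):
            s: Summary | None = getattr(c, key)
            rec[f"{key}_{unit.replace('/', '_per_')}"] = s.mean if s else np.nan
            rec[f"{key}_sem95"] = s.sem95 if s else np.nan
            rec[f"{key}_n"] = s.n if s else 0
        rec["eta_Pa_s"] = c.eta if c.eta is not None else np.nan
        rec["fluidity_per_Pa_s"] = c.fluidity if c.fluidity is not None else np.nan
        records[c.label] = rec
    table = pd.DataFrame.from_dict(records, orient="index")

    tensions = None
    decomposition = None
    by_label = {c.label: c for c in conditions}
    if uniform_label is None or uniform_label not in by_label:
        warnings.warn(
            "no uniform-cortex condition designated: tension decomposition skipped",
            stacklevel=2,
        )
    else:
        wt = by_label.get(wt_label) if wt_label else next(
            (c for c in conditions
             if c.label != uniform_label and c.sigma and c.theta),
            None,
        )
        uni = by_label[uniform_label]
        if wt is None or wt.sigma is None or wt.theta is None or uni.sigma is None:
            warnings.warn(
                "wild-type condition lacks sigma or theta: tension "
                "decomposition skipped",
                stacklevel=2,
            )
        else:
            tensions = solve_tensions(
                wt.sigma.mean, uni.sigma.mean, wt.theta.mean
            )
            decomposition = decompose_tst(tensions)
            diagnostics["dith_wt_label"] = wt.label
            diagnostics["dith_uniform_label"] = uniform_label
    return StudyReport(
        conditions=conditions,
        table=table,
        tensions=tensions,
        decomposition=decomposition,
        diagnostics=diagnostics,
    )
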