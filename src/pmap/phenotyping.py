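"""EC50 fitting, sample ranking and phenotype tail selection.

Per (drug, group) condition, samples are ranked ascending by EC50; the k
lowest-EC50 samples form the sensitive tail and the k highest the resistant
tail (default k=15).  EC50 is obtained from raw dose-response viability by a
four-parameter logistic least-squares fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from pmap.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

RESPONSES = ("sensitive", "resistant")

DEFAULT_CLASS_MAP: dict[str, str] = {
    "doxorubicin": "anthracycline",
    "epirubicin": "anthracycline",
    "docetaxel": "taxane",
    "paclitaxel": "taxane",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DoseResponse:
    """Raw viability measurements for one sample and drug."""

    sample_id: str
    drug: str
    doses: np.ndarray            # includes the zero anchor
    viability: np.ndarray        # fraction of control, same length as doses
    units: str = "uM"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses.shape != self.viability.shape:
            raise DataError("doses and viability lengths differ")
        if np.any(self.doses < 0):
            raise DataError("negative dose")
        if np.unique(self.doses).size < 4:
            raise DataError("need >= 4 distinct doses")
        if not np.all(np.isfinite(self.viability)):
            raise DataError("non-finite viability")


@dataclass(frozen=True)
class Ec50Fit:
    ec50: float
    hill: float
    lower: float
    upper: float
    converged: bool
    reason: str = ""


@dataclass
class PhenotypeAssignment:
    """Tail membership for one (drug, group) condition."""

    drug: str
    group: str
    ranked_samples: list[str]      # ascending EC50, ties by sample id
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("tail size k must be >= 1")
        if len(self.ranked_samples) < 2 * self.k:
            raise DataError(
                f"condition ({self.drug}, {self.group}): "
                f"{len(self.ranked_samples)} samples < 2k = {2 * self.k}"
            )

    @property
    def condition(self) -> tuple[str, str]:
        return (self.drug, self.group)

    @property
    def sensitive_tail(self) -> list[str]:
        return self.ranked_samples[: self.k]

    @property
    def resistant_tail(self) -> list[str]:
        return self.ranked_samples[-self.k:]

    @property
    def tail_samples(self) -> list[str]:
        """Sensitive tail then resistant tail, 2k samples."""
        return self.sensitive_tail + self.resistant_tail


@dataclass(frozen=True)
class PhenotypeClass:
    """A drug class x response aggregate, e.g. anthracycline-resistant."""

    drug_class: str
    response: str
    drugs: tuple[str, ...]

    @property
    def name(self) -> str:
        return f"{self.drug_class}-{self.response}"


def phenotype_classes(class_map: Mapping[str, str] | None = None) -> list[PhenotypeClass]:
    """All drug-class x response combinations implied by a drug->class map."""
    class_map = dict(class_map or DEFAULT_CLASS_MAP)
    by_class: dict[str, list[str]] = {}
    for drug, cls in class_map.items():
        by_class.setdefault(cls, []).append(drug)
    out = []
    for cls in sorted(by_class):
        for response in RESPONSES:
            out.append(PhenotypeClass(cls, response, tuple(sorted(by_class[cls]))))
    return out


# ---------------------------------------------------------------------------
# 4-parameter logistic EC50 fit
# ---------------------------------------------------------------------------


def logistic4(dose: np.ndarray, lower: float, upper: float,
              ec50: float, hill: float) -> np.ndarray:
    """Decreasing 4PL: upper at dose 0, lower as dose -> infinity (hill > 0)."""
    dose = np.asarray(dose, dtype=float)
    out = np.full_like(dose, upper, dtype=float)
    pos = dose > 0
    out[pos] = lower + (upper - lower) / (1.0 + (dose[pos] / ec50) ** hill)
    return out


def fit_ec50(dr: DoseResponse, pin_upper: float | None = None) -> Ec50Fit:
    """Least-squares 4PL fit of viability vs dose.

    EC50 is constrained to [min positive dose / 10, max dose * 10].  Degenerate
    inputs (flat or increasing dose-response) are flagged non-convergent rather
    than raising; callers exclude those samples downstream.
    """
    doses, viab = dr.doses, dr.viability
    if np.ptp(viab) == 0:
        return Ec50Fit(np.nan, np.nan, np.nan, np.nan, False, "constant viability")

    # mean response per dose to detect an inverted (increasing) curve
    order = np.argsort(doses)
    per_dose = pd.Series(viab[order]).groupby(doses[order]).mean()
    if per_dose.iloc[-1] > per_dose.iloc[0]:
        return Ec50Fit(np.nan, np.nan, np.nan, np.nan, False, "increasing viability")

    pos = doses[doses > 0]
    lo_bound, hi_bound = pos.min() / 10.0, doses.max() * 10.0
    p0 = [viab.min(), viab.max(), float(np.median(pos)), 1.0]
    if pin_upper is None:
        bounds = ([-np.inf, -np.inf, lo_bound, 1e-3],
                  [np.inf, np.inf, hi_bound, 20.0])

        def model(d, lower, upper, ec50, hill):
            return logistic4(d, lower, upper, ec50, hill)

    else:
        p0 = [viab.min(), float(np.median(pos)), 1.0]
        bounds = ([-np.inf, lo_bound, 1e-3], [np.inf, hi_bound, 20.0])

        def model(d, lower, ec50, hill):
            return logistic4(d, lower, pin_upper, ec50, hill)

    try:
        popt, _ = curve_fit(model, doses, viab, p0=p0, bounds=bounds,
                            maxfev=20000, xtol=1e-12, ftol=1e-12)
    except (RuntimeError, ValueError) as exc:
        logger.info("EC50 fit failed for %s/%s: %s", dr.sample_id, dr.drug, exc)
        return Ec50Fit(np.nan, np.nan, np.nan, np.nan, False, str(exc))

    if pin_upper is None:
        lower, upper, ec50, hill = popt
    else:
        lower, ec50, hill = popt
        upper = pin_upper
    return Ec50Fit(float(ec50), float(hill), float(lower), float(upper), True)


def fit_ec50_table(dose_responses: Iterable[DoseResponse],
                   groups: Mapping[str, str],
                   units: str = "uM") -> pd.DataFrame:
    """Fit EC50 for many samples; non-convergent fits are dropped with a log."""
    rows = []
    for dr in dose_responses:
        fit = fit_ec50(dr)
        if not fit.converged:
            logger.info("excluding %s/%s: %s", dr.sample_id, dr.drug, fit.reason)
            continue
        rows.append({
            "sample_id": dr.sample_id, "drug": dr.drug,
            "group": groups[dr.sample_id], "ec50": fit.ec50, "units": dr.units,
        })
    return pd.DataFrame(rows, columns=["sample_id", "drug", "group", "ec50", "units"])


# ---------------------------------------------------------------------------
# Phenotype assignment and condition enumeration
# ---------------------------------------------------------------------------


def assign_phenotypes(ec50s: pd.DataFrame, k: int = 15) -> list[PhenotypeAssignment]:
    """One tail assignment per (drug, group) condition.

    Samples rank ascending by EC50; ties break by lexicographic sample id so
    assignment is invariant to input row order.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    required = {"sample_id", "drug", "group", "ec50"}
    missing = required - set(ec50s.columns)
    if missing:
        raise DataError(f"EC50 table missing columns {sorted(missing)}")
    assignments = []
    for (drug, group), sub in sorted(ec50s.groupby(["drug", "group"], sort=True)):
        if len(sub) < 2 * k:
            raise DataError(
                f"condition ({drug}, {group}) has {len(sub)} samples, needs >= {2 * k}"
            )
        ranked = sub.sort_values(["ec50", "sample_id"], kind="mergesort")
        assignments.append(PhenotypeAssignment(
            drug=str(drug), group=str(group),
            ranked_samples=[str(s) for s in ranked["sample_id"]], k=k,
        ))
    return assignments


def enumerate_conditions(drugs: Sequence[str], groups: Sequence[str],
                         responses: Sequence[str] = RESPONSES
                         ) -> list[tuple[str, str, str]]:
    """Full cross product drug x group x response."""
    if not drugs or not groups:
        raise ConfigError("drugs and groups must be non-empty")
    return [(d, g, r) for d in sorted(drugs) for g in sorted(groups)
            for r in responses]


def assignments_to_frame(assignments: Sequence[PhenotypeAssignment]) -> pd.DataFrame:
    """Long-format tail table: condition, sample_id, rank, tail."""
    rows = []
    for a in assignments:
        tails = {s: "sensitive" for s in a.sensitive_tail}
        tails.update({s: "resistant" for s in a.resistant_tail})
        for rank, sid in enumerate(a.ranked_samples):
            rows.append({
                "drug": a.drug, "group": a.group, "sample_id": sid,
                "rank": rank, "tail": tails.get(sid, "none"), "k": a.k,
            })
    return pd.DataFrame(rows, columns=["drug", "group", "sample_id", "rank", "tail", "k"])


def assignments_from_frame(frame: pd.DataFrame) -> list[PhenotypeAssignment]:
    out = []
    for (drug, group), sub in sorted(frame.groupby(["drug", "group"], sort=True)):
        ranked = sub.sort_values("rank")
        k = int(ranked["k"].iloc[0])
        out.append(PhenotypeAssignment(
            drug=str(drug), group=str(group),
            ranked_samples=[str(s) for s in ranked["sample_id"]], k=k,
        ))
    return out
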