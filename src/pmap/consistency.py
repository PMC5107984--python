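"""Knockdown-screen consistency classification.

The sign of a gene's summed PF score predicts the direction of drug-response
change under knockdown: positive (sensitive-network dominant) predicts
increased sensitivity, negative predicts decreased sensitivity, zero yields
no prediction.  Agreement with observed screen outcomes is banded by PF
magnitude: weak |PF| < 10, moderate 10 <= |PF| <= 100 (boundaries closed),
strong |PF| > 100.  A gene matching in a strict subset of the recorded cell
lines keeps its band but is annotated as restricted to those lines; no match
anywhere (including all-non-responsive) is inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from pmap.errors import DataError

INCREASED = "increased_sensitivity"
DECREASED = "decreased_sensitivity"
NON_RESPONSIVE = "non_responsive"
OBSERVATION_TOKENS = {INCREASED, DECREASED, NON_RESPONSIVE}

WEAK = "weak"
MODERATE = "moderate"
STRONG = "strong"
INCONSISTENT = "inconsistent"
NOT_EVALUABLE = "not_evaluable"

SCREEN_COLUMNS = ["gene", "cell_line", "drug", "observation"]


@dataclass
class ScreenObservation:
    """Observed knockdown outcomes for one gene: (cell_line, drug) -> token."""

    gene: str
    observations: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observations:
            raise DataError(f"{self.gene}: no observations recorded")
        for key, token in self.observations.items():
            if token not in OBSERVATION_TOKENS:
                raise DataError(f"{self.gene} {key}: unknown observation {token!r}")

    @property
    def cell_lines(self) -> list[str]:
        return sorted({c for c, _ in self.observations})

    def line_direction(self, cell_line: str) -> str:
        """Per-cell-line observed direction, judged by responsive drugs.

        Returns one observed direction when all responsive drugs agree,
        ``non_responsive`` when no drug responded, ``mixed`` otherwise.
        """
        tokens = [t for (c, _), t in self.observations.items() if c == cell_line]
        responsive = {t for t in tokens if t != NON_RESPONSIVE}
        if not responsive:
            return NON_RESPONSIVE
        if len(responsive) == 1:
            return next(iter(responsive))
        return "mixed"


@dataclass(frozen=True)
class ConsistencyCall:
    gene: str
    pf_sum: int
    predicted_direction: str | None
    category: str
    matching_cell_lines: tuple[str, ...]
    recorded_cell_lines: tuple[str, ...]
    line_directions: tuple[tuple[str, str], ...]

    @property
    def restricted(self) -> bool:
        """True when the match holds in a strict subset of recorded lines."""
        return (self.category in (WEAK, MODERATE, STRONG)
                and len(self.matching_cell_lines) < len(self.recorded_cell_lines))

    @property
    def matches_all_lines(self) -> bool:
        return (self.category in (WEAK, MODERATE, STRONG)
                and len(self.matching_cell_lines) == len(self.recorded_cell_lines))


def predict_direction(pf_sum: int) -> str | None:
    """Predicted change of drug sensitivity when the gene is knocked down."""
    if pf_sum > 0:
        return INCREASED
    if pf_sum < 0:
        return DECREASED
    return None


def magnitude_band(pf_sum: int) -> str:
    a = abs(pf_sum)
    if a < 10:
        return WEAK
    if a <= 100:
        return MODERATE
    return STRONG


def classify_consistency(gene: str, pf_sum: int,
                         obs: ScreenObservation) -> ConsistencyCall:
    """Classify one gene's screen outcome against its PF-sign prediction."""
    if obs.gene != gene:
        raise DataError(f"observation gene {obs.gene!r} != {gene!r}")
    predicted = predict_direction(pf_sum)
    lines = obs.cell_lines
    directions = {c: obs.line_direction(c) for c in lines}
    if predicted is None:
        return ConsistencyCall(gene, pf_sum, None, NOT_EVALUABLE, (),
                               tuple(lines), tuple(sorted(directions.items())))
    matching = tuple(c for c in lines if directions[c] == predicted)
    category = magnitude_band(pf_sum) if matching else INCONSISTENT
    return ConsistencyCall(gene, pf_sum, predicted, category, matching,
                           tuple(lines), tuple(sorted(directions.items())))


def classify_table(screen: pd.DataFrame, pf: Mapping[str, int]
                   ) -> list[ConsistencyCall]:
    """Classify every gene in a long-format screen table.

    ``screen`` has columns gene, cell_line, drug, observation; ``pf`` maps
    gene -> summed PF score.
    """
    missing = [c for c in SCREEN_COLUMNS if c not in screen.columns]
    if missing:
        raise DataError(f"screen table missing columns {missing}")
    calls = []
    for gene, sub in screen.groupby("gene", sort=True):
        if gene not in pf:
            raise DataError(f"no PF score for screened gene {gene!r}")
        obs = ScreenObservation(
            gene=str(gene),
            observations={(str(r.cell_line), str(r.drug)): str(r.observation)
                          for r in sub.itertuples()},
        )
        calls.append(classify_consistency(str(gene), int(pf[gene]), obs))
    return calls


def calls_to_frame(calls: Sequence[ConsistencyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "gene": c.gene, "pf_sum": c.pf_sum,
            "predicted_direction": c.predicted_direction or "none",
            "category": c.category,
            "matching_cell_lines": ",".join(c.matching_cell_lines),
            "recorded_cell_lines": ",".join(c.recorded_cell_lines),
        } for c in calls],
        columns=["gene", "pf_sum", "predicted_direction", "category",
                 "matching_cell_lines", "recorded_cell_lines"],
    )


def summarize_screen(calls: Iterable[ConsistencyCall]) -> dict[str, float]:
    """Aggregate counts over a screen.

    Reports both the PF-consistency ledger (full / partial / inconsistent
    match against prediction) and the raw observed-direction ledger (how many
    genes moved the same way in every recorded cell line), since the two need
    not agree.
    """
    calls = list(calls)
    if not calls:
        raise DataError("no consistency calls to summarize")
    n_tested = sum(1 for c in calls if c.predicted_direction is not None)
    n_full = sum(1 for c in calls if c.matches_all_lines)
    n_partial = sum(1 for c in calls if c.restricted)
    n_inconsistent = sum(1 for c in calls if c.category == INCONSISTENT)
    n_not_eval = sum(1 for c in calls if c.category == NOT_EVALUABLE)

    def _uniform(call: ConsistencyCall, direction: str) -> bool:
        dirs = dict(call.line_directions)
        return bool(dirs) and all(d == direction for d in dirs.values())

    n_inc_both = sum(1 for c in calls if _uniform(c, INCREASED))
    n_dec_both = sum(1 for c in calls if _uniform(c, DECREASED))
    return {
        "n_genes": len(calls),
        "n_tested": n_tested,
        "n_match_all_lines": n_full,
        "n_match_partial": n_partial,
        "n_inconsistent": n_inconsistent,
        "n_not_evaluable": n_not_eval,
        "pct_match_all_lines": 100.0 * n_full / n_tested if n_tested else 0.0,
        "n_increased_all_lines": n_inc_both,
        "n_decreased_all_lines": n_dec_both,
    }


# ---------------------------------------------------------------------------
# Bundled screen transcriptions (anthracycline / taxane knockdown tables)
# ---------------------------------------------------------------------------


def load_bundled_screen(drug_class: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the packaged knockdown-screen transcription for a drug class.

    Returns (screen, pf) frames; ``pf`` carries gene, pf_sum and the
    transcribed expected category / restriction columns for regression tests.
    """
    if drug_class not in {"anthracycline", "taxane"}:
        raise DataError(f"no bundled screen for drug class {drug_class!r}")
    pkg = resources.files("pmap.data")
    screen = pd.read_csv(pkg / f"{drug_class}_screen.tsv", sep="\t")
    pf = pd.read_csv(pkg / f"{drug_class}_pf.tsv", sep="\t",
                     keep_default_na=False)
    return screen, pf
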