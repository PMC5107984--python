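"""Phenotypic differentially expressed genes (PDEGs).

Per (drug, group) condition a binary template (1 = sensitive tail, 0 =
resistant tail) is correlated with each gene's expression over the 2k tail
samples; significance comes from the t-transform of Pearson r with 2k-2
degrees of freedom.  Condition-level calls aggregate into phenotype-class
PDEG sets: a gene qualifies if it passes template matching in a member
condition with the class's direction and is up-regulated (z-score above
``up_z`` against the condition's tail samples) in at least two cell lines of
that response across the class, counted only in conditions it passed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from pmap.errors import ConfigError, DataError
from pmap.io_formats import ExpressionMatrix
from pmap.phenotyping import PhenotypeAssignment, PhenotypeClass

logger = logging.getLogger(__name__)

UP_IN_SENSITIVE = "up_in_sensitive"
UP_IN_RESISTANT = "up_in_resistant"

_DIRECTION_FOR_RESPONSE = {"sensitive": UP_IN_SENSITIVE, "resistant": UP_IN_RESISTANT}


@dataclass(frozen=True)
class TemplateMatchResult:
    drug: str
    group: str
    gene: str
    correlation: float
    p_value: float
    direction: str

    @property
    def condition(self) -> tuple[str, str]:
        return (self.drug, self.group)


@dataclass
class PdegSet:
    """PDEGs for one phenotype class with per-gene evidence.

    ``evidence`` maps gene -> list of (drug, group, sample_id) triples naming
    the cell lines in which the gene met the up-regulation criterion.
    """

    phenotype_class: str
    genes: set[str] = field(default_factory=set)
    evidence: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def template_match(expr: ExpressionMatrix, assignment: PhenotypeAssignment,
                   alpha: float = 1e-3) -> list[TemplateMatchResult]:
    """Correlate every gene with the sensitive/resistant template.

    Returns results for genes with two-sided p <= alpha.  Genes with zero
    variance across the tail samples are skipped (logged).
    """
    if not 0 < alpha <= 1:
        raise ConfigError("alpha must be in (0, 1]")
    k = assignment.k
    tail_samples = assignment.tail_samples
    missing = [s for s in tail_samples if s not in expr.samples]
    if missing:
        raise DataError(
            f"tail samples absent from expression matrix: {missing[:5]}"
        )
    sub = expr.subset_samples(tail_samples)          # genes x 2k
    template = np.concatenate([np.ones(k), np.zeros(k)])

    n = 2 * k
    x = sub - sub.mean(axis=1, keepdims=True)
    t_c = template - template.mean()
    sx = np.sqrt((x ** 2).sum(axis=1))
    st = np.sqrt((t_c ** 2).sum())
    nonzero = sx > 0
    n_skipped = int((~nonzero).sum())
    if n_skipped:
        logger.info(
            "condition (%s, %s): skipped %d zero-variance gene(s)",
            assignment.drug, assignment.group, n_skipped,
        )
    r = np.zeros(sub.shape[0])
    r[nonzero] = (x[nonzero] @ t_c) / (sx[nonzero] * st)
    r = np.clip(r, -1.0, 1.0)

    df = n - 2
    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)

    out = []
    for i, gene in enumerate(expr.genes):
        if not nonzero[i] or p[i] > alpha:
            continue
        out.append(TemplateMatchResult(
            drug=assignment.drug, group=assignment.group, gene=gene,
            correlation=float(r[i]), p_value=float(p[i]),
            direction=UP_IN_SENSITIVE if r[i] > 0 else UP_IN_RESISTANT,
        ))
    return out


def _upregulated_lines(expr: ExpressionMatrix, assignment: PhenotypeAssignment,
                       gene: str, response: str, up_z: float) -> list[str]:
    """Tail cell lines of ``response`` where the gene's z-score (vs all 2k
    tail samples of the condition) exceeds ``up_z``."""
    tail = assignment.tail_samples
    values = expr.subset_samples(tail)[expr._gene_index[gene]]
    mu, sd = values.mean(), values.std(ddof=0)
    if sd == 0:
        return []
    z = (values - mu) / sd
    side = (assignment.sensitive_tail if response == "sensitive"
            else assignment.resistant_tail)
    offset = 0 if response == "sensitive" else assignment.k
    return [s for j, s in enumerate(side) if z[offset + j] > up_z]


def call_pdegs(results: Iterable[TemplateMatchResult],
               expr: ExpressionMatrix,
               assignments: Sequence[PhenotypeAssignment],
               classes: Sequence[PhenotypeClass],
               up_z: float = 1.0,
               min_lines: int = 2) -> dict[str, PdegSet]:
    """Aggregate condition-level template calls into class PDEG sets.

    Evidence lines are counted only within conditions where the gene passed
    template matching with the class's direction (strict reading); the gene
    enters the set when its evidence spans >= ``min_lines`` cell lines.
    """
    by_condition = {(a.drug, a.group): a for a in assignments}
    grouped: dict[tuple[str, str], list[TemplateMatchResult]] = {}
    for res in results:
        if res.condition not in by_condition:
            raise DataError(f"result for unknown condition {res.condition}")
        grouped.setdefault(res.condition, []).append(res)

    out: dict[str, PdegSet] = {}
    for cls in classes:
        want_dir = _DIRECTION_FOR_RESPONSE[cls.response]
        pdeg_set = PdegSet(phenotype_class=cls.name)
        candidate_evidence: dict[str, list[tuple[str, str, str]]] = {}
        for (drug, group), cond_results in sorted(grouped.items()):
            if drug not in cls.drugs:
                continue
            assignment = by_condition[(drug, group)]
            for res in cond_results:
                if res.direction != want_dir:
                    continue
                lines = _upregulated_lines(expr, assignment, res.gene,
                                           cls.response, up_z)
                if lines:
                    candidate_evidence.setdefault(res.gene, []).extend(
                        (drug, group, s) for s in lines
                    )
        for gene, lines in candidate_evidence.items():
            if len(lines) >= min_lines:
                pdeg_set.genes.add(gene)
                pdeg_set.evidence[gene] = sorted(lines)
        logger.info("class %s: %d PDEGs", cls.name, len(pdeg_set))
        out[cls.name] = pdeg_set
    return out


def pdegs_to_frame(pdeg_sets: Mapping[str, PdegSet],
                   results: Iterable[TemplateMatchResult] | None = None):
    """Flatten PDEG sets to a table (phenotype_class, gene, n_evidence_lines,
    best_p)."""
    import pandas as pd

    best_p: dict[tuple[str, str], float] = {}
    if results is not None:
        for res in results:
            for cls_name, pset in pdeg_sets.items():
                if res.gene in pset.genes:
                    key = (cls_name, res.gene)
                    best_p[key] = min(best_p.get(key, 1.0), res.p_value)
    rows = []
    for cls_name in sorted(pdeg_sets):
        pset = pdeg_sets[cls_name]
        for gene in sorted(pset.genes):
            rows.append({
                "phenotype_class": cls_name,
                "gene": gene,
                "n_evidence_lines": len(pset.evidence.get(gene, [])),
                "best_p": best_p.get((cls_name, gene), float("nan")),
            })
    return pd.DataFrame(rows, columns=["phenotype_class", "gene",
                                       "n_evidence_lines", "best_p"])


def pdegs_from_frame(frame) -> dict[str, PdegSet]:
    out: dict[str, PdegSet] = {}
    for cls_name, sub in frame.groupby("phenotype_class"):
        out[str(cls_name)] = PdegSet(
            phenotype_class=str(cls_name),
            genes=set(map(str, sub["gene"])),
        )
    return out
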