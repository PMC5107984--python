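"""Local enrichment procedures.

Two routes: exact hypergeometric over-representation with Bonferroni
correction (pathways with fewer than ``min_genes`` in-universe members are
excluded from testing and from the correction count), and pre-ranked GSEA
with a Kolmogorov-Smirnov running-sum statistic, |score|^p hit weights and a
gene-label permutation null with the +1 Monte-Carlo correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pmap.errors import ConfigError, DataError
from pmap.io_formats import GeneSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OraResult:
    pathway: str
    overlap: int
    pathway_size: int
    universe_size: int
    draws: int
    p_raw: float
    p_adj: float
    significant: bool


def ora(query: set[str], sets: Mapping[str, GeneSet], universe: set[str],
        alpha: float = 0.05, min_genes: int = 5) -> list[OraResult]:
    """Hypergeometric upper-tail test per pathway, Bonferroni-adjusted.

    All counts are restricted to the universe.  Query genes outside the
    universe are intersected away with a log message.
    """
    if not universe:
        raise DataError("empty universe")
    stray = query - universe
    if stray:
        logger.info("%d query gene(s) outside universe dropped", len(stray))
    query = query & universe

    tested: list[tuple[str, int, int]] = []
    for name in sorted(sets):
        members = set(sets[name].genes) & universe
        if len(members) < min_genes:
            continue
        tested.append((name, len(members), len(query & members)))

    n_tested = len(tested)
    results = []
    for name, size, overlap in tested:
        # P(X >= overlap), X ~ Hypergeom(N=universe, K=size, n=draws)
        p_raw = float(stats.hypergeom.sf(overlap - 1, len(universe), size,
                                         len(query)))
        p_adj = min(1.0, p_raw * n_tested)
        results.append(OraResult(
            pathway=name, overlap=overlap, pathway_size=size,
            universe_size=len(universe), draws=len(query),
            p_raw=p_raw, p_adj=p_adj,
            significant=p_adj < alpha,
        ))
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.pathway))
    return results


def ora_to_frame(results: Sequence[OraResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in results],
        columns=["pathway", "overlap", "pathway_size", "universe_size",
                 "draws", "p_raw", "p_adj", "significant"],
    )


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GseaResult:
    gene_set: str
    es: float
    nes: float
    np_value: float
    n_perm: int
    size: int
    leading_edge: tuple[str, ...]


def _enrichment_score(scores: np.ndarray, hit_mask: np.ndarray,
                      p: float) -> tuple[float, int]:
    """KS-style running-sum ES and the index of its extremum.

    Hits step up by |score|^p normalized over hits; misses step down by
    1/(N - n_hits).  ES is the signed extremum of the running sum.
    """
    n = scores.size
    n_hits = int(hit_mask.sum())
    weights = np.abs(scores) ** p
    hit_weights = np.where(hit_mask, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:
        # all-zero scores under p>0: fall back to uniform hit steps
        hit_weights = hit_mask.astype(float)
        total = float(n_hits)
    steps = hit_weights / total - (~hit_mask) / float(n - n_hits)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def gsea_preranked(ranking: Sequence[tuple[str, float]],
                   sets: Mapping[str, GeneSet],
                   n_perm: int = 1000, p: float = 1.0,
                   seed: int | None = None) -> list[GseaResult]:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``ranking`` is an ordered (gene, score) list, best first; it is re-sorted
    descending by score with ties broken by symbol so the order is strict.
    The null randomly reassigns which ranked genes belong to the set (label
    swap); np = (1 + #{|ES_perm| >= |ES_obs|}) / (n_perm + 1) and
    NES = ES / mean |same-sign permuted ES|.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    genes = [g for g, _ in ranking]
    if len(set(genes)) != len(genes):
        raise DataError("duplicate genes in ranking")
    order = sorted(ranking, key=lambda t: (-t[1], t[0]))
    genes = [g for g, _ in order]
    scores = np.array([s for _, s in order], dtype=float)
    if not np.all(np.isfinite(scores)):
        raise DataError("non-finite scores in ranking")
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    results = []
    for name in sorted(sets):
        members = set(sets[name].genes)
        positions = sorted(gene_pos[g] for g in members if g in gene_pos)
        n_hits = len(positions)
        if n_hits == 0:
            logger.info("gene set %s has no overlap with ranking; skipped", name)
            continue
        if n_hits == n:
            results.append(GseaResult(name, 0.0, 0.0, 1.0, n_perm, n_hits, ()))
            continue
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[positions] = True
        es, i_ext = _enrichment_score(scores, hit_mask, p)

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=n_hits, replace=False)] = True
            perm_es[b], _ = _enrichment_score(scores, perm_mask, p)
        np_value = (1.0 + np.sum(np.abs(perm_es) >= abs(es))) / (n_perm + 1.0)
        same_sign = perm_es[perm_es * es > 0] if es != 0 else perm_es
        denom = np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        nes = float(es / denom) if denom and np.isfinite(denom) else 0.0

        if es >= 0:
            leading = tuple(genes[i] for i in range(i_ext + 1) if hit_mask[i])
        else:
            leading = tuple(genes[i] for i in range(i_ext, n) if hit_mask[i])
        results.append(GseaResult(
            gene_set=name, es=es, nes=nes, np_value=float(np_value),
            n_perm=n_perm, size=n_hits, leading_edge=leading,
        ))
    results.sort(key=lambda r: (r.np_value, -abs(r.es), r.gene_set))
    return results


def gsea_to_frame(results: Sequence[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "gene_set": r.gene_set, "es": r.es, "nes": r.nes,
            "np": r.np_value, "n_perm": r.n_perm, "size": r.size,
            "leading_edge": ",".join(r.leading_edge),
        } for r in results],
        columns=["gene_set", "es", "nes", "np", "n_perm", "size",
                 "leading_edge"],
    )
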