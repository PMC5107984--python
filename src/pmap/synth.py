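"""Synthetic, statistically structured pipeline inputs with planted truth.

Everything downstream is testable offline: expression with planted two-state
genes per phenotype class, per-sample dose-response curves from a known
four-parameter logistic, a preferential-attachment PPI graph rewired so each
planted N1 gene touches enough planted PDEGs of its class, toy GMT gene sets
and an optional knockdown screen.  A fixed seed plus identical config yields
bit-identical outputs.

The Gaussian log2 noise model is a stand-in for expression variability, not a
claim about any particular dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from pmap import io_formats, phenotyping
from pmap.errors import ConfigError, DataError
from pmap.io_formats import ExpressionMatrix, GeneSet, GeneSetCollection
from pmap.phenotyping import (DEFAULT_CLASS_MAP, PhenotypeAssignment,
                              phenotype_classes)

logger = logging.getLogger(__name__)

# 9-point grids: zero anchor + 8 positive doses
DOSE_GRIDS: dict[str, tuple[float, ...]] = {
    "anthracycline": (0, 0.0156, 0.03125, 0.0625, 0.125, 0.25, 0.55, 1, 2),   # uM
    "taxane": (0, 0.01, 0.1, 1, 10, 50, 100, 1000, 5000),                     # nM
}
DOSE_UNITS = {"anthracycline": "uM", "taxane": "nM"}


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 400
    n_samples_per_condition: int = 40
    drugs: tuple[tuple[str, str], ...] = tuple(sorted(DEFAULT_CLASS_MAP.items()))
    groups: tuple[str, ...] = ("African", "Caucasian", "Chinese")
    n_planted_pdegs_per_class: int = 20
    pdeg_effect_size: float = 2.0
    noise_sd: float = 0.5
    ppi_n_nodes: int = 600
    ppi_attachment: int = 2
    n_planted_n1: int = 3
    planted_n1_min_pdeg_links: int = 4
    k: int = 15
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    ec50_log10_spread: float = 0.5
    dr_noise_sd: float = 0.05
    hill: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_per_condition",
                     "n_planted_pdegs_per_class", "ppi_n_nodes",
                     "ppi_attachment", "n_planted_n1", "k"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.planted_n1_min_pdeg_links < 2:
            raise ConfigError("planted_n1_min_pdeg_links must be >= 2")
        n_classes = len({cls for _, cls in self.drugs}) * 2
        needed = n_classes * self.n_planted_pdegs_per_class \
            + n_classes * self.n_planted_n1
        if needed >= self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {needed} planted genes"
            )
        if self.planted_n1_min_pdeg_links > self.n_planted_pdegs_per_class:
            raise ConfigError("planted N1 wiring infeasible: too few planted PDEGs")
        if self.ppi_n_nodes < self.n_genes:
            raise ConfigError("ppi_n_nodes must be >= n_genes")
        if self.n_samples_per_condition < 2 * self.k:
            raise ConfigError("n_samples_per_condition must be >= 2k")

    @property
    def class_map(self) -> dict[str, str]:
        return dict(self.drugs)

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure: which genes were made PDEGs / N1, and PF signs."""

    planted_pdegs: dict[str, set[str]] = field(default_factory=dict)
    planted_n1: dict[str, set[str]] = field(default_factory=dict)
    planted_pf_sign: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for cls, n1 in self.planted_n1.items():
            if n1 & self.planted_pdegs.get(cls, set()):
                raise DataError(f"planted N1 overlaps planted PDEGs in {cls}")


def gene_names(config: SynthConfig) -> list[str]:
    width = len(str(config.ppi_n_nodes))
    return [f"G{i:0{width}d}" for i in range(config.ppi_n_nodes)]


def sample_names(config: SynthConfig) -> dict[str, list[str]]:
    """Per-group sample panels (shared across drugs within a group)."""
    return {
        g: [f"{g}_s{i:03d}" for i in range(config.n_samples_per_condition)]
        for g in config.groups
    }


def plant_truth(config: SynthConfig) -> GroundTruth:
    """Deterministically allocate disjoint planted PDEG / N1 gene blocks."""
    names = gene_names(config)[: config.n_genes]
    classes = phenotype_classes(config.class_map)
    truth = GroundTruth()
    cursor = 0
    for cls in classes:
        block = set(names[cursor: cursor + config.n_planted_pdegs_per_class])
        cursor += config.n_planted_pdegs_per_class
        truth.planted_pdegs[cls.name] = block
    for cls in classes:
        block = set(names[cursor: cursor + config.n_planted_n1])
        cursor += config.n_planted_n1
        truth.planted_n1[cls.name] = block
        sign = +1 if cls.response == "sensitive" else -1
        for g in block:
            truth.planted_pf_sign[g] = sign
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# EC50 / dose-response
# ---------------------------------------------------------------------------


def _true_ec50s(config: SynthConfig) -> pd.DataFrame:
    """Latent per-sample EC50s; the per-class latent is shared across a
    class's drugs so extreme phenotypes coincide within a drug class."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    panels = sample_names(config)
    classes = sorted({cls for _, cls in config.drugs})
    rows = []
    for group in config.groups:
        latent = {cls: rng.normal(size=config.n_samples_per_condition)
                  for cls in classes}
        for drug, cls in config.drugs:
            grid = np.asarray(DOSE_GRIDS[cls])
            center = float(np.exp(np.mean(np.log(grid[grid > 0]))))
            jitter = rng.normal(scale=0.05, size=config.n_samples_per_condition)
            log10_ec50 = (np.log10(center)
                          + config.ec50_log10_spread * latent[cls] + jitter)
            for sid, v in zip(panels[group], 10.0 ** log10_ec50):
                rows.append({"sample_id": sid, "drug": drug, "group": group,
                             "ec50": float(v), "units": DOSE_UNITS[cls]})
    return pd.DataFrame(rows, columns=["sample_id", "drug", "group", "ec50",
                                       "units"])


def generate_ec50(config: SynthConfig) -> pd.DataFrame:
    """EC50 table ready for :func:`pmap.phenotyping.assign_phenotypes`."""
    return _true_ec50s(config)


def generate_dose_response(config: SynthConfig,
                           n_replicates: int = 3,
                           dose_grids: Mapping[str, Sequence[float]] | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw viability table from a known 4PL, plus the true EC50s.

    Returns (viability, truth): viability has one row per sample x drug x
    dose x replicate; truth has columns sample_id, drug, ec50_true.  The true
    EC50s are the same latents that :func:`generate_ec50` reports.
    """
    grids = {cls: np.asarray(g, dtype=float)
             for cls, g in (dose_grids or DOSE_GRIDS).items()}
    for cls, grid in grids.items():
        pos = grid[grid != 0]
        if np.any(pos <= 0):
            raise ConfigError(f"{cls}: non-positive dose other than zero anchor")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    truth = _true_ec50s(config)
    class_map = config.class_map
    rows = []
    for r in truth.itertuples():
        grid = grids[class_map[r.drug]]
        clean = phenotyping.logistic4(np.repeat(grid, n_replicates),
                                      0.1, 1.0, r.ec50, config.hill)
        noisy = clean + rng.normal(scale=config.dr_noise_sd, size=clean.size)
        for j, (dose, v) in enumerate(zip(np.repeat(grid, n_replicates), noisy)):
            rows.append({
                "sample_id": r.sample_id, "drug": r.drug, "group": r.group,
                "dose": float(dose), "replicate": j % n_replicates,
                "viability": float(v),
            })
    viability = pd.DataFrame(rows, columns=["sample_id", "drug", "group",
                                            "dose", "replicate", "viability"])
    truth = truth.rename(columns={"ec50": "ec50_true"})
    return viability, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(config: SynthConfig,
                        assignments: Sequence[PhenotypeAssignment],
                        truth: GroundTruth | None = None
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Baseline log2 expression with planted two-state PDEGs.

    Planted PDEGs of a class get ``pdeg_effect_size`` added in every sample
    belonging to that class's response tail in any member condition; all
    other gene/sample cells are baseline mean plus Gaussian noise.
    """
    if truth is None:
        truth = plant_truth(config)
    panels = sample_names(config)
    all_samples = [s for g in config.groups for s in panels[g]]
    by_condition = {(a.drug, a.group): a for a in assignments}
    for drug, _cls in config.drugs:
        for group in config.groups:
            if (drug, group) not in by_condition:
                raise ConfigError(f"assignment missing condition ({drug}, {group})")
            a = by_condition[(drug, group)]
            if set(a.ranked_samples) - set(all_samples):
                raise ConfigError(
                    f"assignment for ({drug}, {group}) names unknown samples"
                )

    names = gene_names(config)[: config.n_genes]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)
    values = baseline[:, None] + rng.normal(
        scale=config.noise_sd, size=(config.n_genes, len(all_samples)))

    sample_index = {s: j for j, s in enumerate(all_samples)}
    gene_index = {g: i for i, g in enumerate(names)}
    class_map = config.class_map
    for cls in phenotype_classes(class_map):
        tail_samples: set[str] = set()
        for drug in cls.drugs:
            for group in config.groups:
                a = by_condition[(drug, group)]
                tail = (a.sensitive_tail if cls.response == "sensitive"
                        else a.resistant_tail)
                tail_samples.update(tail)
        cols = [sample_index[s] for s in sorted(tail_samples)]
        for gene in sorted(truth.planted_pdegs[cls.name]):
            values[gene_index[gene], cols] += config.pdeg_effect_size

    meta = {}
    for group in config.groups:
        for s in panels[group]:
            meta[s] = {"group": group, "drug": "none"}
    expr = ExpressionMatrix(genes=names, samples=all_samples, values=values,
                            sample_meta=meta)
    return expr, truth


# ---------------------------------------------------------------------------
# PPI graph
# ---------------------------------------------------------------------------


def generate_ppi(config: SynthConfig, truth: GroundTruth
                 ) -> list[tuple[str, str]]:
    """Scale-free simple graph with planted N1 wiring.

    Preferential-attachment skeleton over the full node namespace, then
    rewired: each planted N1 gene loses accidental edges to planted PDEGs of
    other classes and gains edges to ``planted_n1_min_pdeg_links`` randomly
    chosen planted PDEGs of its own class.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 19]))
    skeleton = nx.barabasi_albert_graph(
        config.ppi_n_nodes, config.ppi_attachment,
        seed=int(rng.integers(2**31)))
    names = gene_names(config)
    graph = nx.relabel_nodes(skeleton, dict(enumerate(names)))

    all_planted_pdegs = {g for s in truth.planted_pdegs.values() for g in s}
    for cls_name in sorted(truth.planted_n1):
        own_pdegs = truth.planted_pdegs[cls_name]
        foreign = all_planted_pdegs - own_pdegs
        for g in sorted(truth.planted_n1[cls_name]):
            for nb in sorted(foreign & set(graph.adj[g])):
                graph.remove_edge(g, nb)
            targets = rng.choice(sorted(own_pdegs),
                                 size=config.planted_n1_min_pdeg_links,
                                 replace=False)
            for p in targets:
                graph.add_edge(g, str(p))
    graph.remove_edges_from(nx.selfloop_edges(graph))
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    logger.info("synthetic PPI: %d nodes, %d edges",
                graph.number_of_nodes(), len(edges))
    return edges


# ---------------------------------------------------------------------------
# Gene sets and knockdown screen
# ---------------------------------------------------------------------------


def generate_gene_sets(config: SynthConfig, truth: GroundTruth,
                       n_random_sets: int = 5) -> GeneSetCollection:
    """Toy GMT collection: one set per planted PDEG block plus random sets."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    names = gene_names(config)[: config.n_genes]
    collection = GeneSetCollection()
    for cls_name in sorted(truth.planted_pdegs):
        members = tuple(sorted(truth.planted_pdegs[cls_name]))
        collection.add(GeneSet(f"PLANTED_{cls_name.upper().replace('-', '_')}",
                               f"planted PDEGs for {cls_name}", members))
    for i in range(n_random_sets):
        size = int(rng.integers(8, 25))
        members = tuple(sorted(rng.choice(names, size=size, replace=False)))
        collection.add(GeneSet(f"RANDOM_SET_{i:02d}", "random decoy", members))
    return collection


def generate_screen(pf_sums: Mapping[str, int], config: SynthConfig,
                    cell_lines: Sequence[str] = ("LINE_A", "LINE_B"),
                    drugs: Sequence[str] = ("drug_x", "drug_y"),
                    agreement: float = 0.5) -> pd.DataFrame:
    """Knockdown outcome table with a tunable PF-sign agreement rate."""
    from pmap import consistency as cons

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    rows = []
    for gene in sorted(pf_sums):
        predicted = cons.predict_direction(int(pf_sums[gene]))
        if predicted is None:
            predicted = cons.NON_RESPONSIVE
        if rng.random() < agreement:
            token = predicted
        else:
            others = sorted(cons.OBSERVATION_TOKENS - {predicted})
            token = others[int(rng.integers(len(others)))]
        for cell in cell_lines:
            for drug in drugs:
                rows.append({"gene": gene, "cell_line": cell, "drug": drug,
                             "observation": token})
    return pd.DataFrame(rows, columns=["gene", "cell_line", "drug",
                                       "observation"])


# ---------------------------------------------------------------------------
# Fixture directory
# ---------------------------------------------------------------------------


def write_fixture_dir(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and persist a complete, pipeline-ready input directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = plant_truth(config)
    ec50 = generate_ec50(config)
    assignments = phenotyping.assign_phenotypes(ec50, k=config.k)
    expr, truth = generate_expression(config, assignments, truth)
    edges = generate_ppi(config, truth)
    sets = generate_gene_sets(config, truth)
    viability, dr_truth = generate_dose_response(config)

    paths = {
        "expression": outdir / "expression.tsv",
        "ec50": outdir / "ec50.tsv",
        "dose_response": outdir / "dose_response.tsv",
        "ppi": outdir / "ppi.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }
    io_formats.write_expression(expr, paths["expression"])
    io_formats.write_ec50(ec50, paths["ec50"])
    io_formats.write_table(viability, paths["dose_response"])
    io_formats.write_ppi(edges, paths["ppi"])
    io_formats.write_gmt(sets, paths["gene_sets"])
    io_formats.write_json({
        "planted_pdegs": {k: sorted(v) for k, v in truth.planted_pdegs.items()},
        "planted_n1": {k: sorted(v) for k, v in truth.planted_n1.items()},
        "planted_pf_sign": truth.planted_pf_sign,
        "dose_response_truth": dr_truth.to_dict(orient="list"),
        "class_map": config.class_map,
        "k": config.k,
        "seed": config.seed,
    }, paths["ground_truth"])
    return paths
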