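"""End-to-end pipeline orchestration with plain-file stage handoff.

Stage order: phenotyping -> PDEG calling -> DRN mining per phenotype class ->
PF scoring per drug class -> enrichment -> optional screen consistency.
Every stage persists TSV/JSON artifacts into the output directory and the run
manifest records a content hash and row count for each, so reruns under the
same seed are verifiably identical and any stage can be rerun from the saved
intermediates.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from pmap import __version__, consistency, drn, enrichment, io_formats, pdeg, phenotyping
from pmap.errors import ConfigError, StageError
from pmap.phenotyping import DEFAULT_CLASS_MAP

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression: str
    ppi: str
    ec50: str | None = None
    dose_response: str | None = None
    gene_sets: str | None = None
    screen: str | None = None
    outdir: str = "pmap_out"
    k: int = 15
    class_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    alpha: float = 1e-3
    up_z: float = 1.0
    min_links: int = 2
    n_perm: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.ec50 is None and self.dose_response is None:
            raise ConfigError("need either an EC50 table or raw dose-response data")
        if self.k < 1 or self.min_links < 1 or self.n_perm < 1:
            raise ConfigError("k, min_links and n_perm must be positive")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        for name in ("expression", "ppi", "ec50", "dose_response",
                     "gene_sets", "screen"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: pipeline config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _row_count(path: Path) -> int:
    with open(path, "rb") as fh:
        return sum(1 for _ in fh)


class _Manifest:
    def __init__(self, config: PipelineConfig) -> None:
        self.data: dict[str, Any] = {
            "version": __version__,
            "seed": config.seed,
            "inputs": {},
            "outputs": {},
            "timings_s": {},
        }

    def add_input(self, name: str, path: str | Path) -> None:
        p = Path(path)
        self.data["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    def add_output(self, path: Path) -> None:
        self.data["outputs"][path.name] = {
            "sha256": _sha256(path), "rows": _row_count(path),
        }

    def time_stage(self, name: str, seconds: float) -> None:
        self.data["timings_s"][name] = round(seconds, 3)


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest dict (also written to disk).

    A stage failure writes a FAILED marker naming the stage and re-raises as
    :class:`StageError`; artifacts from completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump({k: v for k, v in config.__dict__.items()}, fh,
                       sort_keys=True)
    manifest = _Manifest(config)
    for name in ("expression", "ppi", "ec50", "dose_response", "gene_sets",
                 "screen"):
        if getattr(config, name) is not None:
            manifest.add_input(name, getattr(config, name))

    state: dict[str, Any] = {}
    stages = [
        ("phenotype", _stage_phenotype),
        ("pdeg", _stage_pdeg),
        ("drn", _stage_drn),
        ("enrichment", _stage_enrichment),
        ("consistency", _stage_consistency),
    ]
    for name, fn in stages:
        logger.info("=== stage %s ===", name)
        t0 = time.perf_counter()
        try:
            outputs = fn(config, state, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise StageError(f"stage {name} failed: {exc}") from exc
        manifest.time_stage(name, time.perf_counter() - t0)
        for path in outputs:
            manifest.add_output(path)
            logger.info("  wrote %s (%d rows)", path.name, _row_count(path))
    io_formats.write_json(manifest.data, outdir / "manifest.json")
    return manifest.data


def _stage_phenotype(config: PipelineConfig, state: dict, outdir: Path) -> list[Path]:
    if config.ec50 is not None:
        ec50 = io_formats.read_ec50(config.ec50)
    else:
        raw = io_formats.read_table(config.dose_response)
        groups = (raw.drop_duplicates("sample_id")
                     .set_index("sample_id")["group"].to_dict())
        drs = []
        for (sid, drug), sub in raw.groupby(["sample_id", "drug"]):
            drs.append(phenotyping.DoseResponse(
                sample_id=str(sid), drug=str(drug),
                doses=sub["dose"].to_numpy(),
                viability=sub["viability"].to_numpy(),
            ))
        ec50 = phenotyping.fit_ec50_table(drs, groups)
        io_formats.write_ec50(ec50, outdir / "ec50_fitted.tsv")
    assignments = phenotyping.assign_phenotypes(ec50, k=config.k)
    state["assignments"] = assignments
    frame = phenotyping.assignments_to_frame(assignments)
    path = outdir / "assignments.tsv"
    io_formats.write_table(frame, path)
    out = [path]
    if config.ec50 is None:
        out.append(outdir / "ec50_fitted.tsv")
    return out


def _stage_pdeg(config: PipelineConfig, state: dict, outdir: Path) -> list[Path]:
    expr = io_formats.read_expression(config.expression)
    state["expr"] = expr
    results = []
    for a in state["assignments"]:
        results.extend(pdeg.template_match(expr, a, alpha=config.alpha))
    classes = phenotyping.phenotype_classes(config.class_map)
    state["classes"] = classes
    pdeg_sets = pdeg.call_pdegs(results, expr, state["assignments"], classes,
                                up_z=config.up_z)
    state["pdeg_sets"] = pdeg_sets
    frame = pdeg.pdegs_to_frame(pdeg_sets, results)
    path = outdir / "pdegs.tsv"
    io_formats.write_table(frame, path)
    return [path]


def _stage_drn(config: PipelineConfig, state: dict, outdir: Path) -> list[Path]:
    edges = io_formats.read_ppi(config.ppi)
    graph = drn.build_graph(edges)
    outputs = []
    results: dict[str, drn.DrnResult] = {}
    for cls in state["classes"]:
        pset = state["pdeg_sets"][cls.name]
        result = drn.mine_drn(graph, pset.genes, cls.name,
                              min_links=config.min_links)
        results[cls.name] = result
        cls_dir = outdir / f"drn_{cls.name}"
        cls_dir.mkdir(exist_ok=True)
        io_formats.write_table(
            pd.DataFrame({"gene": sorted(result.n1),
                          "freq": [result.freq_n1[g] for g in sorted(result.n1)]}),
            cls_dir / "n1.tsv")
        io_formats.write_table(
            pd.DataFrame({"gene": sorted(result.n2),
                          "freq": [result.freq_n2[g] for g in sorted(result.n2)]}),
            cls_dir / "n2.tsv")
        io_formats.write_table(
            pd.DataFrame(result.pair_registry, columns=["pdeg", "n1_gene"]),
            cls_dir / "pair_registry.tsv")
        io_formats.write_table(
            pd.DataFrame(result.edges, columns=["gene_a", "gene_b", "roles"]),
            cls_dir / "drn_edges.tsv")
        io_formats.write_table(drn.degree_summary(result),
                               cls_dir / "degree_hist.tsv")
        outputs.extend(sorted(cls_dir.glob("*.tsv")))
    state["drn_results"] = results

    pf_by_class: dict[str, list[drn.PfRecord]] = {}
    for drug_class in sorted({cls.drug_class for cls in state["classes"]}):
        records = drn.pf_scores(results[f"{drug_class}-sensitive"],
                                results[f"{drug_class}-resistant"])
        pf_by_class[drug_class] = records
        path = outdir / f"pf_scores_{drug_class}.tsv"
        io_formats.write_table(drn.pf_to_frame(records), path)
        outputs.append(path)
    state["pf_by_class"] = pf_by_class
    return outputs


def _stage_enrichment(config: PipelineConfig, state: dict, outdir: Path) -> list[Path]:
    if config.gene_sets is None:
        return []
    sets = io_formats.read_gmt(config.gene_sets)
    universe = set(state["expr"].genes)
    outputs = []
    for cls in state["classes"]:
        query = state["pdeg_sets"][cls.name].genes
        results = enrichment.ora(set(query), sets, universe)
        path = outdir / f"ora_{cls.name}.tsv"
        io_formats.write_table(enrichment.ora_to_frame(results), path)
        outputs.append(path)
    for drug_class, records in sorted(state["pf_by_class"].items()):
        ranking = [(r.gene, float(r.pf_n1)) for r in records]
        results = enrichment.gsea_preranked(ranking, sets,
                                            n_perm=config.n_perm,
                                            seed=config.seed)
        path = outdir / f"gsea_{drug_class}.tsv"
        io_formats.write_table(enrichment.gsea_to_frame(results), path)
        outputs.append(path)
    return outputs


def _stage_consistency(config: PipelineConfig, state: dict, outdir: Path) -> list[Path]:
    if config.screen is None:
        return []
    screen = io_formats.read_table(config.screen)
    pf_map: dict[str, int] = {}
    for records in state["pf_by_class"].values():
        for r in records:
            # keep the largest-magnitude score when a gene scores in both classes
            if r.gene not in pf_map or abs(r.pf_sum) > abs(pf_map[r.gene]):
                pf_map[r.gene] = r.pf_sum
    screen = screen[screen["gene"].isin(pf_map)]
    if screen.empty:
        logger.info("no screened gene has a PF score; skipping consistency")
        return []
    calls = consistency.classify_table(screen, pf_map)
    path = outdir / "consistency_calls.tsv"
    io_formats.write_table(consistency.calls_to_frame(calls), path)
    summary = consistency.summarize_screen(calls)
    spath = outdir / "consistency_summary.json"
    io_formats.write_json(summary, spath)
    return [path, spath]
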