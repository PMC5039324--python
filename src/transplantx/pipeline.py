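"""End-to-end orchestration: simulate -> prep -> three scans -> enrichment.

Every stage reads and writes plain TSV so intermediates are inspectable and
each stage can be re-run independently.  A run directory receives the result
files, a JSON manifest of every parameter, library version and input
checksum, and a log.  Runs are deterministic given the config seed: one
master seed sequence hands an independent child seed to every stochastic
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpr_filter import scan_pattern
from .design import SampleDesign
from .enrichment import enrich
from .errors import ParameterError, TransplantxError
from .expression_prep import collapse_isoforms, filter_genes, normalize, size_factors
from .io_formats import (
    SyncTable,
    write_annotation,
    write_count_matrix,
    write_design,
    write_go_map,
)
from .poolseq_cmh import default_pairing, scan_snps
from .syndata import (
    ExpressionSimParams,
    SnpSimParams,
    generate_design,
    simulate_counts,
    simulate_go_annotations,
    simulate_pool_snps,
    split_isoforms,
    with_seed,
)
from .transplant_ancova import scan_expression

logger = logging.getLogger("transplantx")


@dataclass
class RunConfig:
    """Everything a full synthetic run needs; YAML-serializable."""

    out_dir: str = "transplantx_run"
    seed: int = 0
    replicates_per_treatment: int = 2
    pool_size_range: tuple[int, int] = (28, 76)
    expression: ExpressionSimParams = field(default_factory=ExpressionSimParams)
    snps: SnpSimParams = field(default_factory=SnpSimParams)
    n_go_terms: int = 40
    go_background_prob: float = 0.05
    go_planted_factor: float = 8.0
    go_planted_term: str = "GO:9999999"
    alpha: float = 0.05
    scale: str = "log2p1"
    min_minor_count: int = 2
    min_coverage: int = 10
    fdr: str = "BY"
    max_isoforms: int = 3

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "expression" in kwargs and isinstance(kwargs["expression"], dict):
            kwargs["expression"] = ExpressionSimParams(**kwargs["expression"])
        if "snps" in kwargs and isinstance(kwargs["snps"], dict):
            kwargs["snps"] = SnpSimParams(**kwargs["snps"])
        if "pool_size_range" in kwargs:
            kwargs["pool_size_range"] = tuple(kwargs["pool_size_range"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pool_size_range"] = list(self.pool_size_range)
        d["expression"]["depth_factor_range"] = list(
            self.expression.depth_factor_range
        )
        d["snps"]["base_freq_range"] = list(self.snps.base_freq_range)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_all(config: RunConfig) -> Path:
    """Run the whole synthetic pipeline into ``config.out_dir``.

    Stages: simulate (design, contig counts, sync, GO map, truth tables),
    prep (collapse, size factors, normalize, filter), ANCOVA scan, pattern
    scan, CMH scan, GO enrichment of the recovered H2 list.  Returns the run
    directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = _child_seeds(config.seed, 5)
    manifest: dict = {
        "package": "transplantx",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config.to_dict(),
        "derived_seeds": seeds,
        "stages": {},
    }
    try:
        # -- simulate -------------------------------------------------------
        logger.info("stage simulate: seed %d", config.seed)
        design = generate_design(
            config.replicates_per_treatment, config.pool_size_range, seed=seeds[0]
        )
        write_design(design, out / "design.tsv")
        sim = simulate_counts(design, with_seed(config.expression, seeds[1]))
        contig_counts, annot = split_isoforms(
            sim, max_isoforms=config.max_isoforms, seed=seeds[2]
        )
        write_count_matrix(contig_counts, out / "contig_counts.tsv")
        write_annotation(annot, out / "annotation.tsv")
        sim.truth.to_csv(out / "truth_genes.tsv", sep="\t")
        snps = simulate_pool_snps(design, with_seed(config.snps, seeds[3]))
        snps.sync.write(out / "sync.tsv")
        snps.truth.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
        h2_genes = list(sim.truth.index[sim.truth["label"] == "H2"])
        go_map = simulate_go_annotations(
            list(sim.truth.index),
            n_terms=config.n_go_terms,
            planted=(config.go_planted_term, h2_genes, config.go_planted_factor)
            if h2_genes
            else None,
            background_prob=config.go_background_prob,
            seed=seeds[4],
        )
        write_go_map(go_map, out / "go_map.tsv")
        manifest["stages"]["simulate"] = {
            "n_samples": len(design),
            "n_genes": int(sim.counts.shape[0]),
            "n_contigs": int(contig_counts.shape[0]),
            "n_sites": int(snps.sync.n_sites),
        }
        # -- prep -----------------------------------------------------------
        logger.info("stage prep")
        unigenes = collapse_isoforms(contig_counts, annot)
        write_count_matrix(unigenes, out / "unigene_counts.tsv")
        factors = size_factors(unigenes)
        factors.to_csv(out / "size_factors.tsv", sep="\t", header=True)
        normalized = normalize(unigenes, factors)
        write_count_matrix(normalized, out / "normalized_counts.tsv")
        kept, report = filter_genes(normalized)
        write_count_matrix(kept, out / "filtered_counts.tsv")
        report.to_csv(out / "filter_report.tsv", sep="\t")
        manifest["stages"]["prep"] = {
            "n_unigenes": int(unigenes.shape[0]),
            "n_kept": int(kept.shape[0]),
            "size_factors": {k: float(v) for k, v in factors.items()},
        }
        # -- ANCOVA scan ----------------------------------------------------
        logger.info("stage scan-ancova: %d genes", kept.shape[0])
        scan = scan_expression(kept, design, alpha=config.alpha, scale=config.scale)
        scan.to_csv(out / "ancova_results.tsv", sep="\t", float_format="%.6g")
        manifest["stages"]["scan_ancova"] = scan.attrs["class_counts"]
        # -- pattern scan ---------------------------------------------------
        logger.info("stage scan-pattern")
        pattern_genes = scan_pattern(kept, design)
        (out / "pattern_genes.txt").write_text(
            "".join(g + "\n" for g in pattern_genes)
        )
        manifest["stages"]["scan_pattern"] = {"n_pattern": len(pattern_genes)}
        # -- CMH scan -------------------------------------------------------
        logger.info("stage scan-cmh: %d sites", snps.sync.n_sites)
        cmh = scan_snps(
            snps.sync,
            design,
            pairing=default_pairing(design),
            alpha=config.alpha,
            min_minor_count=config.min_minor_count,
            min_coverage=config.min_coverage,
        )
        cmh.table.to_csv(out / "cmh_results.tsv", sep="\t", index=False,
                         float_format="%.6g")
        (out / "cmh_significant_contigs.txt").write_text(
            "".join(c + "\n" for c in cmh.significant_contigs)
        )
        manifest["stages"]["scan_cmh"] = {
            "n_sites": cmh.n_sites,
            "n_testable": cmh.n_testable,
            "n_significant": cmh.n_significant,
            "n_significant_contigs": len(cmh.significant_contigs),
            "bonferroni_threshold": cmh.bonferroni_threshold,
        }
        # -- enrichment -----------------------------------------------------
        logger.info("stage enrich")
        h2_hits = list(scan.index[scan["hypothesis"] == "H2"])
        universe = list(kept.index)
        if h2_hits:
            table = enrich(h2_hits, universe, go_map, fdr=config.fdr)
        else:
            table = pd.DataFrame()
        table.to_csv(out / "enrichment_h2.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "list_size": len(h2_hits),
            "n_terms_tested": int(len(table)),
        }
    except TransplantxError as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest["checksums"] = {
        f.name: _sha256(f)
        for f in sorted(out.iterdir())
        if f.suffix in (".tsv", ".txt")
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return out
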