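"""End-to-end orchestration: scan -> thresholds -> intervals -> candidates
-> convergence -> ranking.

The pipeline is configured from a YAML file (see :func:`validate_config`)
in which each data role (genotypes, phenotype, annotation, gene sets) is
either a path to a file or a synthetic-generation block, never both.  A
fixed seed yields bit-identical reports and artifacts: every stage draws
its own sub-seed from one seed sequence.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as io_formats
from .annotation import GeneAnnotation, genes_in_interval, read_gene_annotation
from .containers import GenotypeMatrix, PhenotypeVector
from .convergence import bootstrap_hisim, rank_candidates
from .errors import ConfigError, QtlConvergeError
from .scan import (
    fit_multi_qtl,
    pair_scan,
    permutation_thresholds,
    single_scan,
    support_interval,
)
from .simulate import (
    GeneSetCorpusSpec,
    QtlArchitecture,
    generate_gene_annotation,
    generate_geneset_corpus,
    simulate_phenotype,
    simulate_ri_genotypes,
    uniform_marker_map,
)

logger = logging.getLogger("qtlconverge")

__all__ = ["PipelineConfig", "PipelineReport", "validate_config", "run_pipeline"]

_ROLES = ("genotypes", "phenotype", "annotation", "gene_sets")

_DEFAULTS = {
    "scan": {
        "n_perm": 1000,
        "drop": 1.5,
        "significant_percentile": 95.0,
        "suggestive_percentile": 63.0,
        "peak_policy": "suggestive",
        "pair_scan": False,
        "pair_scan_n_perm": 0,
        "pair_min_separation": "chromosome",
    },
    "candidates": {"biotypes": ["protein_coding"], "containment": False},
    "convergence": {
        "fraction": 0.75,
        "iterations": 1000,
        "retention": 0.5,
        "min_sets": 2,
        "resample_mode": "round",
    },
}

_SYNTH_GENO_DEFAULTS = {
    "n_strains": 200,
    "n_chromosomes": 10,
    "chrom_length_bp": 120_000_000,
    "markers_per_chromosome": 15,
    "recomb_fraction": 0.25,
}

_SYNTH_ANNOT_DEFAULTS = {
    "n_genes": 16000,
    "biotypes": {"protein_coding": 0.8, "lncRNA": 0.1, "pseudogene": 0.1},
    "extra_genes": [],
}

_SYNTH_SETS_DEFAULTS = {
    "n_sets": 113,
    "mean_set_size": 66.5,
    "planted": [],
    "max_background_membership": None,
}


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline configuration."""

    seed: int
    inputs: dict
    synthetic: dict
    scan: dict
    candidates: dict
    convergence: dict

    def echo(self) -> dict:
        return {
            "seed": self.seed,
            "inputs": self.inputs,
            "synthetic": self.synthetic,
            "scan": self.scan,
            "candidates": self.candidates,
            "convergence": self.convergence,
        }


@dataclass
class PipelineReport:
    """Machine-readable summary of one pipeline run."""

    settings: dict
    sub_seeds: dict
    thresholds: dict
    peaks: list
    intervals: list
    candidate_counts: list
    model: dict | None
    pair_scan: dict | None
    ranking: list
    stage_seconds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "settings": self.settings,
            "sub_seeds": self.sub_seeds,
            "thresholds": self.thresholds,
            "peaks": self.peaks,
            "intervals": self.intervals,
            "candidate_counts": self.candidate_counts,
            "model": self.model,
            "pair_scan": self.pair_scan,
            "ranking": self.ranking,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _check_unknown(block: dict, allowed, path: str, problems: list[str]):
    for key in block:
        if key not in allowed:
            problems.append(f"unknown key {path}.{key}")


def _merge_defaults(block: dict, defaults: dict) -> dict:
    merged = dict(defaults)
    merged.update(block)
    return merged


def validate_config(source) -> PipelineConfig:
    """Parse, default and range-check a pipeline configuration.

    ``source`` is a path to a YAML file or an already-parsed mapping.
    Every problem is reported with its key path; defaults are 1000
    permutations, a 1.5-LOD drop, bootstrap at 75% for 1000 iterations
    with 50% retention, and a protein-coding biotype filter.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")

    problems: list[str] = []
    _check_unknown(raw, {"seed", "inputs", "synthetic", "scan", "candidates", "convergence"}, "config", problems)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        problems.append("config.seed: must be a non-negative integer")

    inputs = dict(raw.get("inputs") or {})
    synthetic = dict(raw.get("synthetic") or {})
    _check_unknown(inputs, set(_ROLES), "inputs", problems)
    _check_unknown(synthetic, set(_ROLES), "synthetic", problems)
    for role in _ROLES:
        has_input = role in inputs
        has_synth = role in synthetic
        if has_input and has_synth:
            problems.append(f"config: role {role!r} given both as inputs.{role} and synthetic.{role}")
        if not has_input and not has_synth:
            problems.append(f"config: role {role!r} missing (provide inputs.{role} or synthetic.{role})")

    scan = _merge_defaults(dict(raw.get("scan") or {}), _DEFAULTS["scan"])
    _check_unknown(scan, set(_DEFAULTS["scan"]), "scan", problems)
    if not (isinstance(scan["n_perm"], int) and scan["n_perm"] >= 1):
        problems.append("scan.n_perm: must be a positive integer")
    if not scan["drop"] > 0:
        problems.append("scan.drop: must be positive")
    for key in ("significant_percentile", "suggestive_percentile"):
        if not 0 < scan[key] < 100:
            problems.append(f"scan.{key}: must lie in (0, 100)")
    if scan["peak_policy"] not in ("suggestive", "significant"):
        problems.append("scan.peak_policy: must be 'suggestive' or 'significant'")

    candidates = _merge_defaults(dict(raw.get("candidates") or {}), _DEFAULTS["candidates"])
    _check_unknown(candidates, set(_DEFAULTS["candidates"]), "candidates", problems)

    convergence = _merge_defaults(dict(raw.get("convergence") or {}), _DEFAULTS["convergence"])
    _check_unknown(convergence, set(_DEFAULTS["convergence"]), "convergence", problems)
    if not 0 < convergence["fraction"] <= 1:
        problems.append("convergence.fraction: must lie in (0, 1]")
    if not (isinstance(convergence["iterations"], int) and convergence["iterations"] >= 1):
        problems.append("convergence.iterations: must be a positive integer")
    if not 0 <= convergence["retention"] < 1:
        problems.append("convergence.retention: must lie in [0, 1)")
    if convergence["min_sets"] < 2:
        problems.append("convergence.min_sets: must be >= 2")

    if "genotypes" in synthetic:
        synthetic["genotypes"] = _merge_defaults(
            dict(synthetic["genotypes"] or {}), _SYNTH_GENO_DEFAULTS
        )
        _check_unknown(synthetic["genotypes"], set(_SYNTH_GENO_DEFAULTS), "synthetic.genotypes", problems)
        if not 0 <= synthetic["genotypes"]["recomb_fraction"] <= 0.5:
            problems.append("synthetic.genotypes.recomb_fraction: must lie in [0, 0.5]")
    if "phenotype" in synthetic:
        block = dict(synthetic["phenotype"] or {})
        _check_unknown(block, {"additive", "epistatic"}, "synthetic.phenotype", problems)
        block.setdefault("additive", [])
        block.setdefault("epistatic", None)
        synthetic["phenotype"] = block
        if "genotypes" not in synthetic:
            problems.append("synthetic.phenotype requires synthetic.genotypes")
    if "annotation" in synthetic:
        synthetic["annotation"] = _merge_defaults(
            dict(synthetic["annotation"] or {}), _SYNTH_ANNOT_DEFAULTS
        )
        _check_unknown(synthetic["annotation"], set(_SYNTH_ANNOT_DEFAULTS), "synthetic.annotation", problems)
    if "gene_sets" in synthetic:
        synthetic["gene_sets"] = _merge_defaults(
            dict(synthetic["gene_sets"] or {}), _SYNTH_SETS_DEFAULTS
        )
        _check_unknown(synthetic["gene_sets"], set(_SYNTH_SETS_DEFAULTS), "synthetic.gene_sets", problems)

    if problems:
        raise ConfigError(problems)
    return PipelineConfig(
        seed=seed,
        inputs=inputs,
        synthetic=synthetic,
        scan=scan,
        candidates=candidates,
        convergence=convergence,
    )


# ---------------------------------------------------------------------------
# stage helpers


def _sub_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(6) % (2**31)
    names = ["genotypes", "phenotype", "annotation", "gene_sets", "permutations", "bootstrap"]
    return {name: int(s) for name, s in zip(names, state)}


def _resolve_marker(genotypes: GenotypeMatrix, ref: dict) -> str:
    if "marker" in ref:
        genotypes.markers.index_of(ref["marker"])
        return ref["marker"]
    idx = genotypes.markers.indices_on(str(ref["chrom"]))
    if not len(idx):
        raise ConfigError(f"no markers on chromosome {ref['chrom']!r}")
    return str(genotypes.markers.marker[idx[int(ref["index"])]])


def _materialize_genotypes(config: PipelineConfig, seeds: dict) -> GenotypeMatrix:
    if "genotypes" in config.inputs:
        return io_formats.read_genotypes(config.inputs["genotypes"])
    block = config.synthetic["genotypes"]
    marker_map = uniform_marker_map(
        n_chromosomes=block["n_chromosomes"],
        chrom_length_bp=block["chrom_length_bp"],
        markers_per_chromosome=block["markers_per_chromosome"],
    )
    return simulate_ri_genotypes(
        block["n_strains"], marker_map, block["recomb_fraction"], seed=seeds["genotypes"]
    )


def _materialize_phenotype(config, genotypes, seeds) -> PhenotypeVector:
    if "phenotype" in config.inputs:
        return io_formats.read_phenotype(config.inputs["phenotype"])
    block = config.synthetic["phenotype"]
    additive = tuple(
        (_resolve_marker(genotypes, ref), float(ref["variance"])) for ref in block["additive"]
    )
    epistatic = None
    if block["epistatic"]:
        ep = block["epistatic"]
        epistatic = (
            _resolve_marker(genotypes, ep["a"]),
            _resolve_marker(genotypes, ep["b"]),
            float(ep["variance"]),
        )
    arch = QtlArchitecture(additive=additive, epistatic=epistatic)
    return simulate_phenotype(genotypes, arch, seed=seeds["phenotype"])


def _materialize_annotation(config, genotypes, seeds) -> list[GeneAnnotation]:
    if "annotation" in config.inputs:
        return read_gene_annotation(config.inputs["annotation"])
    block = config.synthetic["annotation"]
    chrom_lengths = {}
    geno_block = config.synthetic.get("genotypes", _SYNTH_GENO_DEFAULTS)
    for c in genotypes.markers.chromosomes:
        chrom_lengths[c] = geno_block["chrom_length_bp"]
    genes = generate_gene_annotation(
        chrom_lengths,
        block["n_genes"],
        biotype_mix=block["biotypes"],
        seed=seeds["annotation"],
    )
    for extra in block["extra_genes"]:
        genes.append(
            GeneAnnotation(
                gene_id=extra["id"],
                symbol=extra.get("symbol", extra["id"]),
                chrom=str(extra["chrom"]),
                start=int(extra["start"]),
                end=int(extra["end"]),
                biotype=extra.get("biotype", "protein_coding"),
            )
        )
    return genes


def _materialize_corpus(config, annotation, seeds):
    if "gene_sets" in config.inputs:
        return io_formats.read_gmt(config.inputs["gene_sets"])
    block = config.synthetic["gene_sets"]
    spec = GeneSetCorpusSpec(
        n_sets=block["n_sets"],
        mean_set_size=block["mean_set_size"],
        universe=tuple(g.gene_id for g in annotation),
        planted=tuple((p["gene"], int(p["count"])) for p in block["planted"]),
        max_background_membership=block["max_background_membership"],
        seed=seeds["gene_sets"],
    )
    return generate_geneset_corpus(spec)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineReport:
    """Execute the full analysis and return a machine-readable report.

    Stages: single-marker scan; permutation thresholds; per-chromosome
    peaks crossing the configured threshold expanded to LOD-drop support
    intervals; positional candidates per interval (pooled, with interval
    provenance); a multi-locus additive model over the peak markers;
    optionally a genome-wide pair scan; the bootstrapped HiSim graph of
    the gene-set corpus; and the pooled candidate ranking by degree of
    connectivity.  When ``out_dir`` is given, per-stage artifacts
    (TSV/JSON/GraphML) are written alongside ``report.json``.
    """
    t_all = time.perf_counter()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed)
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        timings[name] = time.perf_counter() - t0
        logger.info("stage %-12s %.2fs", name, timings[name])
        return result

    try:
        genotypes = _stage("genotypes", lambda: _materialize_genotypes(config, seeds))
        phenotype = _stage("phenotype", lambda: _materialize_phenotype(config, genotypes, seeds))
        annotation = _stage("annotation", lambda: _materialize_annotation(config, genotypes, seeds))
        corpus = _stage("gene_sets", lambda: _materialize_corpus(config, annotation, seeds))
    except QtlConvergeError as exc:
        raise QtlConvergeError(f"input stage failed: {exc}") from exc

    curve = _stage("scan", lambda: single_scan(genotypes, phenotype))
    thresholds = _stage(
        "thresholds",
        lambda: permutation_thresholds(
            genotypes,
            phenotype,
            n_perm=config.scan["n_perm"],
            seed=seeds["permutations"],
            significant_percentile=config.scan["significant_percentile"],
            suggestive_percentile=config.scan["suggestive_percentile"],
        ),
    )
    cutoff = (
        thresholds.suggestive
        if config.scan["peak_policy"] == "suggestive"
        else thresholds.significant
    )

    peaks = []
    intervals = []
    for chrom in genotypes.markers.chromosomes:
        sub = curve.table[curve.table["chrom"] == chrom]
        if sub.empty:
            continue
        peak_marker = curve.peak_marker(chrom)
        peak_lod = curve.lod_of(peak_marker)
        if peak_lod <= cutoff:
            continue
        crossed = "significant" if peak_lod > thresholds.significant else "suggestive"
        row = sub[sub["marker"] == peak_marker].iloc[0]
        peaks.append(
            {
                "chrom": str(chrom),
                "marker": peak_marker,
                "pos_bp": int(row["pos_bp"]),
                "lod": float(peak_lod),
                "sign": int(row["sign"]),
                "crossed": crossed,
            }
        )
        intervals.append(support_interval(curve, peak_marker, drop=config.scan["drop"]))

    candidate_rows = []
    candidate_ids: list[str] = []
    for i, interval in enumerate(intervals):
        hit = genes_in_interval(
            annotation,
            interval,
            biotypes=config.candidates["biotypes"],
            containment=config.candidates["containment"],
        )
        by_id = {g.gene_id: g for g in annotation}
        for gid in hit.gene_ids:
            gene = by_id[gid]
            candidate_rows.append(
                {
                    "gene": gid,
                    "chrom": gene.chrom,
                    "start": gene.start,
                    "end": gene.end,
                    "biotype": gene.biotype,
                    "interval_index": i,
                    "interval_chrom": interval.chrom,
                }
            )
            candidate_ids.append(gid)
    candidate_ids = list(dict.fromkeys(candidate_ids))
    candidate_counts = [
        {
            "interval_index": i,
            "chrom": iv.chrom,
            "n_candidates": sum(1 for r in candidate_rows if r["interval_index"] == i),
        }
        for i, iv in enumerate(intervals)
    ]

    model_dict = None
    if peaks:
        model = _stage(
            "model",
            lambda: fit_multi_qtl(genotypes, phenotype, loci=[p["marker"] for p in peaks]),
        )
        model_dict = {
            "loci": list(model.loci),
            "term_percents": {name: pct for name, pct in model.term_percents},
            "total_percent": model.total_percent,
            "residual_df": model.residual_df,
            "n": model.n,
        }

    pair_dict = None
    if config.scan["pair_scan"]:
        pair = _stage(
            "pair_scan",
            lambda: pair_scan(
                genotypes,
                phenotype,
                min_separation=config.scan["pair_min_separation"],
                n_perm=config.scan["pair_scan_n_perm"],
                seed=seeds["permutations"] + 1,
            ),
        )
        pair_dict = {
            "marker_a": pair.marker_a,
            "marker_b": pair.marker_b,
            "interaction_lod": pair.interaction_lod,
            "full_model_lod": pair.full_model_lod,
            "p_value": pair.p_value,
            "n_perm": pair.n_perm,
        }

    graph = _stage(
        "convergence",
        lambda: bootstrap_hisim(
            corpus,
            fraction=config.convergence["fraction"],
            iterations=config.convergence["iterations"],
            retention=config.convergence["retention"],
            seed=seeds["bootstrap"],
            resample_mode=config.convergence["resample_mode"],
        ),
    )
    graph.annotate_candidates(candidate_ids)

    ranking_rows = []
    if candidate_ids:
        ranking = _stage("ranking", lambda: rank_candidates(corpus, candidate_ids, graph))
        ranking_rows = [
            {
                "gene": r.gene_id,
                "degree": r.degree,
                "supporting_sets": list(r.supporting_sets),
                "deepest_biclique_sets": r.deepest_biclique_sets,
            }
            for r in ranking
        ]

    report = PipelineReport(
        settings=config.echo(),
        sub_seeds=seeds,
        thresholds={
            "significant": thresholds.significant,
            "suggestive": thresholds.suggestive,
            "n_perm": thresholds.n_perm,
        },
        peaks=peaks,
        intervals=[
            {
                "chrom": iv.chrom,
                "peak_marker": iv.peak_marker,
                "peak_lod": iv.peak_lod,
                "left_bp": iv.left_bp,
                "right_bp": iv.right_bp,
                "drop": iv.drop,
            }
            for iv in intervals
        ],
        candidate_counts=candidate_counts,
        model=model_dict,
        pair_scan=pair_dict,
        ranking=ranking_rows,
        stage_seconds=timings,
    )

    if out is not None:
        import pandas as pd

        if "genotypes" in config.synthetic:
            io_formats.write_genotypes(genotypes, out / "genotypes.csv")
        if "phenotype" in config.synthetic:
            io_formats.write_phenotype(phenotype, out / "phenotype.csv")
        if "gene_sets" in config.synthetic:
            io_formats.write_gmt(corpus, out / "gene_sets.gmt")
        io_formats.write_scan(curve, out / "scan.tsv")
        io_formats.write_thresholds(thresholds, out / "thresholds.json")
        io_formats.write_intervals(intervals, out / "intervals.json")
        pd.DataFrame(
            candidate_rows,
            columns=["gene", "chrom", "start", "end", "biotype", "interval_index", "interval_chrom"],
        ).to_csv(out / "candidates.tsv", sep="\t", index=False)
        io_formats.write_graph(graph, out / "hisim.graphml", format="graphml")
        pd.DataFrame(
            [
                {
                    "gene": r["gene"],
                    "degree": r["degree"],
                    "supporting_sets": "|".join(r["supporting_sets"]),
                    "deepest_biclique_sets": r["deepest_biclique_sets"],
                }
                for r in ranking_rows
            ],
            columns=["gene", "degree", "supporting_sets", "deepest_biclique_sets"],
        ).to_csv(out / "ranking.tsv", sep="\t", index=False)
        (out / "report.json").write_text(report.to_json())

    logger.info("pipeline finished in %.2fs", time.perf_counter() - t_all)
    return report
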