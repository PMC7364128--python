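"""Reusable simulation studies characterizing the pipeline's behaviour.

Each study regenerates synthetic data under the package's reference
conditions (an RI panel of 200 strains genotyped on a 10-chromosome,
150-marker backbone grid; planted additive loci at 11.38% and 15.60% of trait
variance; a 113-set corpus averaging 66.5 genes per set over a
genome-scale universe) and measures an operating characteristic of the
method: variance-component recovery, genome-wide type-I error of the
permutation threshold, coverage of the 1.5-LOD support interval, or
end-to-end recovery of a planted convergent candidate.
"""
from __future__ import annotations

import numpy as np

from .pipeline import run_pipeline, validate_config
from .scan import fit_multi_qtl, permutation_thresholds, single_scan, support_interval
from .simulate import (
    QtlArchitecture,
    simulate_phenotype,
    simulate_ri_genotypes,
    uniform_marker_map,
)

__all__ = [
    "qtl_recovery_study",
    "type1_error_study",
    "interval_coverage_study",
    "planted_candidate_config",
    "planted_candidate_study",
]

# reference planted variance fractions for the two-locus architecture
LOCUS1_FRACTION = 0.1138
LOCUS2_FRACTION = 0.1560


def _study_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(2 * n) % (2**31)


def qtl_recovery_study(
    n_seeds: int = 100,
    seed: int = 0,
    n_strains: int = 200,
    fractions: tuple[float, float] = (LOCUS1_FRACTION, LOCUS2_FRACTION),
) -> dict:
    """Recovery of two unlinked planted additive loci.

    For each replicate, an RI panel is simulated with loci planted at
    the target variance fractions on chromosomes 1 and 2; the study
    reports the mean drop-one percent-variance estimates from the
    two-locus additive model, the mean total model percent, and the
    fraction of replicates whose genome-wide top two scan peaks are
    exactly the planted markers.
    """
    marker_map = uniform_marker_map()
    m1 = str(marker_map.marker[marker_map.indices_on("1")[7]])
    m2 = str(marker_map.marker[marker_map.indices_on("2")[7]])
    arch = QtlArchitecture(additive=((m1, fractions[0]), (m2, fractions[1])))
    seeds = _study_seeds(seed, n_seeds)

    pct1, pct2, total, top2_hits = [], [], [], 0
    for i in range(n_seeds):
        genotypes = simulate_ri_genotypes(n_strains, marker_map, 0.25, seed=int(seeds[2 * i]))
        phenotype = simulate_phenotype(genotypes, arch, seed=int(seeds[2 * i + 1]))
        model = fit_multi_qtl(genotypes, phenotype, loci=[m1, m2])
        pct1.append(model.percent_of(m1))
        pct2.append(model.percent_of(m2))
        total.append(model.total_percent)
        curve = single_scan(genotypes, phenotype)
        # genome-wide top two peaks = per-chromosome peak markers with the
        # two highest LODs (markers linked to a planted locus are not
        # separate peaks)
        chrom_peaks = [
            (curve.lod_of(curve.peak_marker(c)), curve.peak_marker(c))
            for c in genotypes.markers.chromosomes
        ]
        chrom_peaks.sort(reverse=True)
        if {m1, m2} == {marker for _, marker in chrom_peaks[:2]}:
            top2_hits += 1
    return {
        "mean_percent_locus1": float(np.mean(pct1)),
        "mean_percent_locus2": float(np.mean(pct2)),
        "mean_total_percent": float(np.mean(total)),
        "top2_recovery_rate": top2_hits / n_seeds,
        "n_seeds": n_seeds,
    }


def type1_error_study(
    n_datasets: int = 200,
    n_perm: int = 200,
    seed: int = 0,
    n_strains: int = 100,
) -> dict:
    """Genome-wide false-positive rate of the permutation threshold.

    Each dataset carries a pure-noise trait; the study counts how often
    the observed genome-wide maximum LOD exceeds that dataset's own
    significant (95th-percentile) threshold.  The nominal rate is 0.05.
    """
    marker_map = uniform_marker_map()
    arch = QtlArchitecture()
    seeds = _study_seeds(seed, n_datasets)
    hits = 0
    for i in range(n_datasets):
        genotypes = simulate_ri_genotypes(n_strains, marker_map, 0.25, seed=int(seeds[2 * i]))
        phenotype = simulate_phenotype(genotypes, arch, seed=int(seeds[2 * i + 1]))
        curve = single_scan(genotypes, phenotype)
        thresholds = permutation_thresholds(
            genotypes, phenotype, n_perm=n_perm, seed=int(seeds[2 * i + 1]) + 1
        )
        if curve.max_lod() > thresholds.significant:
            hits += 1
    return {"false_positive_rate": hits / n_datasets, "n_datasets": n_datasets, "n_perm": n_perm}


def interval_coverage_study(
    n_seeds: int = 200,
    seed: int = 0,
    n_strains: int = 100,
    fraction: float = 0.15,
    drop: float = 1.5,
) -> dict:
    """Coverage of the LOD-drop support interval for one planted locus.

    For each replicate the interval is taken around the genome-wide peak
    marker; coverage means the planted marker's position falls inside
    the interval (on the right chromosome).  The 1.5-LOD rule is an
    approximate 95% confidence region.
    """
    marker_map = uniform_marker_map()
    planted = str(marker_map.marker[marker_map.indices_on("1")[7]])
    planted_pos = int(marker_map.pos_bp[marker_map.index_of(planted)])
    arch = QtlArchitecture(additive=((planted, fraction),))
    seeds = _study_seeds(seed, n_seeds)
    covered = 0
    for i in range(n_seeds):
        genotypes = simulate_ri_genotypes(n_strains, marker_map, 0.25, seed=int(seeds[2 * i]))
        phenotype = simulate_phenotype(genotypes, arch, seed=int(seeds[2 * i + 1]))
        curve = single_scan(genotypes, phenotype)
        interval = support_interval(curve, curve.peak_marker(), drop=drop)
        if interval.chrom == "1" and interval.left_bp <= planted_pos <= interval.right_bp:
            covered += 1
    return {"coverage_rate": covered / n_seeds, "n_seeds": n_seeds}


def planted_candidate_config(
    seed: int,
    n_perm: int = 200,
    bootstrap_iterations: int = 25,
    planted_gene: str = "plantedA",
    planted_count: int = 7,
) -> dict:
    """Pipeline configuration with a convergent candidate planted inside
    the first QTL's support interval.

    The planted gene sits at the first planted marker's position on
    chromosome 1, is a member of exactly ``planted_count`` corpus sets,
    and background genes are capped at 4 memberships, so the planted
    gene should emerge as the top-ranked candidate whenever the interval
    stage recovers it.
    """
    # marker grid index 7 on chromosome 1 (see uniform_marker_map spacing)
    spacing = 120_000_000 // 16
    pos = 8 * spacing
    return {
        "seed": seed,
        "synthetic": {
            "genotypes": {},
            "phenotype": {
                "additive": [
                    {"chrom": "1", "index": 7, "variance": LOCUS1_FRACTION},
                    {"chrom": "2", "index": 7, "variance": LOCUS2_FRACTION},
                ]
            },
            "annotation": {
                "extra_genes": [
                    {
                        "id": planted_gene,
                        "chrom": "1",
                        "start": pos - 20_000,
                        "end": pos + 20_000,
                        "biotype": "protein_coding",
                    }
                ]
            },
            "gene_sets": {
                "planted": [{"gene": planted_gene, "count": planted_count}],
                "max_background_membership": 4,
            },
        },
        "scan": {"n_perm": n_perm},
        "convergence": {"iterations": bootstrap_iterations},
    }


def planted_candidate_study(
    n_runs: int = 50,
    seed: int = 0,
    n_perm: int = 200,
    bootstrap_iterations: int = 25,
) -> dict:
    """End-to-end recovery of a planted convergent candidate.

    Runs the full pipeline ``n_runs`` times; success means the planted
    gene is ranked first with degree exactly equal to its planted
    membership count (7).
    """
    seeds = _study_seeds(seed, n_runs)
    successes = 0
    degrees = []
    for i in range(n_runs):
        config = validate_config(
            planted_candidate_config(
                int(seeds[2 * i]), n_perm=n_perm, bootstrap_iterations=bootstrap_iterations
            )
        )
        report = run_pipeline(config)
        if report.ranking:
            top = report.ranking[0]
            degrees.append(top["degree"])
            if top["gene"] == "plantedA" and top["degree"] == 7:
                successes += 1
        else:
            degrees.append(0)
    return {
        "first_rank_rate": successes / n_runs,
        "n_runs": n_runs,
        "top_degrees": degrees,
    }
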