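"""Synthetic-data generators for the full discovery pipeline.

The generators emulate the study design the pipeline is built for: a
two-founder recombinant-inbred (RI) panel phenotyped for a quantitative
trait with a small number of planted loci, a genome annotation supplying
positional candidates, and a curated corpus of functional-genomics gene
sets in which one positional candidate carries a planted convergent
signal (membership in a specified number of sets).

Genotype model
--------------
Per strain and chromosome, the first marker allele is a fair coin and each
subsequent marker flips with probability ``recomb_fraction`` (a first-order
Markov chain along the marker order).  ``recomb_fraction`` is interpreted
directly as the observed strain-level recombination fraction between
adjacent markers; RI map expansion is deliberately not modelled because
downstream stages only need realistic marker correlation.

Trait model
-----------
``trait = sum_i a_i g_i + b * (g1 - mean)(g2 - mean) + eps`` with the
coefficients solved from the realized genotype variances so that each
term's expected variance fraction equals its target, ``a_i > 0`` so the
``1`` (D-type) allele is the increaser, and ``eps`` standard normal scaled
to fill the remaining variance.  The epistatic term uses the product of
mean-centered codes, which is orthogonal to the main effects in
expectation.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneAnnotation
from .containers import GenotypeMatrix, MarkerMap, PhenotypeVector
from .errors import CorpusError, SimulationError
from .genesets import GeneSet, GeneSetCorpus

__all__ = [
    "QtlArchitecture",
    "GeneSetCorpusSpec",
    "uniform_marker_map",
    "simulate_ri_genotypes",
    "simulate_phenotype",
    "generate_gene_annotation",
    "generate_geneset_corpus",
]


@dataclass(frozen=True)
class QtlArchitecture:
    """Planted genetic architecture of a simulated trait.

    ``additive`` maps marker id -> target variance fraction in [0, 1).
    ``epistatic`` optionally names a marker pair and the target variance
    fraction of their interaction.  Fractions must sum to < 1; the
    remainder is filled with iid Gaussian noise.
    """

    additive: tuple[tuple[str, float], ...] = ()
    epistatic: tuple[str, str, float] | None = None

    def __post_init__(self):
        fractions = [f for _, f in self.additive]
        if self.epistatic is not None:
            fractions.append(self.epistatic[2])
        if any(f < 0 or f >= 1 for f in fractions):
            raise SimulationError("variance fractions must lie in [0, 1)")
        if sum(fractions) >= 1:
            raise SimulationError("variance fractions must sum to < 1")

    def validate_markers(self, markers: MarkerMap) -> None:
        names = [m for m, _ in self.additive]
        if self.epistatic is not None:
            names += [self.epistatic[0], self.epistatic[1]]
        for name in names:
            markers.index_of(name)


@dataclass(frozen=True)
class GeneSetCorpusSpec:
    """Parameters of a synthetic gene-set corpus.

    Defaults mirror the corpus scale the pipeline targets: 113 sets with a
    mean of 66.5 genes per set, drawn from a genome-scale universe.  Each
    planted candidate appears in exactly its specified number of sets;
    background genes enter each set independently with probability
    ``mean_set_size / universe size`` (optionally capped at
    ``max_background_membership`` total memberships per gene).
    """

    n_sets: int = 113
    mean_set_size: float = 66.5
    n_genes: int = 16000
    universe: tuple[str, ...] | None = None
    planted: tuple[tuple[str, int], ...] = ()
    max_background_membership: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_sets < 1:
            raise SimulationError("n_sets must be positive")
        if self.mean_set_size <= 0:
            raise SimulationError("mean_set_size must be positive")
        for gene, count in self.planted:
            if count < 0 or count > self.n_sets:
                raise SimulationError(
                    f"planted membership count for {gene!r} must lie in [0, n_sets]"
                )

    @property
    def gene_universe(self) -> list[str]:
        if self.universe is not None:
            universe = list(self.universe)
        else:
            universe = [f"Gene{i:05d}" for i in range(self.n_genes)]
        known = set(universe)
        for gene, _ in self.planted:
            if gene not in known:
                universe.append(gene)
                known.add(gene)
        return universe


def uniform_marker_map(
    n_chromosomes: int = 10,
    chrom_length_bp: int = 120_000_000,
    markers_per_chromosome: int = 15,
    prefix: str = "rs",
) -> MarkerMap:
    """Evenly spaced marker grid over equally sized chromosomes.

    The default is the package's reference backbone map: 150 markers at
    ~7.5 Mb spacing, the legacy density at which adjacent markers in an
    RI panel are only loosely correlated and a QTL peak identifies one
    marker rather than a linked block.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise SimulationError("need at least one chromosome and one marker")
    marker, chrom, pos = [], [], []
    spacing = chrom_length_bp // (markers_per_chromosome + 1)
    k = 0
    for c in range(1, n_chromosomes + 1):
        for j in range(markers_per_chromosome):
            marker.append(f"{prefix}{k:05d}")
            chrom.append(str(c))
            pos.append((j + 1) * spacing)
            k += 1
    return MarkerMap(marker, chrom, pos)


def simulate_ri_genotypes(
    n_strains: int,
    marker_map: MarkerMap,
    recomb_fraction: float | Sequence[float],
    seed: int,
) -> GenotypeMatrix:
    """Simulate fully inbred RI genotypes along a marker map.

    ``recomb_fraction`` may be a scalar applied to every adjacent marker
    pair, or a sequence with one value per adjacent pair (concatenated
    over chromosomes in map order).
    """
    if n_strains < 1:
        raise SimulationError("n_strains must be positive")
    if len(marker_map) == 0:
        raise SimulationError("marker map must be non-empty")

    n_pairs = sum(
        max(len(marker_map.indices_on(c)) - 1, 0) for c in marker_map.chromosomes
    )
    if np.isscalar(recomb_fraction):
        fractions = np.full(n_pairs, float(recomb_fraction))
    else:
        fractions = np.asarray(recomb_fraction, dtype=float)
        if fractions.shape != (n_pairs,):
            raise SimulationError(
                f"expected {n_pairs} per-pair recombination fractions, got {fractions.shape}"
            )
    if np.any(fractions < 0) or np.any(fractions > 0.5):
        raise SimulationError("recomb_fraction must lie in [0, 0.5]")

    rng = np.random.default_rng(seed)
    calls = np.empty((n_strains, len(marker_map)))
    offset = 0
    for c in marker_map.chromosomes:
        idx = marker_map.indices_on(c)
        first = rng.integers(0, 2, size=n_strains).astype(float)
        calls[:, idx[0]] = first
        current = first
        for j in range(1, len(idx)):
            flip = rng.random(n_strains) < fractions[offset + j - 1]
            current = np.where(flip, 1.0 - current, current)
            calls[:, idx[j]] = current
        offset += max(len(idx) - 1, 0)
    strains = [f"RIS{i + 1:03d}" for i in range(n_strains)]
    return GenotypeMatrix(strains, marker_map, calls)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    architecture: QtlArchitecture,
    seed: int,
) -> PhenotypeVector:
    """Simulate a quantitative trait with planted additive/epistatic loci."""
    architecture.validate_markers(genotypes.markers)
    rng = np.random.default_rng(seed)
    n = genotypes.n_strains
    total_fraction = 0.0
    trait = np.zeros(n)

    for marker_id, fraction in architecture.additive:
        g = genotypes.column(marker_id)
        if np.isnan(g).any():
            raise SimulationError("planted markers must have complete genotype calls")
        var_g = g.var()
        if fraction > 0 and var_g == 0:
            raise SimulationError(
                f"marker {marker_id!r} is monomorphic; cannot plant variance on it"
            )
        if fraction > 0:
            trait += np.sqrt(fraction / var_g) * (g - g.mean())
        total_fraction += fraction

    if architecture.epistatic is not None:
        ma, mb, fraction = architecture.epistatic
        ga = genotypes.column(ma)
        gb = genotypes.column(mb)
        z = (ga - ga.mean()) * (gb - gb.mean())
        var_z = z.var()
        if fraction > 0 and var_z == 0:
            raise SimulationError("interaction coding is constant; cannot plant epistasis")
        if fraction > 0:
            trait += np.sqrt(fraction / var_z) * (z - z.mean())
        total_fraction += fraction

    noise_sd = np.sqrt(1.0 - total_fraction)
    trait = trait + noise_sd * rng.standard_normal(n)
    import pandas as pd

    return PhenotypeVector(pd.Series(trait, index=genotypes.strains))


def generate_gene_annotation(
    chrom_lengths: Mapping[str, int],
    n_genes: int,
    biotype_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    min_length: int = 2_000,
    max_length: int = 60_000,
) -> list[GeneAnnotation]:
    """Place non-overlapping-agnostic gene intervals uniformly on a genome.

    Genes are placed independently (overlaps permitted, as in real
    annotations); chromosomes are chosen proportionally to their length
    and biotypes by the stated mix.  Coordinates are 1-based inclusive.
    """
    if not chrom_lengths:
        raise SimulationError("chrom_lengths must name at least one chromosome")
    if n_genes < 0:
        raise SimulationError("n_genes must be non-negative")
    if biotype_mix is None:
        biotype_mix = {"protein_coding": 0.8, "lncRNA": 0.1, "pseudogene": 0.1}
    if not biotype_mix:
        raise SimulationError("biotype mix must be non-empty")
    props = np.array(list(biotype_mix.values()), dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise SimulationError("biotype proportions must sum to 1")

    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())
    gene_len = rng.integers(min_length, max_length + 1, size=n_genes)
    biotypes = rng.choice(list(biotype_mix), size=n_genes, p=props)

    genes = []
    for i in range(n_genes):
        c = chroms[chrom_idx[i]]
        span = int(min(gene_len[i], chrom_lengths[c] - 1))
        start = int(rng.integers(1, chrom_lengths[c] - span + 1))
        gid = f"Gene{i:05d}"
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                symbol=gid,
                chrom=c,
                start=start,
                end=start + span,
                biotype=str(biotypes[i]),
            )
        )
    genes.sort(key=lambda g: (chroms.index(g.chrom), g.start, g.gene_id))
    return genes


def generate_geneset_corpus(spec: GeneSetCorpusSpec) -> GeneSetCorpus:
    """Generate a gene-set corpus with planted convergent candidates.

    Every planted gene is a member of exactly its specified number of
    sets; background genes enter sets under an independent-inclusion
    model calibrated so the expected set size matches ``mean_set_size``.
    """
    rng = np.random.default_rng(spec.seed)
    universe = spec.gene_universe
    planted_map = dict(spec.planted)
    if len(planted_map) != len(spec.planted):
        raise SimulationError("duplicate planted gene id")

    background = [g for g in universe if g not in planted_map]
    p_inclusion = min(spec.mean_set_size / max(len(universe), 1), 1.0)

    members: list[list[str]] = [[] for _ in range(spec.n_sets)]
    counts = rng.binomial(spec.n_sets, p_inclusion, size=len(background))
    if spec.max_background_membership is not None:
        counts = np.minimum(counts, spec.max_background_membership)
    for gene, k in zip(background, counts):
        if k == 0:
            continue
        for j in rng.choice(spec.n_sets, size=int(k), replace=False):
            members[j].append(gene)
    for gene, k in planted_map.items():
        if k == 0:
            continue
        for j in rng.choice(spec.n_sets, size=int(k), replace=False):
            members[j].append(gene)

    sets = []
    for j, genes in enumerate(members):
        if not genes:
            raise CorpusError(
                f"generated gene set {j} is empty; raise mean_set_size or the "
                "inclusion probability"
            )
        sets.append(
            GeneSet(
                set_id=f"GS{j:03d}",
                description="synthetic gene set",
                genes=tuple(sorted(genes)),
            )
        )
    return GeneSetCorpus(sets)
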