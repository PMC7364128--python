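"""Readers and writers shared across pipeline stages.

Genotype CSV dialect (GeneNetwork-style): a header row of marker ids, a
``chromosome`` row, a ``position_bp`` row, then one row per strain with
cells in ``{B, D, NA}`` (configurable).  Gene sets travel as GMT
(tab-separated: set id, description, gene ids...).  Graphs are written
as GraphML (round-trippable) or DOT (write-only).
"""
from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerMap, PhenotypeVector
from .convergence import HiSimGraph
from .errors import CorpusError, FormatError
from .genesets import GeneSet, GeneSetCorpus
from .scan import LodCurve, ScanThresholds, SupportInterval

logger = logging.getLogger("qtlconverge")

__all__ = [
    "TableDialect",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_gmt",
    "write_gmt",
    "write_graph",
    "read_graphml",
    "write_scan",
    "read_scan",
    "write_thresholds",
    "read_thresholds",
    "write_intervals",
    "read_intervals",
]


@dataclass(frozen=True)
class TableDialect:
    """Tokens and separators of the genotype CSV dialect."""

    delimiter: str = ","
    comment_prefix: str = "#"
    missing_tokens: tuple[str, ...] = ("NA", "")
    allele_tokens: tuple[str, str] = ("B", "D")
    allow_het_skip: bool = False  # soft-skip unknown tokens as missing

    def __post_init__(self):
        if set(self.missing_tokens) & set(self.allele_tokens):
            raise FormatError("missing and allele tokens must be disjoint")


# ---------------------------------------------------------------------------
# genotypes / phenotype

_CHROM_ROW = "chromosome"
_POS_ROW = "position_bp"


def read_genotypes(path, dialect: TableDialect = TableDialect()) -> GenotypeMatrix:
    """Read a strain x marker genotype matrix with its marker map."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        for raw in csv.reader(fh, delimiter=dialect.delimiter):
            if raw and raw[0].startswith(dialect.comment_prefix):
                continue
            rows.append(raw)
    if len(rows) < 3:
        raise FormatError(f"{path.name}: need header, chromosome and position rows")
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    markers = header[1:]
    if chrom_row[0] != _CHROM_ROW or pos_row[0] != _POS_ROW:
        raise FormatError(
            f"{path.name}: rows 2-3 must be labelled {_CHROM_ROW!r} and {_POS_ROW!r}"
        )
    try:
        positions = [int(p) for p in pos_row[1:]]
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-integer marker position") from exc
    marker_map = MarkerMap(markers, chrom_row[1:], positions)

    b_tok, d_tok = dialect.allele_tokens
    strains = []
    calls = []
    for lineno, row in enumerate(rows[3:], start=4):
        if not row or not row[0].strip():
            continue
        strain = row[0]
        if strain in strains:
            raise FormatError(f"{path.name}:{lineno}: duplicate strain id {strain!r}")
        if len(row) != len(markers) + 1:
            raise FormatError(
                f"{path.name}:{lineno}: expected {len(markers)} genotype cells"
            )
        values = []
        for col, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell == b_tok:
                values.append(0.0)
            elif cell == d_tok:
                values.append(1.0)
            elif cell in dialect.missing_tokens:
                values.append(np.nan)
            elif dialect.allow_het_skip:
                logger.warning(
                    "%s:%d col %d: token %r treated as missing", path.name, lineno, col, cell
                )
                values.append(np.nan)
            else:
                raise FormatError(
                    f"{path.name}:{lineno} col {col}: unknown allele token {cell!r} "
                    "(RI panels carry no heterozygotes)"
                )
        strains.append(strain)
        calls.append(values)
    return GenotypeMatrix(strains, marker_map, np.array(calls, dtype=float))


def write_genotypes(genotypes: GenotypeMatrix, path, dialect: TableDialect = TableDialect()) -> None:
    path = Path(path)
    mm = genotypes.markers
    b_tok, d_tok = dialect.allele_tokens
    missing = dialect.missing_tokens[0] or "NA"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        w.writerow(["id", *mm.marker])
        w.writerow([_CHROM_ROW, *mm.chrom])
        w.writerow([_POS_ROW, *mm.pos_bp])
        for i, strain in enumerate(genotypes.strains):
            cells = []
            for v in genotypes.calls[i]:
                if np.isnan(v):
                    cells.append(missing)
                else:
                    cells.append(d_tok if v == 1.0 else b_tok)
            w.writerow([strain, *cells])


def read_phenotype(path, value_column: str = "value") -> PhenotypeVector:
    """Read a strain phenotype table (CSV: strain, value, covariates...)."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{Path(path).name}: need strain and value columns")
    strain_col = df.columns[0]
    if value_column not in df.columns:
        value_column = df.columns[1]
    series = pd.Series(df[value_column].to_numpy(float), index=df[strain_col])
    covars = None
    extra = [c for c in df.columns if c not in (strain_col, value_column)]
    if extra:
        covars = df.set_index(strain_col)[extra]
    return PhenotypeVector(series, covariates=covars)


def write_phenotype(phenotype: PhenotypeVector, path) -> None:
    df = pd.DataFrame({"strain": phenotype.strains, "value": phenotype.series.to_numpy()})
    if phenotype.covariates is not None:
        for c in phenotype.covariates.columns:
            df[c] = phenotype.covariates[c].to_numpy()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCorpus:
    """Read a GMT gene-set file (set id, description, gene ids...)."""
    path = Path(path)
    sets = []
    seen_ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                logger.info("%s:%d: skipped blank line", path.name, lineno)
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT lines need set id, description and "
                    "at least one gene"
                )
            set_id, description = fields[0], fields[1]
            if set_id in seen_ids:
                raise FormatError(f"{path.name}:{lineno}: duplicate set id {set_id!r}")
            seen_ids.add(set_id)
            genes = [g for g in fields[2:] if g.strip()]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                warnings.warn(
                    f"{path.name}:{lineno}: duplicate genes in set {set_id!r} removed",
                    stacklevel=2,
                )
            if not deduped:
                raise FormatError(f"{path.name}:{lineno}: set {set_id!r} has no genes")
            sets.append(GeneSet(set_id=set_id, description=description, genes=tuple(deduped)))
    return GeneSetCorpus(sets)


def write_gmt(corpus: GeneSetCorpus, path) -> None:
    with open(path, "w") as fh:
        for s in corpus:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# graphs


def _stringify_graph(graph: HiSimGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in sorted(graph.graph.nodes):
        d = graph.graph.nodes[node]
        g.add_node(
            node,
            kind=d["kind"],
            set_ids="|".join(d["set_ids"]),
            gene_ids="|".join(d["gene_ids"]),
            gene_count=len(d["gene_ids"]),
            contains_candidate=bool(d.get("contains_candidate", False)),
            candidate_ids="|".join(d.get("candidate_ids", ())),
        )
    for u, v, d in sorted(graph.graph.edges(data=True)):
        g.add_edge(u, v, support=float(d.get("support", 1.0)))
    return g


def write_graph(graph: HiSimGraph, path, format: str = "graphml") -> None:
    """Serialize a HiSim graph with all node/edge attributes."""
    path = Path(path)
    fmt = format.lower()
    g = _stringify_graph(graph)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph hisim {\n")
            for node, d in g.nodes(data=True):
                shape = "box" if d["kind"] == "terminal" else "ellipse"
                color = "pink" if d["contains_candidate"] else "white"
                label = d["set_ids"].replace("|", "\\n")
                fh.write(
                    f'  "{node}" [shape={shape}, style=filled, fillcolor="{color}", '
                    f'label="{label}\\n{d["gene_count"]} genes"];\n'
                )
            for u, v, d in g.edges(data=True):
                fh.write(f'  "{u}" -> "{v}" [label="{d["support"]:.2f}"];\n')
            fh.write("}\n")
    else:
        raise FormatError(f"unknown graph format {format!r}")


def read_graphml(path) -> HiSimGraph:
    """Read a HiSim graph written by :func:`write_graph` (GraphML)."""
    raw = nx.read_graphml(Path(path))
    g = nx.DiGraph()
    for node, d in raw.nodes(data=True):
        g.add_node(
            node,
            kind=d["kind"],
            set_ids=tuple(d["set_ids"].split("|")) if d["set_ids"] else (),
            gene_ids=tuple(d["gene_ids"].split("|")) if d["gene_ids"] else (),
            contains_candidate=bool(d.get("contains_candidate", False)),
            candidate_ids=tuple(d["candidate_ids"].split("|")) if d.get("candidate_ids") else (),
        )
    for u, v, d in raw.edges(data=True):
        g.add_edge(u, v, support=float(d.get("support", 1.0)))
    return HiSimGraph(g)


# ---------------------------------------------------------------------------
# scan artifacts


def write_scan(curve: LodCurve, path) -> None:
    curve.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(path) -> LodCurve:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    return LodCurve(table=df)


def write_thresholds(thresholds: ScanThresholds, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "significant": thresholds.significant,
                "suggestive": thresholds.suggestive,
                "n_perm": thresholds.n_perm,
                "seed": thresholds.seed,
                "significant_percentile": thresholds.significant_percentile,
                "suggestive_percentile": thresholds.suggestive_percentile,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_thresholds(path) -> ScanThresholds:
    with open(path) as fh:
        return ScanThresholds(**json.load(fh))


def write_intervals(intervals, path) -> None:
    payload = [
        {
            "chrom": iv.chrom,
            "peak_marker": iv.peak_marker,
            "peak_lod": iv.peak_lod,
            "left_bp": iv.left_bp,
            "right_bp": iv.right_bp,
            "drop": iv.drop,
        }
        for iv in intervals
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_intervals(path) -> list[SupportInterval]:
    with open(path) as fh:
        return [SupportInterval(**d) for d in json.load(fh)]
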