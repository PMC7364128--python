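"""Gene annotations and positional-candidate extraction.

Internal coordinates are 1-based inclusive (the GFF3 convention); the BED
reader/writer converts from/to BED's 0-based half-open convention at the
parser boundary.
"""
from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

from .errors import FormatError, QtlConvergeError
from .scan import SupportInterval

__all__ = [
    "GeneAnnotation",
    "CandidateList",
    "genes_in_interval",
    "read_gene_annotation",
    "write_gene_annotation",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: 1-based inclusive interval plus biotype."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    biotype: str = "unknown"

    def __post_init__(self):
        if self.start > self.end:
            raise QtlConvergeError(
                f"gene {self.gene_id!r}: start {self.start} exceeds end {self.end}"
            )
        if self.start < 1:
            raise QtlConvergeError(f"gene {self.gene_id!r}: coordinates are 1-based")


@dataclass(frozen=True)
class CandidateList:
    """Positional candidates extracted from one support interval."""

    interval: SupportInterval
    gene_ids: tuple[str, ...]
    biotypes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.gene_ids)


def genes_in_interval(
    annotation: Sequence[GeneAnnotation],
    interval: SupportInterval,
    biotypes: Iterable[str] | None = ("protein_coding",),
    containment: bool = False,
) -> CandidateList:
    """Genes overlapping a support interval, ordered by start position.

    The default rule is any-overlap (>= 1 bp shared with the interval);
    ``containment=True`` requires the gene to lie entirely inside it.
    ``biotypes=None`` disables the biotype filter (default keeps
    protein-coding genes only).  An empty result is valid.
    """
    allowed = None if biotypes is None else set(biotypes)
    hits = []
    for gene in annotation:
        if gene.chrom != interval.chrom:
            continue
        if allowed is not None and gene.biotype not in allowed:
            continue
        if containment:
            inside = gene.start >= interval.left_bp and gene.end <= interval.right_bp
        else:
            inside = gene.start <= interval.right_bp and gene.end >= interval.left_bp
        if inside:
            hits.append(gene)
    hits.sort(key=lambda g: (g.start, g.gene_id))
    seen: dict[str, None] = {}
    for g in hits:
        seen.setdefault(g.gene_id, None)
    return CandidateList(
        interval=interval,
        gene_ids=tuple(seen),
        biotypes=tuple(sorted(allowed)) if allowed is not None else (),
    )


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix == ".bed":
        return "bed"
    raise FormatError(f"cannot infer annotation format from {path.name!r}")


def read_gene_annotation(path, format: str | None = None) -> list[GeneAnnotation]:
    """Read gene records from a GFF3 or BED file.

    GFF3: features of type ``gene`` are kept; the biotype is taken from
    the ``gene_biotype`` (or ``biotype``) attribute and the name from
    ``Name``/``gene_name`` falling back to ``ID``.  BED: 0-based
    half-open coordinates are converted to 1-based inclusive, with the
    biotype read from an optional fifth column (else ``"unknown"``).
    """
    path = Path(path)
    fmt = (format or _detect_format(path)).lower()
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed":
        return _read_bed(path)
    raise FormatError(f"unknown annotation format {format!r}")


def _read_gff3(path: Path) -> list[GeneAnnotation]:
    text = path.read_text()
    # validate column counts up front so errors carry line numbers
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise FormatError(f"{path.name}:{lineno}: expected 9 tab-separated GFF3 columns")
    if not text.strip():
        return []
    import gffutils

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        attrs = feat.attributes
        biotype = (attrs.get("gene_biotype") or attrs.get("biotype") or ["unknown"])[0]
        name = (attrs.get("Name") or attrs.get("gene_name") or [feat.id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=feat.id,
                symbol=name,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                biotype=biotype,
            )
        )
    return genes


def _read_bed(path: Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path.name}:{lineno}: BED needs at least chrom/start/end/name"
                )
            try:
                start0 = int(fields[1])
                end0 = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-integer coordinate") from exc
            biotype = fields[4] if len(fields) > 4 and fields[4] not in (".", "") else "unknown"
            genes.append(
                GeneAnnotation(
                    gene_id=fields[3],
                    symbol=fields[3],
                    chrom=fields[0],
                    start=start0 + 1,  # 0-based half-open -> 1-based inclusive
                    end=end0,
                    biotype=biotype,
                )
            )
    return genes


def write_gene_annotation(
    annotation: Sequence[GeneAnnotation], path, format: str | None = None
) -> None:
    """Write gene records as BED (with biotype column) or GFF3."""
    path = Path(path)
    fmt = (format or _detect_format(path)).lower()
    with open(path, "w") as fh:
        if fmt == "bed":
            for g in annotation:
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t{g.biotype}\n")
        elif fmt == "gff3":
            fh.write("##gff-version 3\n")
            for g in annotation:
                attrs = f"ID={g.gene_id};Name={g.symbol};gene_biotype={g.biotype}"
                fh.write(
                    f"{g.chrom}\tqtlconverge\tgene\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}\n"
                )
        else:
            raise FormatError(f"unknown annotation format {format!r}")
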