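"""Core data containers for recombinant-inbred (RI) panel data.

An RI panel descends from a cross of two inbred founders; every strain is
homozygous at every locus, so genotypes are coded ``0`` (B-type founder
allele) and ``1`` (D-type founder allele) with ``NaN`` for missing calls.
"""
from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import QtlConvergeError

__all__ = ["MarkerMap", "GenotypeMatrix", "PhenotypeVector"]


class MarkerMap:
    """Ordered collection of genetic markers with genomic coordinates.

    Parameters
    ----------
    marker
        Unique marker identifiers.
    chrom
        Chromosome label per marker.  Chromosome order follows first
        appearance in the input.
    pos_bp
        Base-pair position per marker; non-negative and strictly
        increasing within each chromosome.
    cm
        Optional genetic-map position in centimorgans.
    """

    def __init__(
        self,
        marker: Sequence[str],
        chrom: Sequence[str],
        pos_bp: Sequence[int],
        cm: Sequence[float] | None = None,
    ):
        self.marker = np.asarray(marker, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos_bp = np.asarray(pos_bp, dtype=np.int64)
        self.cm = None if cm is None else np.asarray(cm, dtype=float)
        if not (len(self.marker) == len(self.chrom) == len(self.pos_bp)):
            raise QtlConvergeError("marker, chrom and pos_bp must have equal length")
        if self.cm is not None and len(self.cm) != len(self.marker):
            raise QtlConvergeError("cm must match the number of markers")
        if len(set(self.marker)) != len(self.marker):
            raise QtlConvergeError("marker ids must be unique")
        if np.any(self.pos_bp < 0):
            raise QtlConvergeError("marker positions must be non-negative")
        # strictly increasing positions within each chromosome
        for c in self.chromosomes:
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise QtlConvergeError(
                    f"positions on chromosome {c!r} must be strictly increasing"
                )
        self._index = {m: i for i, m in enumerate(self.marker)}

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def indices_on(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chromosome)

    def to_frame(self) -> pd.DataFrame:
        data = {"marker": self.marker, "chrom": self.chrom, "pos_bp": self.pos_bp}
        if self.cm is not None:
            data["cm"] = self.cm
        return pd.DataFrame(data)

    def __len__(self) -> int:
        return len(self.marker)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        same_cm = (
            (self.cm is None and other.cm is None)
            or (self.cm is not None and other.cm is not None and np.allclose(self.cm, other.cm))
        )
        return (
            list(self.marker) == list(other.marker)
            and list(self.chrom) == list(other.chrom)
            and list(self.pos_bp) == list(other.pos_bp)
            and same_cm
        )

    def __repr__(self) -> str:
        return f"MarkerMap({len(self)} markers, {len(self.chromosomes)} chromosomes)"


class GenotypeMatrix:
    """Strain-by-marker genotype calls for a fully inbred RI panel.

    Calls are stored as a float array with values in ``{0.0, 1.0, NaN}``;
    heterozygous codes are rejected because RI strains are inbred.
    """

    def __init__(self, strains: Sequence[str], markers: MarkerMap, calls: np.ndarray):
        self.strains = list(strains)
        self.markers = markers
        self.calls = np.asarray(calls, dtype=float)
        if len(set(self.strains)) != len(self.strains):
            raise QtlConvergeError("strain ids must be unique")
        if self.calls.shape != (len(self.strains), len(markers)):
            raise QtlConvergeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strains)} strains x {len(markers)} markers"
            )
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise QtlConvergeError("genotype calls must be 0, 1 or missing (no heterozygotes)")
        self._strain_index = {s: i for i, s in enumerate(self.strains)}

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.markers.index_of(marker_id)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.strains == other.strains
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_strains} strains x {self.n_markers} markers)"


class PhenotypeVector:
    """One trait value per strain, with optional per-strain covariates."""

    def __init__(self, values: pd.Series | dict, covariates: pd.DataFrame | None = None):
        series = pd.Series(values, dtype=float)
        series.index = series.index.astype(str)
        if series.index.duplicated().any():
            raise QtlConvergeError("duplicate strain ids in phenotype")
        if not np.isfinite(series.dropna()).all():
            raise QtlConvergeError("phenotype values must be finite")
        self.series = series
        self.covariates = covariates
        if covariates is not None and not covariates.index.equals(series.index):
            raise QtlConvergeError("covariate rows must match phenotype strains")

    @property
    def strains(self) -> list[str]:
        return list(self.series.index)

    def __len__(self) -> int:
        return len(self.series)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhenotypeVector):
            return NotImplemented
        return self.series.equals(other.series)

    def __repr__(self) -> str:
        return f"PhenotypeVector({len(self)} strains)"


def align(genotypes: GenotypeMatrix, phenotype: PhenotypeVector):
    """Shared strains, in genotype order, with non-missing phenotype.

    Returns ``(strain_ids, G, y)`` where ``G`` is the genotype sub-matrix
    and ``y`` the matching phenotype values.
    """
    phen = phenotype.series.dropna()
    keep = [i for i, s in enumerate(genotypes.strains) if s in phen.index]
    strains = [genotypes.strains[i] for i in keep]
    G = genotypes.calls[keep, :]
    y = phen.loc[strains].to_numpy()
    return strains, G, y
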