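"""Gene-set containers for the convergence analysis.

A gene set is one experiment's (or annotation's) named list of genes; a
corpus is an ordered collection of such sets sharing one gene namespace.
"""
from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .errors import CorpusError

__all__ = ["GeneSet", "GeneSetCorpus"]


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty, duplicate-free collection of gene ids."""

    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise CorpusError(f"gene set {self.set_id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise CorpusError(f"gene set {self.set_id!r} contains duplicate gene ids")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCorpus:
    """Ordered collection of gene sets with a derived gene universe."""

    def __init__(self, sets: Sequence[GeneSet]):
        self.sets = list(sets)
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise CorpusError("duplicate set ids in corpus")
        self._by_id = {s.set_id: s for s in self.sets}

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    @property
    def universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sets:
            for g in s.genes:
                seen.setdefault(g, None)
        return sorted(seen)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def membership(self, gene: str) -> list[str]:
        """Ids of the corpus sets containing ``gene``."""
        return [s.set_id for s in self.sets if gene in set(s.genes)]

    def subset(self, set_ids: Iterable[str]) -> "GeneSetCorpus":
        """Sub-corpus restricted to ``set_ids`` (original order kept)."""
        wanted = set(set_ids)
        return GeneSetCorpus([s for s in self.sets if s.set_id in wanted])

    def mean_set_size(self) -> float:
        return sum(len(s) for s in self.sets) / len(self.sets)

    def __repr__(self) -> str:
        return f"GeneSetCorpus({len(self)} sets, {len(self.universe)} genes)"
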