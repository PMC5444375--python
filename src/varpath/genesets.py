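"""Gene-set collections (GMT) and their per-level count decomposition.

Gene identifiers are matched to the expression matrix by exact string
comparison after whitespace trimming; users must harmonize identifier
namespaces (symbols vs. Entrez vs. Ensembl) upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .discretize import CategoryScheme
from .errors import ValidationError

__all__ = [
    "GeneSetCollection",
    "PathwayCounts",
    "ReferenceCounts",
    "read_gmt",
    "write_gmt",
    "decompose",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, e.g. KEGG or REACTOME pathways."""

    sets: dict[str, tuple[str, list[str]]]
    source: str = "custom"

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class PathwayCounts:
    """Observed per-level gene counts O_1..O_m for one pathway and group."""

    set_name: str
    group: str
    counts: np.ndarray  # length m, integers
    genes_per_level: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ReferenceCounts:
    """Per-level counts over all measured, assigned genes; the null
    composition for the one-group test."""

    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def read_gmt(path: str) -> GeneSetCollection:
    """Read Broad-dialect GMT: name TAB description TAB gene TAB gene...

    Duplicate genes within a set are collapsed (order preserved); empty
    sets are dropped with a warning; a line with fewer than three fields
    is a hard error naming the line number.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    "need name, description and >= 1 gene"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g.strip() for g in fields[2:] if g.strip()))
            if not genes:
                warnings.warn(f"{path}:{lineno}: set {name!r} is empty, dropped")
                continue
            sets[name] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def decompose(
    collection: GeneSetCollection,
    scheme: CategoryScheme,
    group: str = "all",
    min_size: int = 10,
) -> tuple[list[PathwayCounts], ReferenceCounts, list[str]]:
    """Decompose each pathway into per-level gene counts for one group.

    Counts are taken over the intersection of each set with the measured,
    level-assigned genes; sets whose intersection has fewer than
    ``min_size`` genes are excluded and their names returned. The
    reference counts cover ALL assigned genes, pathway-annotated or not
    (no leave-one-out correction).
    """
    if group not in scheme.assignments:
        raise ValidationError(
            f"scheme has no assignments for group {group!r}; "
            f"available: {sorted(scheme.assignments)}"
        )
    assign = scheme.assignments[group]
    m = scheme.m

    ref = np.zeros(m, dtype=int)
    for lv in assign.values():
        ref[lv - 1] += 1

    results: list[PathwayCounts] = []
    dropped: list[str] = []
    for name, (_, genes) in collection.sets.items():
        measured = [g for g in genes if g in assign]
        if len(measured) < min_size:
            dropped.append(name)
            continue
        counts = np.zeros(m, dtype=int)
        per_level: dict[int, list[str]] = {i: [] for i in range(1, m + 1)}
        for g in measured:
            lv = assign[g]
            counts[lv - 1] += 1
            per_level[lv].append(g)
        results.append(
            PathwayCounts(
                set_name=name, group=group, counts=counts, genes_per_level=per_level
            )
        )
    if not results and collection.sets:
        raise ValidationError(
            f"no gene set has >= {min_size} measured genes in group {group!r}; "
            "check that gene identifiers match the expression matrix"
        )
    return results, ReferenceCounts(counts=ref), dropped
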