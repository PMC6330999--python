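"""Per-pair features feeding the fuzzy variables, plus a synteny diagnostic.

Three features are computed for every candidate pair:

* **local synteny score** -- the mean, over the two genes, of the proportion
  of each gene's neighbor window whose members have a homoeolog partner in
  the other gene's window.  Local windows (default 10 genes) make the score
  robust to chromosome-scale rearrangements and to draft assemblies, where
  whole-chromosome (global) synteny breaks down.
* **evolutionary distance** -- passed through from the pair table, in PAM
  units; never computed here.
* **total copy number** -- the number of homoeolog partners of gene1 plus
  that of gene2; 2 for a strict one-to-one pair.  High values flag
  suspiciously duplicated families (e.g. transposable elements annotated as
  genes).

The chromosome-pair count matrix is a diagnostic: reciprocal translocations
between subgenomes show up as elevated off-diagonal cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from homeoconf.io import (
    GenomeAnnotation,
    HomoeologPair,
    PairTable,
    ValidationError,
)

DEFAULT_WINDOW_SIZE = 10


@dataclass(frozen=True)
class PairFeatures:
    """The three fuzzy inputs for one candidate pair."""

    synteny_score: float
    distance: float
    total_copy_nr: int


@dataclass
class ChromPairMatrix:
    """Counts of pairs per (scaffold-in-subgenome-1, scaffold-in-subgenome-2)."""

    subgenome1: str
    subgenome2: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_rows(self) -> list[tuple[str, str, int]]:
        """Long-format rows (scaffold1, scaffold2, count), sorted."""
        return [(s1, s2, self.counts[(s1, s2)]) for s1, s2 in sorted(self.counts)]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("scaffold1\tscaffold2\tcount\n")
            for s1, s2, n in self.to_rows():
                fh.write(f"{s1}\t{s2}\t{n}\n")


def neighbor_window(
    annotation: GenomeAnnotation,
    gene: str,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[str]:
    """The up-to-``window_size`` genes nearest the focal gene on its scaffold.

    Neighbors are selected by rank distance in the scaffold's gene order,
    preferring the upstream gene on ties; at scaffold edges the window
    borrows from the available side, so a gene at one end of a long scaffold
    still gets ``window_size`` neighbors.  The focal gene is excluded.
    Scaffolds with fewer than ``window_size`` other genes contribute all of
    them; a single-gene scaffold yields an empty window.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    scaffold = annotation.scaffold_of(gene)
    order = annotation.order[scaffold]
    idx = annotation.rank[gene]
    n = len(order)
    picked: list[int] = []
    d = 1
    while len(picked) < window_size and len(picked) < n - 1:
        if idx - d >= 0:
            picked.append(idx - d)
        if len(picked) < window_size and idx + d < n:
            picked.append(idx + d)
        d += 1
    picked.sort()
    return [order[i] for i in picked]


def synteny_score(
    pair: HomoeologPair,
    annotation: GenomeAnnotation,
    table: PairTable,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> float:
    """Windowed local synteny score in [0, 1] for one pair.

    A window gene *matches* when any of its partners in the genome-wide pair
    table lies in the other gene's window.  The score is the mean of the two
    windows' match proportions.  If either gene sits on a scaffold with
    fewer than two genes (itself included) the score is defined as 0: no
    neighborhood, no synteny evidence.
    """
    s1 = annotation.scaffold_of(pair.gene1)
    s2 = annotation.scaffold_of(pair.gene2)
    if len(annotation.order[s1]) < 2 or len(annotation.order[s2]) < 2:
        return 0.0
    w1 = neighbor_window(annotation, pair.gene1, window_size)
    w2 = neighbor_window(annotation, pair.gene2, window_size)
    set1, set2 = set(w1), set(w2)
    empty: set[str] = set()
    m1 = sum(1 for g in w1 if table.partners.get(g, empty) & set2)
    m2 = sum(1 for g in w2 if table.partners.get(g, empty) & set1)
    return 0.5 * (m1 / len(w1) + m2 / len(w2))


def total_copy_number(pair: HomoeologPair, table: PairTable) -> int:
    """Partner count of gene1 plus partner count of gene2 (minimum 2)."""
    return table.partner_count(pair.gene1) + table.partner_count(pair.gene2)


def compute_features(
    table: PairTable,
    annotation: GenomeAnnotation,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[PairFeatures]:
    """Features for every pair in the table, in table order."""
    return [
        PairFeatures(
            synteny_score=synteny_score(p, annotation, table, window_size),
            distance=p.distance,
            total_copy_nr=total_copy_number(p, table),
        )
        for p in table.pairs
    ]


def pair_count_matrix(
    table: PairTable,
    annotation: GenomeAnnotation,
    subgenome1: str,
    subgenome2: str,
) -> ChromPairMatrix:
    """Pair counts per scaffold pair between two subgenomes.

    Unplaced scaffolds are counted under their own scaffold id; collapsing
    them onto chromosomes is left to a caller-supplied renaming of the
    annotation.
    """
    known = set(annotation.subgenomes)
    for label in (subgenome1, subgenome2):
        if label not in known:
            raise ValidationError(
                f"unknown subgenome label {label!r}; annotation has {sorted(known)}"
            )
    counts: dict[tuple[str, str], int] = {}
    for p in table.pairs:
        subs = {
            annotation.subgenome_of(p.gene1): p.gene1,
            annotation.subgenome_of(p.gene2): p.gene2,
        }
        if set(subs) != {subgenome1, subgenome2}:
            continue
        cell = (
            annotation.scaffold_of(subs[subgenome1]),
            annotation.scaffold_of(subs[subgenome2]),
        )
        counts[cell] = counts.get(cell, 0) + 1
    return ChromPairMatrix(subgenome1=subgenome1, subgenome2=subgenome2, counts=counts)
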