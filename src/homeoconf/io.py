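"""Validated containers and flat-file I/O for annotations and pair tables.

Two input files drive a scoring run: a gene annotation assigning every gene
to a subgenome, scaffold and coordinate interval (GFF3 or a 6-column TSV),
and a candidate homoeolog pair table carrying one evolutionary distance in
PAM units per pair (3-column TSV).  Genes without a subgenome assignment are
dropped up front -- homoeology is only defined between subgenomes -- and the
drop count is kept on the annotation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class HomeoconfError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(HomeoconfError):
    """A malformed input row; the message names the offending line."""


class ValidationError(HomeoconfError):
    """Structurally parseable input that violates a domain invariant."""


VALID_STRANDS = {"+", "-", "unknown"}


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identifier, subgenome label, scaffold and 1-based coordinates."""

    gene_id: str
    subgenome: str
    scaffold: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if not self.subgenome:
            raise ValidationError(f"gene {self.gene_id}: empty subgenome label")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be one of {sorted(VALID_STRANDS)}"
            )


@dataclass
class GenomeAnnotation:
    """Gene records plus the per-scaffold gene order the synteny window uses.

    ``order`` lists gene ids per scaffold sorted by start coordinate
    (ties broken by lexicographic gene id); ``rank`` maps each gene id to its
    index in its scaffold's order list.  Strand is carried but never used:
    the windowed synteny score is orientation-free.
    """

    genes: dict[str, GeneRecord]
    order: dict[str, list[str]]
    rank: dict[str, int]
    n_dropped: int = 0

    @classmethod
    def from_records(
        cls, records: Iterable[GeneRecord], n_dropped: int = 0
    ) -> "GenomeAnnotation":
        genes: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in genes:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
            genes[rec.gene_id] = rec
        by_scaffold: dict[str, list[GeneRecord]] = {}
        for rec in genes.values():
            by_scaffold.setdefault(rec.scaffold, []).append(rec)
        order: dict[str, list[str]] = {}
        rank: dict[str, int] = {}
        for scaffold in sorted(by_scaffold):
            recs = sorted(by_scaffold[scaffold], key=lambda r: (r.start, r.gene_id))
            ids = [r.gene_id for r in recs]
            order[scaffold] = ids
            for i, gid in enumerate(ids):
                rank[gid] = i
        return cls(genes=genes, order=order, rank=rank, n_dropped=n_dropped)

    def scaffold_of(self, gene_id: str) -> str:
        try:
            return self.genes[gene_id].scaffold
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def subgenome_of(self, gene_id: str) -> str:
        try:
            return self.genes[gene_id].subgenome
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    @property
    def subgenomes(self) -> list[str]:
        return sorted({rec.subgenome for rec in self.genes.values()})

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class HomoeologPair:
    """A candidate homoeolog pair with its evolutionary distance (PAM units)."""

    gene1: str
    gene2: str
    distance: float

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValidationError(f"pair of a gene with itself: {self.gene1!r}")
        if self.distance < 0:
            raise ValidationError(
                f"pair ({self.gene1}, {self.gene2}): negative distance {self.distance}"
            )

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene1, self.gene2))


@dataclass
class PairTable:
    """Candidate pairs plus a symmetric gene -> partner-set index.

    The partner index drives both the synteny window matching and the total
    copy number, so it is always rebuilt from ``pairs`` and kept symmetric.
    """

    pairs: list[HomoeologPair]
    partners: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[HomoeologPair]) -> "PairTable":
        unique: dict[frozenset, HomoeologPair] = {}
        n_dup = 0
        for p in pairs:
            if p.key in unique:
                n_dup += 1
                continue
            unique[p.key] = p
        if n_dup:
            warnings.warn(
                f"collapsed {n_dup} duplicate unordered pair(s)", stacklevel=2
            )
        table = cls(pairs=list(unique.values()))
        table.rebuild_index()
        return table

    def rebuild_index(self) -> None:
        partners: dict[str, set[str]] = {}
        for p in self.pairs:
            partners.setdefault(p.gene1, set()).add(p.gene2)
            partners.setdefault(p.gene2, set()).add(p.gene1)
        self.partners = partners

    def partner_count(self, gene_id: str) -> int:
        try:
            return len(self.partners[gene_id])
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in pair table") from None

    def validate_against(self, annotation: GenomeAnnotation) -> None:
        """Check every paired gene is annotated and pairs span subgenomes."""
        missing = sorted(
            {g for p in self.pairs for g in (p.gene1, p.gene2)} - set(annotation.genes)
        )
        if missing:
            raise ValidationError(
                f"{len(missing)} paired gene(s) absent from annotation: "
                + ", ".join(missing[:10])
                + ("..." if len(missing) > 10 else "")
            )
        same = [
            p
            for p in self.pairs
            if annotation.subgenome_of(p.gene1) == annotation.subgenome_of(p.gene2)
        ]
        if same:
            p = same[0]
            raise ValidationError(
                f"{len(same)} pair(s) within one subgenome, e.g. ({p.gene1}, {p.gene2})"
            )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ScoredPair:
    """A pair with its three features and its raw and rescaled confidence."""

    pair: HomoeologPair
    synteny_score: float
    total_copy_nr: int
    raw_confidence: float
    scaled_confidence: float


# ---------------------------------------------------------------------------
# readers / writers

_TSV_COLUMNS = 6  # gene_id, subgenome, scaffold, start, end, strand


def _read_annotation_tsv(path: Path) -> tuple[list[GeneRecord], int]:
    records: list[GeneRecord] = []
    n_dropped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "gene_id":
                continue  # optional header
            if len(row) != _TSV_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_TSV_COLUMNS} tab-separated "
                    f"columns, got {len(row)}"
                )
            gene_id, subgenome, scaffold, start, end, strand = row
            if not subgenome.strip():
                n_dropped += 1
                continue
            try:
                rec = GeneRecord(
                    gene_id=gene_id,
                    subgenome=subgenome,
                    scaffold=scaffold,
                    start=int(start),
                    end=int(end),
                    strand=strand or "unknown",
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records, n_dropped


def _read_annotation_gff3(path: Path, subgenome_attr: str) -> tuple[list[GeneRecord], int]:
    from gffutils.feature import feature_from_line

    records: list[GeneRecord] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if feat.featuretype != "gene":
                continue
            ids = feat.attributes.get("ID") or []
            if not ids:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            labels = feat.attributes.get(subgenome_attr) or []
            if not labels or not labels[0].strip():
                n_dropped += 1
                continue
            strand = feat.strand if feat.strand in ("+", "-") else "unknown"
            records.append(
                GeneRecord(
                    gene_id=ids[0],
                    subgenome=labels[0],
                    scaffold=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=strand,
                )
            )
    return records, n_dropped


def read_annotation(
    path: str | Path,
    format: str | None = None,
    subgenome_attr: str = "subgenome",
) -> GenomeAnnotation:
    """Read a gene annotation from GFF3 or 6-column TSV.

    Parameters
    ----------
    path
        Input file.  When ``format`` is None it is inferred from the suffix
        (``.gff``/``.gff3`` -> gff3, anything else -> tsv).
    format
        ``"gff3"`` or ``"tsv"``.
    subgenome_attr
        GFF3 attribute key carrying the subgenome label (default
        ``subgenome``).  Genes lacking the label are dropped and counted on
        the returned annotation's ``n_dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if format == "gff3":
        records, n_dropped = _read_annotation_gff3(path, subgenome_attr)
    elif format == "tsv":
        records, n_dropped = _read_annotation_tsv(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GenomeAnnotation.from_records(records, n_dropped=n_dropped)


def read_pairs(
    path: str | Path, annotation: GenomeAnnotation | None = None
) -> PairTable:
    """Read a 3-column pair TSV (gene1, gene2, distance) into a PairTable.

    Duplicate unordered pairs are collapsed with a warning.  When an
    annotation is supplied, every gene must be annotated and every pair must
    span two subgenomes.
    """
    path = Path(path)
    pairs: list[HomoeologPair] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "gene1":
                continue
            if len(row) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(row)}"
                )
            g1, g2, dist = row
            try:
                d = float(dist)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad distance {dist!r}") from None
            pairs.append(HomoeologPair(gene1=g1, gene2=g2, distance=d))
    table = PairTable.from_pairs(pairs)
    if annotation is not None:
        table.validate_against(annotation)
    return table


SCORED_HEADER = (
    "gene1",
    "gene2",
    "distance",
    "synteny_score",
    "total_copy_nr",
    "raw_confidence",
    "scaled_confidence",
)


def write_scored(scored: Sequence[ScoredPair], path: str | Path) -> None:
    """Write scored pairs as TSV; floats at 4 decimals, input order preserved."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SCORED_HEADER)
        for s in scored:
            writer.writerow(
                [
                    s.pair.gene1,
                    s.pair.gene2,
                    f"{s.pair.distance:.4f}",
                    f"{s.synteny_score:.4f}",
                    s.total_copy_nr,
                    f"{s.raw_confidence:.4f}",
                    f"{s.scaled_confidence:.4f}",
                ]
            )


def read_scored(path: str | Path) -> list[ScoredPair]:
    """Read back a TSV written by :func:`write_scored`."""
    out: list[ScoredPair] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and tuple(header) != SCORED_HEADER:
            raise ParseError(f"{path}: unexpected header {header!r}")
        for row in reader:
            if not row:
                continue
            g1, g2, dist, syn, cn, raw, scaled = row
            out.append(
                ScoredPair(
                    pair=HomoeologPair(g1, g2, float(dist)),
                    synteny_score=float(syn),
                    total_copy_nr=int(cn),
                    raw_confidence=float(raw),
                    scaled_confidence=float(scaled),
                )
            )
    return out
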