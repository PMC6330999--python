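"""Synthetic allopolyploid genomes with known homoeology truth labels.

The generator emulates the genome structure the scorer assumes, without any
sequence simulation.  Two or three subgenomes descend from one ancestral
gene order: each subgenome carries a copy of every ancestral locus on the
matching chromosome, so retained loci form collinear one-to-one homoeolog
pairs across subgenomes.  On top of this backbone it plants the
complications the confidence score is meant to handle:

* **reciprocal translocations** -- contiguous segments exchanged between two
  chromosomes of the first subgenome.  The affected pairs land off-diagonal
  in the chromosome-pair count matrix yet keep high *local* synteny, because
  their neighborhoods move with them.
* **TE-like decoy families** -- high-copy genes scattered at random
  positions (half of them on their own single-gene scaffolds), paired
  across subgenomes with large evolutionary distances, mimicking
  transposable elements annotated as genes.
* **single-gene scaffolds** -- retained homoeologs relocated to one-gene
  scaffolds, which exercises the zero-synteny rule.

Pair distances are drawn from normals truncated at zero: tight and small
for true homoeologs (subgenomes diverged recently), broad and large for
decoys (fast-evolving repeats).  A single integer seed drives all sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from homeoconf.io import (
    GeneRecord,
    GenomeAnnotation,
    HomoeologPair,
    PairTable,
    ValidationError,
)

SUBGENOME_LABELS = "ABC"

TRUE_ONE_TO_ONE = "true_one_to_one"
TRANSLOCATED_TRUE = "translocated_true"
DECOY = "decoy"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic genome.

    Defaults describe a compact but structured allotetraploid: two
    subgenomes of five chromosomes x 400 genes, 90% of loci retained as
    clean 1:1 homoeologs (~1,800 true pairs), two reciprocal translocations
    of 40 genes, twenty 8-copy decoy families (160 decoy pairs) and twenty
    single-gene scaffolds.  True-pair distances ~N(0.1, 0.05) PAM truncated
    at 0, decoy distances ~N(1.0, 0.4): recently diverged subgenomes versus
    fast-evolving repeat families.
    """

    n_subgenomes: int = 2
    n_chromosomes: int = 5
    genes_per_chromosome: int = 400
    p_one_to_one: float = 0.9
    n_translocations: int = 2
    translocation_span: int = 40
    n_decoy_families: int = 20
    decoy_family_size: int = 8
    n_single_gene_scaffolds: int = 20
    distance_true: tuple[float, float] = (0.1, 0.05)
    distance_decoy: tuple[float, float] = (1.0, 0.4)
    seed: int = 42

    def validate(self) -> None:
        if self.n_subgenomes not in (2, 3):
            raise ValidationError("n_subgenomes must be 2 or 3")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValidationError("need at least one chromosome with one gene")
        if not 0.0 <= self.p_one_to_one <= 1.0:
            raise ValidationError("p_one_to_one must be in [0, 1]")
        for name in (
            "n_translocations",
            "translocation_span",
            "n_decoy_families",
            "decoy_family_size",
            "n_single_gene_scaffolds",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_translocations > 0:
            if self.translocation_span > self.genes_per_chromosome:
                raise ValidationError(
                    "translocation_span exceeds genes_per_chromosome"
                )
            if 2 * self.n_translocations > self.n_chromosomes:
                raise ValidationError(
                    "each translocation needs its own pair of chromosomes: "
                    "2 * n_translocations must not exceed n_chromosomes"
                )
        for attr in ("distance_true", "distance_decoy"):
            mean, sd = getattr(self, attr)
            if mean < 0 or sd <= 0:
                raise ValidationError(f"{attr} needs mean >= 0 and sd > 0")

    @property
    def subgenomes(self) -> list[str]:
        return list(SUBGENOME_LABELS[: self.n_subgenomes])

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome

    @property
    def n_retained(self) -> int:
        return round(self.p_one_to_one * self.n_loci)


@dataclass
class SyntheticDataset:
    """Annotation + pair table + per-pair truth labels (and planted metadata)."""

    annotation: GenomeAnnotation
    pairs: PairTable
    truth: dict[frozenset, str]
    config: SimulationConfig
    translocations: list[tuple[str, str]] = field(default_factory=list)

    def pairs_of_class(self, label: str) -> list[HomoeologPair]:
        return [p for p in self.pairs.pairs if self.truth[p.key] == label]

    def write(self, outdir) -> dict[str, str]:
        """Write annotation.tsv, pairs.tsv and truth.tsv under ``outdir``.

        Returns the mapping of logical name to written path.  Output is
        deterministic byte-for-byte given config + seed.
        """
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.tsv",
            "pairs": outdir / "pairs.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["annotation"], "w") as fh:
            fh.write("gene_id\tsubgenome\tscaffold\tstart\tend\tstrand\n")
            for scaffold in sorted(self.annotation.order):
                for gid in self.annotation.order[scaffold]:
                    r = self.annotation.genes[gid]
                    fh.write(
                        f"{r.gene_id}\t{r.subgenome}\t{r.scaffold}\t"
                        f"{r.start}\t{r.end}\t{r.strand}\n"
                    )
        with open(paths["pairs"], "w") as fh:
            fh.write("gene1\tgene2\tdistance\n")
            for p in self.pairs.pairs:
                fh.write(f"{p.gene1}\t{p.gene2}\t{p.distance:.6f}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("gene1\tgene2\tclass\n")
            for p in self.pairs.pairs:
                fh.write(f"{p.gene1}\t{p.gene2}\t{self.truth[p.key]}\n")
        return {k: str(v) for k, v in paths.items()}


def _truncnorm_rvs(mean: float, sd: float, size: int, rng: np.random.Generator):
    a = (0.0 - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def expected_counts(config: SimulationConfig) -> dict[str, int]:
    """Closed-form pair counts planted by :func:`generate`.

    True and decoy counts are exact; the translocated count is an
    expectation (it depends on which loci happen to be retained inside the
    exchanged segments).
    """
    config.validate()
    n_cross = math.comb(config.n_subgenomes, 2)
    n_true = config.n_retained * n_cross
    n_decoy = config.n_decoy_families * config.decoy_family_size
    expected_transloc = round(
        config.p_one_to_one
        * 2
        * config.n_translocations
        * config.translocation_span
        * (config.n_subgenomes - 1)
    )
    return {
        "n_pairs_total": n_true + n_decoy,
        "n_true_pairs": n_true,
        "n_decoy_pairs": n_decoy,
        "expected_translocated_pairs": expected_transloc,
    }


def generate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate one synthetic dataset; bit-identical for identical config+seed."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    subs = config.subgenomes
    gpc = config.genes_per_chromosome

    def gene_id(sub: str, locus: int) -> str:
        return f"{sub}g{locus:05d}"

    # chromosome gene lists, identical ancestral order in every subgenome
    chrom_genes: dict[str, list[str]] = {}
    for sub in subs:
        for c in range(config.n_chromosomes):
            chrom_genes[f"{sub}{c + 1:02d}"] = [
                gene_id(sub, c * gpc + j) for j in range(gpc)
            ]

    # which ancestral loci are retained as homoeolog pairs
    retained = set(
        rng.choice(config.n_loci, size=config.n_retained, replace=False).tolist()
    )

    # reciprocal translocations within the first subgenome: disjoint
    # chromosome pairs exchange a contiguous segment of equal span
    moved_loci: set[int] = set()
    translocations: list[tuple[str, str]] = []
    if config.n_translocations:
        perm = rng.permutation(config.n_chromosomes)
        for t in range(config.n_translocations):
            c1, c2 = int(perm[2 * t]), int(perm[2 * t + 1])
            k1, k2 = f"{subs[0]}{c1 + 1:02d}", f"{subs[0]}{c2 + 1:02d}"
            off1 = int(rng.integers(0, gpc - config.translocation_span + 1))
            off2 = int(rng.integers(0, gpc - config.translocation_span + 1))
            span = config.translocation_span
            seg1 = chrom_genes[k1][off1 : off1 + span]
            seg2 = chrom_genes[k2][off2 : off2 + span]
            chrom_genes[k1][off1 : off1 + span] = seg2
            chrom_genes[k2][off2 : off2 + span] = seg1
            for gid in seg1 + seg2:
                moved_loci.add(int(gid[len(subs[0]) + 1 :]))
            translocations.append((k1, k2))

    # relocate some retained first-subgenome genes to single-gene scaffolds
    # (their pairs get synteny 0); avoid the translocated segments so the
    # two planted effects stay separable in truth labels
    singleton_loci: set[int] = set()
    if config.n_single_gene_scaffolds:
        eligible = sorted(retained - moved_loci)
        n_take = min(config.n_single_gene_scaffolds, len(eligible))
        take = rng.choice(len(eligible), size=n_take, replace=False)
        singleton_loci = {eligible[i] for i in take}
        lost = {gene_id(subs[0], l) for l in singleton_loci}
        for key in list(chrom_genes):
            if key.startswith(subs[0]):
                chrom_genes[key] = [g for g in chrom_genes[key] if g not in lost]
        for i, locus in enumerate(sorted(singleton_loci)):
            chrom_genes[f"scaffold_{i + 1:03d}"] = [gene_id(subs[0], locus)]

    # decoy families: one focal gene in the first subgenome, family_size
    # partner genes round-robin across the other subgenomes; each decoy gene
    # goes to its own single-gene scaffold with probability 0.5, otherwise
    # it is inserted at a random position on a random chromosome
    n_singleton_scaffolds = len(singleton_loci)
    gene_subgenome: dict[str, str] = {}

    def place_decoy(gid: str, sub: str) -> None:
        nonlocal n_singleton_scaffolds
        gene_subgenome[gid] = sub
        on_singleton = bool(rng.random() < 0.5)
        if on_singleton:
            n_singleton_scaffolds += 1
            chrom_genes[f"scaffold_{n_singleton_scaffolds:03d}"] = [gid]
        else:
            c = int(rng.integers(0, config.n_chromosomes))
            key = f"{sub}{c + 1:02d}"
            pos = int(rng.integers(0, len(chrom_genes[key]) + 1))
            chrom_genes[key].insert(pos, gid)

    decoy_pairs: list[tuple[str, str]] = []
    for fam in range(config.n_decoy_families):
        focal = f"TE{fam + 1:03d}_0"
        place_decoy(focal, subs[0])
        for k in range(config.decoy_family_size):
            sub = subs[1 + k % (config.n_subgenomes - 1)]
            member = f"TE{fam + 1:03d}_{k + 1}"
            place_decoy(member, sub)
            decoy_pairs.append((focal, member))

    # true homoeolog pairs across every subgenome combination
    true_pairs: list[tuple[str, str]] = []
    for locus in sorted(retained):
        for i in range(config.n_subgenomes):
            for j in range(i + 1, config.n_subgenomes):
                true_pairs.append((gene_id(subs[i], locus), gene_id(subs[j], locus)))

    d_true = _truncnorm_rvs(*config.distance_true, len(true_pairs), rng)
    d_decoy = _truncnorm_rvs(*config.distance_decoy, len(decoy_pairs), rng)

    pairs: list[HomoeologPair] = []
    truth: dict[frozenset, str] = {}
    for (g1, g2), d in zip(true_pairs, d_true):
        p = HomoeologPair(g1, g2, float(d))
        locus = int(g1[2:])
        label = TRANSLOCATED_TRUE if locus in moved_loci else TRUE_ONE_TO_ONE
        pairs.append(p)
        truth[p.key] = label
    for (g1, g2), d in zip(decoy_pairs, d_decoy):
        p = HomoeologPair(g1, g2, float(d))
        pairs.append(p)
        truth[p.key] = DECOY

    # coordinates follow the final per-scaffold order: 1 kb gene spacing
    records: list[GeneRecord] = []
    for scaffold in sorted(chrom_genes):
        for i, gid in enumerate(chrom_genes[scaffold]):
            gsub = gene_subgenome.get(gid, gid[0])
            start = 1 + 1000 * i
            records.append(
                GeneRecord(
                    gene_id=gid,
                    subgenome=gsub,
                    scaffold=scaffold,
                    start=start,
                    end=start + 500,
                    strand="+",
                )
            )

    annotation = GenomeAnnotation.from_records(records)
    table = PairTable.from_pairs(pairs)
    table.validate_against(annotation)
    return SyntheticDataset(
        annotation=annotation,
        pairs=table,
        truth=truth,
        config=config,
        translocations=translocations,
    )
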