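# Methods

## The scoring problem

Given (a) a gene annotation in which every gene carries a subgenome label,
a scaffold and coordinates, and (b) a table of candidate homoeolog pairs
with one evolutionary distance (PAM units) per pair, `homeoconf` assigns
each pair a confidence score on a 0–100 scale. The method is deliberately
not a trained classifier: no ground truth exists for homoeology calls, so
the score encodes expert reasoning — high synteny, low distance and
one-to-one copy structure are good signs, none of them individually
decisive — as a Mamdani fuzzy control system. Subgenome assignment is
always taken from the annotation, never inferred.

## Features

**Local synteny.** For each gene of a pair, the neighbor window is the up
to `w = 10` genes nearest by rank in the scaffold's gene order (sorted by
start coordinate, ties broken by gene id). A window gene *matches* when any
of its partners in the genome-wide pair table falls in the opposite window.
The score is the mean of the two windows' match proportions, using each
window's actual size as denominator (windows may differ in size near
scaffold ends; the focal genes are excluded from both numerator and
denominator). If either gene's scaffold holds fewer than two genes the
score is defined as 0 — with no neighborhood there is no synteny evidence.
Two interpretation choices were genuinely open and are fixed as follows:
windows borrow from the available side at scaffold edges (a terminal gene
on a long scaffold still gets 10 neighbors, preferring the upstream gene on
rank-distance ties), and "fewer than 10 genes" is read as "fewer than `w`
*other* genes", so short scaffolds contribute everything they have.
Matching consults the full pair table rather than only the focal subgenome
pair — the permissive reading; with two subgenomes the two coincide.
Strand is ignored throughout: the windowed proportion is orientation-free.

**Distance** is consumed as given, in PAM units. It is never computed from
sequence; the package has no alignment machinery.

**Total copy number** is `|partners(g1)| + |partners(g2)|` over the same
table, minimum 2.

## Universes and membership functions

Every variable gets a discretized universe and Gaussian classes
`μ(x) = exp(−(x−c)²/2σ²)`:

| variable    | universe (step)        | low (c, σ)       | med (c, σ)             | high (c, σ)        |
|-------------|------------------------|------------------|------------------------|--------------------|
| distance    | 0 … d_max (0.01)       | 0, d_max/10      | d_max/4, d_max/10      | d_max, d_max/2.5   |
| synteny     | 0 … 1 (0.01)           | 0, 0.15          | 0.3, 0.15              | 1, 0.4             |
| copy number | 2 … c_max (1)          | c_med, c_med     | 4·c_med, 1.5·c_med     | c_max, c_max/2.5   |

with cohort statistics d_max = max distance, c_med = median copy number
(mean of middle two for even n), c_max = max copy number. Synteny classes
are static because the score always lives in [0, 1]; distance and copy
classes adapt so that "low distance" means the same *linguistic* thing in a
recently diverged tetraploid and in a hexaploid full of small scaffolds.
The output variable, confidence, spans 0–100 (step 1) with five classes:
very low (0, 20), low (50, 10), med (70, 10), high (90, 10),
very high (100, 10).

Numerical details: universe grids are inclusive, appending the upper bound
when the range is not a whole number of steps; inputs are clipped to their
universe before fuzzification so a model frozen on one cohort can score new
pairs; two degenerate-cohort fallbacks keep tiny toy datasets working
(d_max = 0 → one grid step; c_max = 2 → copy universe [2, 3] with high
class Gaussian(3, 1.2)), both with a warning.

## Rules and why the middle ones condition on synteny alone

Inference is the conventional Mamdani configuration: AND = min, OR = max,
NOT = 1−x, consequent truncation at the firing strength, pointwise-max
aggregation, discrete centroid defuzzification `Σ(x·μ)/Σ(μ)` on the unit
grid (within 0.5 confidence units of fine-grid trapezoid integration; the
test suite checks this against a 10×-finer oracle on random aggregates).

The default rule base:

1. synteny high **and** distance low **and** copynr low → **very high**
2. synteny high → **high**
3. synteny med → **med**
4. synteny low → **low**
5. synteny low **and** distance high **and** copynr high → **very low**

Rules 1 and 5 define the unambiguous extremes. Rules 2–4 grade everything
in between on synteny alone, which is both the feature weighted most
heavily by design (a syntenic non-homoeolog is very unlikely) and a
structural requirement: the crisp output should be monotone — non-decreasing
in synteny, non-increasing in distance and copy number. Mixing
quality-increasing atoms (distance low, copynr low) into rules with mid- or
low-confidence consequents breaks that monotonicity under centroid
defuzzification, because *weakening* such a rule removes membership mass
from the middle of the confidence scale and the centroid climbs; e.g. with
rule 4 as "synteny low and (distance low or copynr low) → low", raising the
copy number from 4.7 to 5.6 at synteny 0.15 *increases* the score by ~1.8
units. The synteny-only ladder is monotone everywhere (verified exactly on
a 21³ grid). Distance and copy number still act through rules 1 and 5, at
the extremes where they are most informative. The rule base ships as YAML
and can be replaced wholesale at the CLI or API; antecedents are parsed
from `var is label` expressions with and/or/not and parentheses.

## Scaling

Raw centroids cannot reach 100: the very-high class is truncated at the
universe bound, so even a perfect pair's centroid sits in the high 80s.
Per cohort (one scoring invocation over one genome's pair table), scores
are mapped by `scaled = min + (x − min)·(100 − min)/(max − min)` — the
minimum is kept as-is, the maximum becomes exactly 100, order is preserved.
A constant cohort maps to 100 by convention. The fixed-minimum form is one
of two defensible readings of "keep the smallest score as the minimum";
it is the one implemented, and `--no-scale` exposes raw centroids.

## Synthetic data

The generator builds the structure the scorer assumes, from one integer
seed: 2–3 subgenomes copy a shared ancestral gene order (chromosome `k` of
each subgenome is collinear), `round(p · n_loci)` loci are retained as 1:1
homoeolog pairs across every subgenome combination, and three
complications are planted with truth labels — reciprocal translocations
(equal-span segments exchanged between two chromosomes of the first
subgenome; affected pairs are off-diagonal in the chromosome-pair matrix
but keep high local synteny because their windows move with the segment),
TE-like decoy families (one focal gene with `f` cross-subgenome partners
scattered at random positions, half on their own single-gene scaffolds),
and retained pairs relocated to single-gene scaffolds to exercise the
zero-synteny rule. Distances come from normals truncated at zero:
(0.1, 0.05) PAM for true pairs — recently diverged subgenomes — and
(1.0, 0.4) for decoys, mimicking fast-evolving repeats.

Default conditions: 2 subgenomes × 5 chromosomes × 400 genes, p = 0.9,
two 40-gene translocations, twenty 8-copy decoy families, twenty
single-gene scaffolds — ~1,960 pairs, sized so the full default cohort
generates and scores in seconds on one CPU while containing every planted
structure at measurable multiplicity.

What the generator does **not** emulate: sequence evolution, unequal gene
loss between subgenomes, segmental duplications, tandem arrays, assembly
chimerism, or annotation noise in coordinates. Passing tests on this data
therefore show the *mechanics* are right (features, adaptation, inference,
scaling, diagnostics), not that the default rule base is well calibrated
for any particular real genome — calibration is explicitly a matter of
expert judgment, which is why the rules and the window size are exposed as
configuration.

## Known limitations

* Synteny degrades over evolutionary time; in old polyploids the score may
  be uninformative and the rule base would need re-weighting.
* The cohort-adaptive classes make scores comparable within a genome, not
  across genomes; cross-genome comparisons should use the model dump to
  hold membership functions fixed.
* Scaling is cohort-relative by design: adding or removing pairs changes
  every scaled score slightly.
* The centroid is computed on the unit-step output grid; its ≤0.5-unit
  discretization bias is far below the granularity at which the scores are
  meant to be read.
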