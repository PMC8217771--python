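# Methods

## Low-complexity region detection

LCRs are detected from windowed amino-acid composition, not entropy. Every
window of `window_len` residues (default 10) lying fully inside the sequence
is examined; a sequence shorter than one window can have no LCR. Fractional
thresholds are applied as integer counts via ceiling — ≥ 5, ≥ 4 and ≥ 2 of a
10-window for the 50%, 40% and 20% thresholds — so there are no
floating-point comparisons at the boundaries.

*Criterion (i), single*: a window is flagged for residue X when count(X) ≥ 5.
*Criterion (ii), pair*: a window is flagged for the unordered pair {X, Y}
when X attains the window's maximum count with count(X) ≥ 4 and Y is any
other residue with count(Y) ≥ 2. All qualifying residues and pairs are
emitted; ties at the maximum produce multiple pairs. `X` (unknown residue)
counts in the window denominator but is never an enriched residue.

For each residue (or pair), the positions covered by its flagged windows are
unioned and maximal runs of consecutive covered positions are formed. Each
run is then **trimmed at both ends to the nearest enriched residue** (either
member, for pairs) before the minimum stretch length is applied: ≥ 15
successive residues for single regions ("more than 14"), ≥ 20 for pair
regions ("more than 19"). The trimming rule is a deliberate design choice: a
flagged window holding exactly the threshold count extends coverage up to
`window_len − threshold` positions into unrelated flanking sequence, and
without trimming a pure 14-residue stretch embedded mid-sequence would
always be reported as a ~24-residue region, making the "more than 14"
boundary untestable. Trimming restores the boundary exactly (a 14-residue
plant is never called, a 15-residue plant is called with its exact span)
while leaving merged-coverage behaviour intact (e.g. T×8 A×4 T×8 is one
T-rich region 1–20, since every window across the gap still holds ≥ 5 T). A
visible consequence: in `GSGSGS…` the single G-rich span ends on the last G
(1–19) and the S-rich span starts on the first S (2–20), one residue inside
the pair span (1–20).

Single and pair regions are reported independently, even when their spans
coincide — compositional tables in this field list coexisting single and
pair labels for the same protein — and deduplication applies only to exactly
identical (kind, residues, span) tuples. Pair residues and labels are
alphabetized (`GS-rich`, never `SG-rich`). Output is sorted by (start, kind,
residues) and is byte-deterministic.

Homopolymer runs (e.g. poly-Asp tails, reported separately from the LCR
criteria because short runs of 2–15 residues do not reach the window
thresholds) are maximal single-residue runs of at least `min_len ≥ 2`.

## Physicochemical profiles

Net charge uses the Henderson–Hasselbalch form over basic groups
{N-terminus, His, Lys, Arg} and acidic groups {C-terminus, Asp, Glu, Cys,
Tyr}; Cys and Tyr are treated as ionizable acids (IPC convention) with no
disulfide correction. Q(pH) is strictly decreasing, so the pI is the unique
zero on [0, 14], bracketed by the free termini and found by bisection to
1 × 10⁻⁴ pH internally; reported values are rounded to 2 decimals. pKa sets
are named, versioned configuration: `IPC_protein` (default, matching the
IPC 1.0 protein set), `IPC_peptide` and `EMBOSS`, each transcribed from its
source publication. The pI is a pure function of composition (permutation
invariant).

Molecular weight is the sum of standard average residue masses plus one
water. `X` residues contribute zero charge and a configurable average
residue mass defaulting to the mean of the 20 standard residue masses.

The acidity verdict uses strict inequalities on both printed thresholds:
pI < 3.5 AND Asp+Glu fraction > 0.20.

## Classification

The two-peptide rule accepts a protein when its distinct peptides total ≥ 2
**summed over all extracts**, not per extract: extract-specific proteins
(present in a single extract with ≥ 2 peptides, or in two extracts with one
peptide each) are legitimate identifications, and no per-extract threshold
is defined for this kind of experiment. Per-extract presence is count ≥ 1.

Presence classes are assigned in precedence order — common-to-four, then
exactly-three, then ASM-only, then AIM-only — with `other` the remainder, so
the partition is disjoint and exhaustive by construction. The partition
requires exactly the four canonical extracts (two ASM, two AIM; group read
from the prefix before the underscore) and rejects unknown extract ids.

Categories: any catalogued domain makes a protein `conserved_domain`
(sub-category by precedence polysaccharide affinity > enzyme > protease
inhibitor when domains of several sub-categories co-occur); otherwise ≥ 1
LCR makes it `lcr_containing`; otherwise `uncharacterized`. LCR labels are
recorded in every category, since domain proteins frequently carry LCRs too.
The accession → sub-category catalog is configuration seeded with the
commonly reported shell-matrix accessions (chitin-binding PF01607 /
IPR002557 / PF03067, VWA PF00092 / SSF53300, TSP-1 PF00090, lectin folds
SSF49899 / SSF56436, glycoside hydrolase PF00150, tyrosinase PF00264,
Kunitz PF00014, Kazal IPR002350); uncatalogued accessions never trigger the
conserved-domain category unless added.

BMSP-likeness considers only catalogued domains in coordinate order: a
leading block of more than one VWA domain immediately followed by at least
one chitin-binding domain, with no other catalogued domain type between
them. Uncatalogued hits are transparent to the walk.

## Phospho overlay

Likely sites are those with probability strictly greater than 0.5 (the
strictness matches the convention of the upstream predictor's reporting).
Overlap counting merges all LCR spans to one position set, so a site under
two overlapping regions counts once; per-region densities (sites in region /
region length) are still reported per original region. When a protein has no
likely site the overlap fraction is reported as 0 with an explicit
`undefined_base` flag rather than NaN.

## ELLA normalization

The background is subtracted as the mean of the background replicates (the
assay does not pair control wells to sample wells), each lectin's replicates
are averaged, and all values are scaled so the maximum mean is exactly 100%.
Spread is the sample SD (n − 1) of the background-subtracted replicates on
the percent scale; with a single replicate it is reported as 0. Negative
background-subtracted values are preserved by default (`clamp_zero` floors
them), keeping the arithmetic faithful to the raw readings. The
normalization is invariant to adding a constant to, or rescaling, all
readings *including* the background — both properties are tested. A plate
whose strongest lectin does not exceed background is rejected ("no signal
above background").

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:
sequences drawn residue-wise from background frequencies (default uniform
over the standard alphabet), planted single- or pair-biased stretches at
recorded positions with stated purity, optional poly-Asp C-terminal tails
and domain annotations, four-extract evidence templates covering every
presence class, phospho tracks concentrated on S/T, and 21-lectin plates
with Gaussian replicate noise (default SD 0.02 A405 over three replicates,
the typical spread of such plate reads) and a background well. Default
protein lengths are 120–260 residues, the size range typical of secreted
matrix proteins.

In clean mode (default) the background alphabet excludes each protein's
focal residues and every background segment is redrawn until it contains no
flagged composition window at all, so recovery of purity-1.0 plants is exact
and the false-positive rate is zero by construction. Purity-1.0 pair plants
alternate their two residues (50/50), which necessarily also satisfies the
single criterion — recovery assertions therefore match on region kind.
Plants shorter than the stretch minima (14 / 19) are guaranteed to produce
no detection *of their kind*; they cannot suppress the inherent single
content of alternating pair plants, which is real signal under criterion
(i). Plants with purity < 1 are marked approximate in the truth table and
support only overlap-based assertions. Everything is deterministic under the
spec seed; the phospho and plate sub-generators derive their streams from
seed + 1 and seed + 2 so the corpora are independent.

Phospho probabilities are drawn as 0.5 + 0.5·Beta(8, 2) for likely sites and
0.5·Beta(2, 8) for unlikely ones: realistic right- and left-skewed shapes
whose likely/unlikely status is controlled exactly by the in-LCR and
outside-LCR rate parameters (defaults 0.8 and 0.05), which is what lets
forced cases (outside rate 0 → overlap fraction 1.0) be asserted exactly.

What passing tests on synthetic data do **not** show: real shell proteomes
have correlated composition (signal peptides, repeats, domain-linker
structure), LCRs of intermediate purity with ragged edges, and predictor
scores with sequence-context correlation — none of which the generator
models. The synthetic results validate the *operations*, not biological
conclusions.

## Problem sizes

The test suite and acceptance script run the oracle comparison on 500
sequences of 30–80 residues over a four-letter-heavy alphabet, recovery on
100 single + 100 pair planted proteins with 25 + 25 negative controls, pI
grid checks on 100 random 15–60-mers against a 0.0005-pH grid, and cohorts
of 20 proteins for the classification algebra — sizes at which every
property is exercised well away from its boundaries while the whole suite
completes in well under a minute per module.

## Known limitations

* The LCR stretch-length semantics ("successive polypeptides") admit a
  window-run reading; the position-coverage-with-trimming reading implemented
  here is the one that makes the stated boundaries exact and testable.
* The pI model ignores post-translational modifications (notably
  phosphorylation, which the overlay module predicts but the charge model
  does not feed back), disulfides, and electrostatic interactions between
  sites.
* The domain catalog is a curated seed list, not a complete functional
  ontology; classification quality on real data is bounded by the upstream
  annotations supplied.
* ELLA normalization takes one prepared reading set per plate; kinetic
  time-course selection happens upstream.
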