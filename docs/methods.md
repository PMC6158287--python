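# Methods

`sortsel` analyzes pairwise FACS selectivity screens of displayed inhibitor
libraries read out by sequencing, and the tight-binding inhibition kinetics
used to validate them. This note records the models, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where more than one reasonable convention exists.

## Read preparation

Read pairs are dropped when either mate's mean Phred score falls below 20
(99% per-base accuracy); the filter runs before merging. Merging follows the
FLASH approach: read 2 is reverse-complemented and every candidate overlap
length between `min_overlap` (default 10) and the shorter mate length is
scored by mismatch density; the minimum-density overlap wins, ties going to
the longer overlap, and the merge fails when the best density exceeds
`max_mismatch_density` (default 0.25). Consensus calls inside the overlap
take the higher-quality base (read 1 on quality ties), with consensus
quality `max(q1, q2)` on agreement and `|q1 - q2|` on disagreement. These
defaults are FLASH's published ones; the merge is deterministic, so a fixed
input always yields the same consensus. Reads containing N pass through the
merger; they are removed at translation instead.

## Variant calling

Merged reads are translated with the standard genetic code. Because the
library carries substitutions only, alignment to the reference is the
equal-length rule: translated sequences whose length differs from the
reference are discarded (`length_mismatch`), as are sequences containing a
stop (`stop_codon`) or an N-derived ambiguous residue (`ambiguous_residue`);
everything else is compared position by position. Counting is at the protein
level — synonymous codon variants collapse into one amino-acid variant —
because every downstream landscape is amino-acid resolved. Residues are
reported in canonical (BPTI/Kunitz) numbering via a configurable offset; the
bundled reference places the binding loop at residues 11–18 with the
invariant cysteine at 14 excluded from the mutagenized set.

The bundled reference ORF is a **synthetic** 57-codon Kunitz-domain sequence
(deterministic back-translation, one codon per amino acid). It carries the
loop identities the analysis conventions assume (Thr-11, Cys-14, Gly-17) and
serves as simulation substrate; every pipeline stage accepts any reference
FASTA plus numbering offset.

## Enrichment ratios

Variants with one and with two substitutions form separate analysis classes
(the unmutated parent and >2-substitution variants are outside both).
Read-count thresholds are 100 (singles) and 10 (doubles): a variant below
threshold in both the naive and sorted libraries is discarded; below in only
one, that count is floored up to the threshold, which caps the enrichment or
depletion a sparsely sampled variant can claim. Frequencies
`F_v = Reads_v / sum(Reads_v)` are computed after flooring, with the
denominator running over the retained variants of the class in that library
(a `shared_denominator` switch pools the classes). The enrichment ratio is
`ER_v = F_v,sorted / F_v,naive`. Replicate sequencing runs are accepted when
all pairwise Spearman rank correlations (union of variant keys, absences as
zero, average ranks on ties) reach 0.95, then pooled by summing counts;
summation is the natural pooling for multinomial sequencing counts.

## Landscapes

Single-mutant heatmaps are amino acid x position matrices of log2(ER).
Position classes use a strict majority over observed substitutions: more
than half depleted (ER < 1) is a hot spot, more than half enriched a cold
spot, ER exactly 1 counts toward neither side, and positions with fewer than
`min_observed` = 8 of the 19 possible substitutions are reported as
insufficient data rather than forced into a class. Selectivity switches are
single mutations with ER at or above `high_cut` (default 2) in one gate of a
pairwise screen and at or below `low_cut` (default 0.5) in the reciprocal
gate; mutations surviving thresholds in only one gate cannot be assessed and
are listed separately rather than silently dropped. The pairwise selectivity
score between two mutations m1 -> m2 is the fold change of ER toward target
A divided by the fold change toward B; the parent acts as the neutral
reference with ER 1. For doubles, the residue-pair map sums ER over all
retained variants mutated at the same position pair (reported together with
the contributing count N and implicitly the mean via sum/N — the summed
value is what the landscape heatmaps show, but the two are not
interchangeable when N varies across cells); the per-pair combination map
resolves that sum into its amino-acid combinations, and its cells add back
to the pair map exactly. Total selectivity toward a primary target is the
product of the per-competitor relative selectivities.

A pooled-competitor screen (one target versus a labeled mixture) is an
ordinary two-channel comparison and reuses all of the above unchanged.

## Tight-binding kinetics

Slow tight-binding progress curves follow
`P(t) = baseline + vs*t + (v0 - vs)(1 - exp(-kobs*t))/kobs`. The fit is
performed in range-normalized units so its convergence behavior is
independent of signal and time scales, with `vs` parametrized as a fraction
of `v0` in [0, 1] — an inhibitor cannot accelerate the reaction — which also
keeps uninhibited (straight-line) curves well-behaved: there `kobs` is
flagged unidentifiable and the slope is returned as both velocities.
Initialization uses early/late finite-difference slopes. Steady-state
velocities across the inhibitor titration are fit to the Morrison quadratic
`vs/v0 = 1 - ((E + I + Ki_app) - sqrt((E + I + Ki_app)^2 - 4 E I))/(2E)`,
which avoids the free-inhibitor approximation and is the standard treatment
when `[I] ~ [E]` (pM-scale constants). The reported `Ki` applies the
competitive-substrate correction `Ki = Ki_app / (1 + S/Km)`; both assay
substrates are treated as competitive, with user-supplied Km.

The selectivity algebra on fitted Ki values: calculated selectivity of a
mutant toward a reference target versus another is
`(Ki_parent,ref / Ki_mut,ref) / (Ki_parent,other / Ki_mut,other)` (1 for the
parent, scale-invariant per target); total selectivity is the product over
competitor targets; the expected selectivity of a double mutant is the
product of its singles' totals; the switch ratio between two mutants is the
ratio of their Ki fold changes across two targets; and the double-mutant
cycle coupling energy is `ddG_int = -RT ln(S_AB / (S_A * S_B))` with
R = 1.987e-3 kcal/(mol K) and T = 298.15 K by default. The sign convention
makes negative ddG_int mean cooperatively enhanced selectivity; both the
temperature and the convention are arguments because conventions differ
between labs.

## Synthetic-data generator

The library generator draws a roster of loop-saturating single mutants (all
19 substitutions at each of the seven mutagenized loop positions) plus a
configurable number of random loop doubles (default 150), with lognormal
naive abundances (log-sd 0.5; the parent scaffold weighted 20-fold, as
parents dominate real naive libraries). Per-target selection weights are
multiplicative over per-substitution effects drawn lognormally with log-sd
0.6 — interface mutations span large free-energy ranges, but the FACS gate
responds to binding signal, which the saturating binding isotherm at fixed
protease concentration compresses relative to free energy. Sorting is
modeled at the cell level: cells multinomial in abundance, each cell's gate
signal is the log selection weight plus Gaussian display noise with sd 1.15
(roughly the order-of-magnitude expression spread familiar from
yeast-display cytometry), and the top `gate_fraction` (default 5%) of cells
is kept deterministically. Sequencing draws reads multinomially (default
depth 1e5) from the naive and gated compositions, fragments each variant's
ORF into a 2x120-nt overlapping read pair, applies uniform per-base
substitution errors (default 1e-3), and assigns a two-segment quality
profile (Q38 plateau over the first 70% of cycles, sagging to Q30). A fixed
seed yields byte-identical FASTQ. The truth table records each variant's
selection weight normalized by the abundance-weighted mean weight — the
expected enrichment under proportional selection and a rank-faithful proxy
under the top-fraction gate.

Not emulated: PCR amplification bias, indel sequencing errors, chimeras,
protease-concentration titration effects on gate occupancy (abstracted into
the selection weights), and cell-sorting coincidence effects. Passing
end-to-end tests therefore demonstrates that the analysis recovers the
assumed generative structure, not that real libraries satisfy it.

The kinetics generator produces progress curves from the same slow-binding
model the fitter assumes (Morrison steady states; `kobs = koff(1 + I/Ki_app)`
with koff = 2e-3 1/s; 61 time points over 3600 s; default titration
[0, 0.25, 0.5, 1, 2, 4, 8] x (E + Ki_app) with E defaulting to the true Ki,
i.e. the tight-binding regime), plus Gaussian noise scaled to each curve's
signal range. Model mismatch between assay and fit is deliberately absent.

## Validation problem sizes

The package's own validation runs use: a 284-variant roster (133 singles,
150 doubles, parent) at sequencing depth 1e5 and error rate 1e-3 for the
end-to-end sort, which recovers the ground-truth enrichment ranking with
Spearman rho ~ 0.94 and classifies a constructed hot spot (all
substitutions at position 15 halving the selection weight) correctly; and
50-replicate Ki recovery studies at 1% noise over Ki in {1, 10, 100, 1000}
pM, with median relative error ~1–4%. `scripts/acceptance.py` recomputes
all of these from scratch.

## Limitations

The originating screen's own sequencing-derived numbers cannot be recomputed
here: no raw sequencing data are deposited, so the published per-variant
enrichment ratios, the 95% read-pass rate, and the 3.5-million-variant
library composition are out of reach at desk scale and are covered instead
by the property-based suites on simulated data. Printed selectivity values
derived from unrounded enrichment ratios reproduce only to order of
magnitude from their rounded published inputs. Two rows of the published Ki
tables are internally inconsistent with the printed constants (a switch
ratio printed as 5.7 where the printed Ki give ~6.0 for the fold change and
direction-dependent ratios, and one single-mutant selectivity printed as
0.30 that recomputes to ~0.19); the package always reports values computed
from its inputs and does not special-case those rows. Structural
rationalization of selectivity changes is out of scope.
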