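# Methods

## The model

`pedphase` phases unordered biallelic genotypes in multi-generational
pedigrees with a *local* hidden Markov model.  Each analysis centres on one
focus individual together with its parents and grandparents.  The hidden
state at a marker is the inheritance vector of this local pedigree: one bit
per tracked meiosis giving which strand of the transmitting ancestor was
passed on at that locus.  The two-generation model tracks the two meioses
that formed the focus individual (4 states); the default three-generation
model also tracks the four meioses that formed its parents (64 states) —
the phase of alleles that were *not* transmitted must be carried along to
model transitions correctly.  A four-generation model would have 2^14 =
16,384 states and is supported only as a count query.

Transitions are recombination events.  Each meiosis bit flips independently
between adjacent markers with probability given by the Haldane map function
r = (1 − e^(−2d))/2 of the interval's map distance d (Morgans), so the full
transition matrix is a Kronecker product of 2×2 kernels and never needs to
be treated as a dense, unstructured matrix.  Meioses into ancestors absent
from the pedigree are untracked: they get memoryless (r = 1/2) kernels and
contribute no emission constraints, and marginalise out exactly.  For this
reason a context whose grandparents are all unknown is evaluated in the
4-state model, which is mathematically identical there and 16× smaller.

Phase itself is parameterised by a *skewness* value s ∈ [0,1] per
individual per marker: the probability that the ordered realisation of the
unordered genotype {A,B} (A ≤ B) is BA, i.e. that strand 0 carries the
larger allele.  s = 0.5 is order-neutral; 0 and 1 are the two fully phased
states.  The emission probability of a state sums, over the ordered
realisations of every member (weighted by their skewness), the product of
allele-consistency factors along the six meioses; contradictions contribute
a mismatch floor ε (default 10⁻⁶, settable to 0 for guaranteed-clean data)
and missing genotypes contribute a factor of exactly 1.  Because strand
labelling is not tied to parental origin, the model is evaluated under all
8 *shift* combinations (which strand of the focus, sire and dam is the
paternal one) and marginalised; alternatives whose running likelihood falls
below 10⁻⁸ of the best can be truncated beam-style after the first 10% of
markers.  When the downstream-inversion scan is active, the backward pass
is always computed for all shifts: the scan recombines each shift with its
strand-relabel partner, whose backward tables are needed even if its own
total likelihood is negligible.

## Training

Skewness values start at 0.5 everywhere except one *anchor* — the first
heterozygote per individual per chromosome, fixed at exactly 0.0 to break
the strand-labelling symmetry.  Each iteration has two phases.

*Analysis.*  Every focus individual's local HMM is evaluated with the
current table.  Each member receives a vote: the deviation between its
posterior BA-order probability q and its current value p at every
heterozygous marker.  Votes are recorded on the log-odds scale
(logit q − logit p), so several independent analyses of the same parameter
combine the way independent likelihood evidence should: a cell seen
confidently by seven meioses and contradicted by one (a genuine crossover
elsewhere) resolves to near-certainty for the majority instead of the 7:1
*average*, which would leave the cell permanently semi-phased.  A
skewness-agnostic analysis (q = p) contributes exactly zero either way.
Votes to grandparents are divided by the number of (half-)siblings sharing
the connecting parent: all those siblings merely re-observe the single
meiosis that formed that parent, and unscaled they would bias ancestors
toward the allele arrangements of their most prolific descendants.

*Update.*  Summed votes are applied through a clamp that limits each
parameter's step to |p − p′| ≤ p(1−p)·min(1/(0.5+(1−p)), 1/(0.5+p)) — at
most a factor-3 change of the odds p/(1−p) per iteration from 0.5, so a
value starting at 0.5 is confined to [0.25, 0.75] after one iteration.
Anchors never move.  Convergence is declared when the per-individual,
per-chromosome sum of absolute changes falls below 10⁻³ (default), or at 25
iterations.  Votes are fully accumulated before any update, so results are
independent of context evaluation order; chromosomes are linkage-
independent and can be trained in parallel with bit-identical results.

*Inversion.*  Whole-chromosome phasing from a single anchor is fragile:
distant regions can converge to internally consistent but mutually flipped
orientations ("knots").  The scan therefore scores, for every individual
and marker, complementing all of that individual's skewness values strictly
downstream — computable from the cached forward/backward tables because the
flip is equivalent to complementing the state bits (and shift bits) that
reference that member's strands from that marker on.  Scores are summed
over all analyses containing the individual, with grandparent-role
contributions scaled by the same 1/(siblings) factor as votes: every
grandchild context re-tracks the one meiosis that formed the connecting
parent, and an unweighted sum double-counts crossovers observed there,
enough to veto correct inversions and trigger wrong ones.  Within an
iteration, accepted inversions are serialised greedily by score: at most
one per individual, never two individuals sharing an analysis pedigree
(their scores assume the other's table fixed; simultaneous flips cancel and
oscillate), and an accepted inversion blocks the individual for one further
iteration.  Inversions are applied before the vote update of the same
iteration, with the pending votes of complemented cells negated (a strand
relabelling flips the sign of a deviation) — this makes the ordering of the
two steps mathematically irrelevant.  If an anchor lies downstream of an
accepted inversion, the whole chromosome is re-complemented (likelihood-
invariant) so the anchor stays 0.  If, after 5 iterations, an individual's
entire chromosome is still within [0.45, 0.55], its anchor is assumed
uninformative and moved to the next heterozygote.

*Hardening.*  Heterozygous sites with p ≤ t are ordered AB, p ≥ 1−t BA,
anything else left unphased.  The default t = 0.5 phases every site the
training leaned on at all — the method is designed to converge in all
positions, and leaving slow-moving sites open only recategorises them from
"phased by the posterior's lean" to "unphased"; t = 0.1 (9:1 odds) is the
conservative alternative.

## Synthetic crosses

The generator gene-drops a livestock-style mapping population: by default
20 founders (5 sires × 3 dams each), 5 generations, 8 offspring per mating,
2 chromosomes × 100 SNPs at uniform 1 cM spacing (1 cM/Mbp), founder
alleles i.i.d. Bernoulli(0.5) per strand, and clean genotypes.  These
defaults are a reduced-scale stand-in for the dense populations the method
targets (thousands of individuals over 5 generations from ~20 founders,
~10,000 SNPs over a handful of ~100 Mbp chromosomes).  Crossovers are independent
per-interval Bernoulli draws with Haldane fractions — no interference,
matching the HMM's own transition assumption — and every gamete mosaic and
breakpoint is recorded as ground truth.  Founder haplotypes carry no
linkage disequilibrium (irrelevant to the linkage-driven mechanism being
tested); a hook accepts externally supplied founder haplotypes.  Breeders
for generations 3+ are drawn from distinct broods with disjoint parents, so
no analysis pedigree contains the same ancestor twice (the emission model
treats members as distinct individuals).

What passing tests on these crosses do *not* show: robustness to genotyping
error and missingness at realistic rates (supported via ε and the wildcard
emissions, but not stress-tested), founder LD, sex-specific maps, or
genotype densities far from ~1 marker/cM.

## Evaluation

Inferred strand labels are arbitrary per individual-chromosome, so accuracy
is scored under the better of the two global orientations.  The headline
number is the fraction of heterozygous loci whose ordered pair matches
truth (unphased sites count as incorrect); an all-marker variant (trivially
correct homozygotes in the denominator) is also reported, as published
accuracies are often quoted that way, together with per-generation
breakdowns, perfectly phased individual fractions, and switch errors.

## Numerical choices and limitations

* Forward/backward variables are rescaled per locus; per-shift log-scale
  accumulators make likelihoods comparable across shifts and usable by the
  inversion scan.
* The per-interval transition matrices used in the hot loop are assembled
  once per chromosome and tracking pattern as Kronecker products of the 2×2
  meiosis kernels and shared across contexts; the factorized per-bit
  application is kept and tested to agree to 10⁻¹².
* Ties are broken deterministically everywhere (stable sorts, fixed member
  and context order), so training is exactly reproducible and
  serial/parallel runs agree bit-for-bit.
* Training maximises a *composite* likelihood: each local analysis
  conditions on point estimates of relatives' parameters, and the same
  physical meiosis is observed by several analyses.  The vote and
  inversion-score scalings remove the leading double-counting bias, but the
  objective is still not a single joint likelihood, and its total over
  analyses may dip transiently after an accepted inversion even when the
  inversion is correct.
* At reduced scale, phase information can be *exactly* balanced: a founder
  whose heterozygous blocks are separated by a homozygous gap, with equally
  many transmitting meioses recombined and unrecombined across that gap,
  has a likelihood-flat tail orientation that no method can recover.  Such
  ties are rare but real at 8 offspring per mating and 1 cM spacing; they
  are the reason a given seed may fall just short of perfect founder
  accuracy, and they vanish at full-scale marker densities and family
  sizes.
* With the factor-3 clamp, a cell whose evidence saturates at iteration k
  reaches residual 1−p ≈ 3^−(t−k) at iteration t.  Summed over ~50
  heterozygotes, the 10⁻³ convergence tolerance is therefore reachable only
  after ~12+ iterations even in the best case; runs stopped at 10
  iterations (as in the reported study protocol) are "pseudo-asymptotic":
  their hardened output is essentially final even though the formal
  tolerance has not yet been met.

## Design choices that were genuinely open

* *Vote scale.*  Deviations could be summed on the probability scale or the
  log-odds scale.  The log-odds default treats separate analyses as
  independent likelihood evidence; the probability-scale "sum" and "mean"
  modes are kept selectable because they reproduce the plainest reading of
  a deviation-voting scheme.
* *Inversion governance.*  How aggressively to accept inversions is not
  dictated by the model.  The greedy serialised acceptance with neighbour
  exclusion and doubling cooldown was chosen after observing that
  simultaneous flips of coupled relatives cancel and cycle; the threshold
  (0.5 log-units) and per-individual limit (one per iteration) are the
  mildest settings that were stable.
* *Emission factorisation.*  The product form over pedigree members (each
  member's realisation weighted by its skewness, consistency enforced per
  meiosis with floor ε) is validated against an independent enumeration
  oracle, not against any external implementation.
* *Hardening protocol.*  Rounding (threshold 0.5) versus confidence
  thresholds, discussed above.
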