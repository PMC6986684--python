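# Methods

## Copy number from read depth

A library's expected single-copy coverage is E = B/G, where B is the total
number of aligned bases and G the genome size. For a locus spanning L bases
with per-base depths d₁…d_L, the CN estimate is (Σdᵢ/L)/E. With reads
drawn uniformly, the depth at a position inside a region present in c
copies is approximately Poisson(cE), so the estimator is unbiased with
variance c/(LE): at E = 20 and L = 1600 the standard error is below 0.02
even at c = 10, which is why the cohort-level mean absolute error on
synthetic data is ~0.01. Real data add mappability, GC and duplication
biases that this model does not capture (see *Limitations*).

Conventions. Depth records are 1-based (the `samtools depth` dialect);
regions are 0-based half-open (BED); conversion happens exactly once, when
a region is intersected with a profile. Positions missing from a depth file
count as depth 0, because standard depth emitters omit zero rows. B is
taken from the sample sheet, one number per library — alignment itself is
out of scope. G defaults to 818 Mb (female genome size) and is settable
per sample (843 Mb for males); the CN estimate scales linearly in G, so a
mis-sexed sample is off by ~3%. CN values are reported as continuous
numbers, never rounded: the downstream statistics operate on scaled depth.

The collapsed-reference mode interprets the same statistic, computed on a
profile aligned against a reference retaining a single family member, as
the *total* family CN, because reads from all near-identical paralogs
co-map onto the representative. Whether the profile was actually produced
that way is the caller's responsibility — nothing in a depth file records
it.

## Paralog-family sequence characterization

Genetic distance defaults to the p-distance with a Jukes–Cantor option
(−(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4); which correction a given
desktop phylogenetics package applies by default varies, so the choice is a
named parameter rather than an assertion. Codons containing gaps or N in
either sequence are dropped pairwise before any counting.

dN/dS follows the Nei–Gojobori counting scheme. Each codon position
contributes a synonymous-site fraction computed from the standard genetic
code; per codon the synonymous and nonsynonymous site counts sum to 3.
Codon pairs differing at k ≤ 3 positions are resolved by enumerating all k!
minimal mutational pathways and averaging their synonymous/nonsynonymous
step counts with equal weight. Two conventions govern stop codons, both
following SNAP's documented behaviour and both switchable
(`count_stops=True` reverts to plain all-pathway counting): mutations *to*
stop codons are excluded from site-fraction denominators, and pathways
passing *through* a stop are excluded from the average (falling back to all
pathways when every one is blocked). pS = Sd/S and pN = Nd/N are
JC-corrected to dS and dN; a saturated proportion (≥ 3/4) yields NaN, and
dN/dS is reported as undefined — neither 0 nor ∞ — whenever dS is 0 or
either distance is undefined.

Truncation scanning walks in-frame codons from the declared frame offset
and records every TAA/TAG/TGA; a sequence is truncated iff a stop occurs
strictly before its last complete codon. A trailing partial codon is
ignored.

The neighbor-joining utility delegates to scikit-bio's NJ with negative
branch lengths clamped to zero, giving deterministic output; on additive
matrices tip-to-tip path lengths reproduce the input exactly. It is
plumbing for visual inspection of family structure, not a substitute for
maximum-likelihood inference.

## Group statistics

One-way ANOVA per paralog is computed from sums of squares (F = MSB/MSW,
df = (k−1, n−k)) with p from the F distribution; samples with lineage
"unassigned" are excluded, since the comparison of interest is among the
three named lineages. Group means *and* medians are reported. The post hoc
procedure is fixed to Tukey HSD in its Tukey–Kramer form for unequal group
sizes (q = |Δ|/√(MSW(1/nᵢ + 1/nⱼ)/2), p from the studentized-range
distribution); with two groups it collapses exactly to the ANOVA p.
Cultivars sequenced twice are compared with a paired t-test across
paralogs; three or more libraries use a one-way ANOVA with libraries as
groups. No correction is applied across per-paralog tests by default;
Benjamini–Hochberg is available behind a flag, off by default, because a
battery of ~11 related tests is conventionally presented uncorrected in
this setting and the flag makes the alternative explicit.

Degenerate inputs (zero within-group variance, singleton groups) raise
typed errors at the single-test level; the batch table reports them as NaN
rows with a note instead of aborting the whole run.

## Phylogenetic GLS

Relatedness is modelled as pure Brownian motion: V_ij is the depth of the
most recent common ancestor of tips i and j. Whether a Pagel's-λ or
Ornstein–Uhlenbeck structure would fit cultivar panels better is an open
question; pure BM is the minimal standard choice and is stated as an
assumption, not a finding. The GLS fit whitens through the Cholesky factor
of V; β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with an intercept column, σ̂² from the
whitened residuals with n−2 df, two-sided p from the t distribution. The
reported correlation coefficient is the sign-preserving square root of the
GLS R² measured against the GLS-weighted-mean-only model, so V = I
reproduces the ordinary Pearson r exactly. If the Cholesky factorization
fails, one ridge of 1e-10 × trace(V) is added with a logged warning;
failure after that raises a conditioning error rather than silently
regularizing harder.

Association tables report the corrected statistics next to the uncorrected
Pearson r/p on the identical matched samples — the contrast between the
two columns is itself a result (clade-level co-variation that vanishes
under correction indicates relatedness confounding, the failure mode the
two-clade fixture demonstrates).

Chemotype matching prefers a per-sample ("individual") measurement and
falls back to the mean of cultivar-level averages; the provenance of each
value is retained. Totals per cannabinoid follow the decarboxylation rule
total = neutral + f × acid with f defaulting to 0.877, the molar-mass
fraction retained when the acidic form loses CO₂ (e.g. THC 314.5 / THCA
358.5); f is configurable per run because labs differ in whether they
report fully decarboxylated equivalents.

## Expression

FPKM = count × 10⁹/(length_bp × library_size), which satisfies the mass
identity Σᵢ FPKMᵢ·lengthᵢ(kb) = 10⁶ × (assigned fraction of the library).
Pairwise log2 fold changes apply a 0.1-FPKM pseudocount only when either
side is zero, with a companion flag column, and the pseudocount is echoed
in the report header. The significance column is deliberately empty:
dispersion-based differential-expression testing requires replicate-aware
machinery that is out of scope, and carrying the column preserves the
conventional report layout.

## Synthetic data

The generators emulate the *statistical* structure the analysis assumes,
not the sequencing process: no read-level simulation, no mapping ambiguity
between near-identical paralogs, no sequencing-error or GC-bias model.
Passing tests therefore demonstrate correctness of the estimators and
statistics under their stated models — they do not certify robustness to
real-data artifacts such as cross-mapping between diverged paralogs or
reference mis-assembly.

Defaults describe a realistic resequencing study of this kind: 67
libraries in lineages of 15 (broad-leaf), 31 (narrow-leaf), 16 (hemp) and
5 unassigned; 11 paralog regions of 1.6 kb; planted integer CN uniform on
1–10; expected coverage 20×; two libraries per cultivar so
replicate-cultivar tests have material. Depth is Poisson per base
(`noise="none"` gives exact means). Trees are Yule (pure birth); because
the simulator stops exactly at the n-th birth (leaving the newest sister
pair with zero-length terminal edges and a singular BM covariance), all
terminal branches are extended by the Exponential(nλ) waiting time to the
next, unobserved, birth — the correct conditioning for a Yule tree
observed between births. Traits co-evolve as x ~ BM(σ²) and
y = intercept + slope·x + BM residual + iid residual (defaults: slope 1.5,
intercept 1, both σ = 1, iid 0 — the slope-recovery and CI-coverage checks
require a purely phylogenetic residual, and a nonzero iid term is available
to study misspecification). Codon pairs diverge by logged single-nucleotide
substitutions; proposals creating stops are rejected, and nonsynonymous
proposals are accepted with probability min(1, ω) (roles flipping for
ω > 1), steering the realized class mix toward the target dN/dS.
Truncations are planted by overwriting stated codons with TAA after
divergence, and every change is logged to a truth table.

Determinism: every generator is a pure function of (scenario, seed). One
global seed fans out to fixed per-generator child streams
(`default_rng((seed, offset))`), so adding a generator never perturbs the
draws of an existing one, and rerunning a scenario is byte-identical.

The two-clade confounding fixture is a fixed dataset (default
construction, seed 7): two clades of 8 tips behind internal branches of
length 10, predictor and response offset between clades (2 vs 8 and 1 vs
9) but drawn independently within clades (σ = 0.5), so the within-clade
slope is zero by construction. The naive correlation across all 16 tips is
strongly significant; the BM-corrected one is not.

## Problem sizes and numerical choices

The acceptance computations use one 67-sample cohort (11 regions × 1.6 kb)
for the CN error, 200 replicate regions for the bias check, 500 Brownian
simulations on 50-tip Yule trees for slope recovery and CI coverage, 2,000
null PGLS replicates and 5,000 null ANOVA replicates for type-I rates, and
the full enumeration of the 2,155 non-stop codon pairs within two
differences for the counting oracle — sizes at which the Monte-Carlo
standard errors are comfortably below the tolerances being checked.
Tie-breaks and degenerate cases: NJ joins are deterministic; ANOVA/Tukey
raise on zero variance; PGLS raises below n = 3; p-values are clamped to
[0, 1]; the JC correction and the dN/dS ratio go to NaN/undefined at their
domain boundaries instead of extrapolating.

## Limitations

* CN estimates inherit every bias of raw depth: mappability, GC content,
  library duplication, and reference completeness are uncorrected, and
  segmentation-based CNV calling is out of scope.
* Near-identical paralogs cannot be distinguished at the read level; the
  per-locus estimates assume reads map to their locus of origin, which the
  collapsed-reference mode deliberately relaxes in the other direction.
* The BM covariance treats the input tree as known and error-free.
* The counting dN/dS has no transition/transversion or codon-frequency
  weighting (the equal-pathway NG form); likelihood codon models are out
  of scope.
* The expression report carries no significance testing.
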