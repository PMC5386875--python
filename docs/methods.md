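# Methods

## Scope and model

`codonselect` re-implements, as a tested library, the comparative
molecular-evolution workflow used to study high-altitude adaptation in
Schizothoracine fishes: per-branch dN/dS estimation under a codon
substitution model, branch-site tests for positive selection with FDR
control, fourfold-degenerate-site extraction and supergene concatenation,
GO-category rate-shift screening, and enrichment/overlap reporting.  A
codon simulator generates ortholog sets with known selection regimes so
every stage can be validated without the original transcriptome data.

### Codon substitution model

The substitution process is a Goldman–Yang-style Markov chain on the 61
sense codons of the universal code (stop codons are excluded from the
state space, the codeml convention).  Instantaneous rates are zero for
multi-nucleotide changes and otherwise

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

with the diagonal closing rows to zero.  The chain is time-reversible with
stationary distribution `pi`.  Each branch's generator (or, under
mixtures, generator set) is rescaled so branch length *t* is the expected
number of substitutions per codon, mixture-weighted over site classes on
that branch; the simulator uses exactly the same scaling, so simulated and
inferred branch lengths share units.

Codon frequencies default to F3x4 (position-specific nucleotide
frequencies estimated from the alignment, with a pseudocount of 1 per
nucleotide per position to keep frequencies positive on short genes);
uniform frequencies are available and are the simulator default.

### Likelihood and optimisation

Likelihoods come from Felsenstein pruning on site patterns (unique codon
columns with multiplicities).  Gapped or ambiguous codons contribute
all-ones partial likelihoods (missing data); columns are never deleted.
Transition matrices are computed by eigendecomposition of the symmetrised
reversible generator (`diag(sqrt(pi)) Q diag(1/sqrt(pi))`), verified
against `scipy.linalg.expm` to 1e-10.  Because quasi-Newton optimisation
with finite-difference gradients mostly perturbs branch lengths,
eigensystems are cached by (kappa, omega) within each fit; this is the
dominant performance lever.

All fits (M0 one-ratio, free-ratio, branch-site A null and alternative)
estimate branch lengths jointly with the model parameters — branch lengths
are not reused across models — by bounded L-BFGS-B on transformed
parameters with bounds omega in [1e-4, 999], kappa in [0.01, 100], t in
[1e-6, 50] (the codeml bounds).  A single-ratio fit on a multinomial
subsample of sites (<= 500) provides starting values; the branch-site
alternative starts from the null optimum, with optional extra starts at
omega2 near 1 and at a larger value to guard against the boundary local
optimum (`restarts`; the library default is 2: one start at omega2 = 2 and
one at 1.02; large scans use `restarts=1`, which reproduced identical null
calibration in our checks).  Convergence uses relative lnL change < 1e-9
and projected-gradient norm < 1e-6; non-converged genes are flagged and
excluded from PSG calling.  If the alternative ends below the null, it is
restarted from the null parameters with omega2 -> 1 and the LRT statistic
is clamped at zero.

### dN/dS bookkeeping

Reported per-branch quantities mirror a codeml free-ratio table: t, omega,
N, S, dN, dS.  `N` and `S` are model-based mutational opportunities,
`3L * rho`, where `rho` are the neutral (omega = 1) nonsynonymous and
synonymous equilibrium flux fractions under the fitted kappa and pi; the
expected substitution counts on a branch are `t * f(omega) * L` split by
the fitted generator's flux.  Under this normalisation `dN/dS == omega`
identically, and `N + S = 3L`.  `count_sites` additionally provides the
classical per-codon kappa-weighted enumeration (changes to stops excluded,
usage-averaged); the two definitions differ by a few percent because the
enumeration normalises per codon rather than over the equilibrium flux.

### Branch-site test

Branch-site model A: classes 0 (omega0 < 1 everywhere), 1 (neutral
everywhere), 2a/2b (omega2 >= 1 on the tagged foreground branches,
omega0/1 on background), with the positive-selection mass split
p2a : p2b = p0 : p1.  The null fixes omega2 = 1.  The LRT is referred to
chi-square(1), which is conservative relative to the 50:50 boundary
mixture; `lrt_pvalue(..., null="mixture")` provides the mixture reference.
PSGs are genes with Benjamini–Hochberg q < 0.05 across converged fits.
Bayes-Empirical-Bayes site identification is out of scope.

### Fourfold-degenerate sites

The eight fourfold families are derived from the code itself (a
two-nucleotide prefix whose four completions are synonymous): CTN, GTN,
TCN, CCN, ACN, GCN, CGN, GGN.  A codon column yields a 4D site only when
every taxon is ungapped and unambiguous and all taxa share the identical
family prefix — the strict reading under which any third-position change
is guaranteed synonymous.  Columns with `N` or `-` are excluded rather
than imputed.  (Published family lists sometimes mislabel GCN; deriving
from the code avoids transcription errors.)

### Gene filters and lineage statistics

Genes are dropped on a branch when `N*dN < 1` or `S*dS < 1` (too little
signal) or `dS > 1` (saturation); the alignment-length filter keeps
trimmed alignments strictly longer than 150 nt.  Lineage dN/dS
distributions are compared with the Wilcoxon rank-sum test (exact
enumeration when both n <= 10 and no cross-group ties, otherwise the
normal approximation with continuity and tie corrections).

GO categories with at least 30 member orthologs are concatenated into
per-category supergenes, refit under the free-ratio model, and branch X is
tested against branch Y by an exact binomial: the null proportion is Y's
nonsynonymous substitution fraction, and X's expected counts (rounded to
integers) give upper/lower tail p-values for elevation/deceleration at
p < 0.05, unadjusted, as in the original screening.  A likelihood-ratio
variant on unrounded counts is available (`method="lr"`).

**Known property:** the binomial treats the null proportion as exact.
When Y is a lineage-wide reference (the design the consortium procedure
was built for) the test is near-nominal and slightly conservative after
rounding; when X and Y are same-scale branches of the same category
supergene, ignoring Y's sampling noise makes the test anticonservative
(measured size ~0.18 at ~1e3-substitution scale in count-level
simulation).  Screens comparing same-scale branches should be read as
ranking, not calibrated inference.

### Reporting

PSG enrichment uses the one-sided hypergeometric upper tail per term with
BH adjustment across tested terms; the background is the set of genes that
entered branch-site testing, and only terms containing a configurable
minimum number of PSGs (default 1; the study's plots used 3) are tested.
Set overlaps are exact partitions; named-list intersection matches gene
symbols case-insensitively.  PPI degree filtering counts a seed's degree
in the full network (an induced-subgraph option exists) and keeps seeds
with strictly more than `min_degree` interactions.

## Simulator

The generative model is the inference model's exact twin: root codons are
drawn from pi and each branch evolves sites by `exp(Q t)` with that
branch's (class-specific) omega, sampled per site via inverse-CDF on the
transition rows.  Stop codons cannot occur; indels are not simulated, but
random codon cells can be masked to gaps (`gap_fraction`) to exercise
missing-data handling.  Each gene uses the random substream
`(scenario_seed, gene_index)`, so gene sets are reproducible under
reordering.

### Study conditions

The default six-taxon topology mirrors the study:
`(((G_dobula, P_kaznakovi)A, (S_gongshanensis, S_prenanti)B)C, C_idella,
D_rerio)` — highland pair under node A, subhighland pair under node B,
Schizothoracine ancestor at node C, unrooted-style root (nine identifiable
branches).  Baseline omegas are 0.3 on the Schizothoracine branches and
0.16 on the lowland branches (the study's lineage contrast).  Branch
lengths are not published in substitution units (the original tree is
dated in MYA), so they are package conditions: 0.35 substitutions/codon on
Schizothoracine tips and stems, 0.40 on the C stem, 0.50/0.70 on the
lowland tips, i.e. dS roughly 0.25-0.5 per branch.  They were chosen by a
power analysis so each branch's omega is estimable to better than +-0.05
from a 5000-codon supergene with a >=3.5-sigma margin (per-branch ML
error sd ~0.02); shorter, younger-looking branches make per-branch omega
recovery at that precision statistically fragile.

Branch-site genes default to p0 = 0.55, p1 = 0.2 (25% of sites in the
positive classes) with omega2 = 6 on the highland tips — a strong but
plausible selective signature chosen so that genes of 100-250 codons are
detectable; GO elevation defaults to doubling omega on branch A for
designated disjoint 30-gene terms.

### What the simulator does not emulate

Alignment and assembly error, paralogy, indel placement, codon-usage
heterogeneity along genes, rate variation beyond the modelled site
classes, and non-equilibrium base composition.  Passing tests therefore
demonstrate correctness and calibration of the estimators under the
model's own assumptions, not robustness to real-data violations of them.

## Problem sizes in the test suite

The suite runs the study-scale checks at desk scale: supergene recovery
uses 5000-codon alignments with the recovered omega per branch taken as
the median over 3 replicate simulations (single-fit ML noise is ~0.02-0.03
sd per branch); branch-site calibration uses 100 null and 24 positive
replicates; the end-to-end run simulates 300 genes (10 elevated 30-gene GO
terms, 20 branch-site positives) and checks >=80% category recovery,
PSG recall >= 0.7 and observed FDR <= 0.1.  The reproduction script
(`scripts/acceptance.py`) runs the same stages at a smaller scale chosen
to finish in minutes.

## Known limitations

- Only GY-style models: no MG94/FMutSel, no site models (M1a/M2a/M7/M8),
  no BEB site identification.
- chi-square(1) vs the boundary mixture for the LRT is a documented
  switch; the default is the conservative choice.
- The binomial rate-shift screen is uncalibrated for same-scale branch
  pairs (see above).
- Expected substitution counts are rounded for the exact binomial; the
  unrounded LR variant is behind a flag.
- Degree-2 roots are unidentifiable under reversible models; fits expect
  unrooted-style trees (`Phylogeny.unroot()` collapses a rooted pair).
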