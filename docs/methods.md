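# Methods

This note documents the models and procedures implemented in `plastosig`,
the default parameter choices and why they were made, what the synthetic
data emulate (and do not), and the package's known limitations.

## Substitution model

The engine implements GTR+I+Γ<sub>K</sub>. The instantaneous rate matrix
has off-diagonals q<sub>ij</sub> = r<sub>ij</sub>·π<sub>j</sub> built from
six exchangeabilities (GT fixed to 1 for identifiability) and stationary
frequencies π; time-reversibility π<sub>i</sub>q<sub>ij</sub> =
π<sub>j</sub>q<sub>ji</sub> holds by construction. Among-site rate
variation is the usual mixture of a proportion p_inv of invariant sites
and K equal-probability discrete gamma categories (default K = 4) with
shape α, using the *mean-category* discretisation: category k's rate is
the conditional mean of Gamma(α, α) over its quantile slab, computed in
closed form from the incomplete-gamma identity ∫₀ˣ t·g_α(t)dt =
F_{α+1}(x). Mean rates therefore average exactly 1.

**Branch-length units.** Q is scaled so the expected rate over the whole
mixture is one substitution per site per unit branch length:
−Σ π<sub>i</sub>q<sub>ii</sub> = 1/(1−p_inv). This matches the convention
of mainstream ML software, so branch lengths remain comparable when
p_inv changes.

P(t) is computed by symmetrising Q with D = diag(√π) and
eigendecomposing once per model; a fitted topology requires thousands of
P(t) evaluations and this makes each one a pair of 4×4 multiplications.

## Likelihood engine

Felsenstein pruning with:

* **pattern compression** — identical site columns are collapsed and
  weighted; on low-divergence plastome-like data this reduces the site
  dimension by one to two orders of magnitude;
* **per-pattern log scaling** of partial likelihoods in every category,
  so arbitrarily large trees/low likelihoods cannot underflow;
* **ambiguity handling** — IUPAC codes contribute a partial likelihood of
  1 over their compatible states; `-`, `?`, `N` and `X` are equivalent to
  full ambiguity in the likelihood (masking treats only `-` as a gap);
* **invariant class** — L(site) = p_inv·I(site) + (1−p_inv)·(1/K)Σ_k
  L_k(site), where I(site) sums π over the states compatible with every
  taxon (zero if the site cannot be constant). All-gap sites contribute
  lnL = 0 and are logged.

The tree is stored rooted at an arbitrary node; for reversible models the
likelihood is root-invariant (pulley principle), which the tests verify
to 1e-10.

## Fixed-topology optimisation

Tree *search* is out of scope: candidate topologies are user inputs, as
in constrained ML analysis. Fitting is coordinate-wise:

* each branch in turn by bounded Brent search on log-length, using
  directed message caches (the conditional likelihoods of the two tree
  halves seen from the branch) so one-dimensional evaluations are a
  single 4×4 contraction per category;
* then α (Brent on log α ∈ [ln 0.02, ln 100]), p_inv (Brent on
  [0, 0.95]), and optionally the five free exchangeabilities (L-BFGS-B in
  log space). Base frequencies are empirical counts by default —
  reproducible and nearly indistinguishable from ML values at these data
  sizes.

Branch lengths are bounded to [1e-8, 100]. Every sub-step keeps the
previous point unless the likelihood improves, so the outer iteration is
monotone; it stops when a full pass improves lnL by less than the
tolerance (default 1e-4, max 200 passes; non-convergence returns the best
point with a warning). Fixed seeds and deterministic passes make refits
bit-reproducible.

## Per-locus signal dissection

Given site log-likelihood vectors under two fitted topologies, the locus
statistic is ΔlnL(locus) = Σ_{sites∈locus}(lnL_A − lnL_B); the sign
convention (first label minus second) is stated in every output header.
Columns outside all loci are aggregated as `_unpartitioned`, which makes
the table *exactly* conservative: locus deltas plus the remainder equal
the total lnL difference (checked to 1e-8, measured at ~1e-12).

Support classes use the conventional 2 lnL-unit yardstick with strict
inequalities: |ΔlnL| > 2 strong, 1 < |ΔlnL| ≤ 2 moderate, otherwise
weak (so a locus at exactly 2.0 is moderate). With three candidate
resolutions, all three pairwise tables are produced; a locus "supports
T<sub>x</sub>" when it beats both rivals in its pairwise deltas.

The removal experiment re-optimises every candidate topology on the
alignment with the flagged loci excluded and ranks them by total lnL.
Note this re-*scores* fixed candidates; it does not repeat a heuristic
tree search on the reduced data, which is the one deliberate departure
from how such removal experiments are sometimes run.

## Topology tests

All tests consume a topologies × sites log-likelihood matrix and use
RELL resampling (site columns resampled with replacement; totals summed,
no refitting). Default 10,000 replicates, seed mandatory and recorded.

* **KH** — two-sided by default: δ* replicates centred at their mean form
  the null, p = P(|δ*| ≥ |δ_obs|). Two-sidedness keeps the test
  symmetric in its arguments, appropriate when neither topology is
  pre-specified; the one-sided variant is available (`two_sided=False`)
  and is the quantity against which SH is provably conservative.
* **SH** — simultaneous across topologies: per-topology centred
  replicates, null statistic max_j R̃_j − R̃_t, compared to the observed
  deficit from the best topology.
* **AU** — multiscale bootstrap over scale factors r ∈ {0.5 … 1.4}
  (the conventional set): resample round(r·n) sites, track the bootstrap
  proportion BP_t(r) of each topology, fit Φ⁻¹(1−BP) = d√r + c/√r by
  weighted least squares (binomial delta-method weights), and report
  p = 1 − Φ(d − c). Degenerate proportions (all ~0 or ~1) clamp p to 0
  or 1 with a logged flag; ties with the best topology count as wins, so
  a topology identical to the best gets p = 1.

Calibration measured by the validation suite: KH type-I error 0.05–0.06
at α = 0.05 on 1500-site null matrices; SH p ≥ one-sided KH p in 100% of
random instances; AU rejects ~0.10 of null instances for the
selected-worse topology — the known mild liberality of the multiscale
bootstrap near the null, stable across replicate counts, and within
Monte-Carlo error of KH's rate at the experiment sizes used.

## Plastome structure and loci

IR detection is a seed-and-extend search (25-mer anchors, hash lookup
against the reverse complement, anti-diagonal deduplication, greedy
maximal extension) for the longest pair of reverse-complement-identical
repeats with a minimum length of 1000 bp and, by default, zero
mismatches — exact long IRs are the norm in the plastomes this package
targets; a mismatch budget is configurable. The two gaps between the
repeat copies are the single-copy regions; the longer gap is the LSC and
IRa is the copy that follows it. Detection works on the circle (repeats
may span the origin) and is deterministic for a fixed rotation; region
lengths and GC are rotation-invariant, and a rotation normaliser can
place the LSC start at coordinate 0. Coordinates are 0-based half-open
internally, 1-based inclusive only at GenBank boundaries.

Locus extraction produces coding loci (exon concatenations per gene),
introns (within-gene gaps between consecutive exons, `gene_intron` /
`gene_intron1,2`), tRNA/rRNA loci, and intergenic spacers between
adjacent gene spans, named `geneA-geneB` with A upstream. With
`ir_policy=drop_one_copy` the IRb copy is excised first, so IR genes are
kept once; the spacer across the excision junction is emitted as a
single locus joining the tail and head gaps. Gene names are matched
case-insensitively with copy suffixes stripped; the trans-spliced
`rps12` is excluded from coding extraction by default (its dispersed
pieces do not form a contiguous locus) and logged. Zero-length spacers
are skipped. On a record whose features tile without overlap, the
extracted loci sum exactly to the genome length minus one IR copy — an
identity the tests assert.

## Synthetic data

`simulate_alignment` draws root states from π, assigns each site one
rate class (invariant with probability p_inv, otherwise one of the K
gamma rates — the class is shared across all branches, matching the
likelihood model), and evolves states down the tree via P(t·rate).

The planted-conflict generator emulates the regime in which a rapid
radiation leaves a focal trichotomy with a very short internal branch,
while a small minority of loci carry a *concentrated* alternative
history (as introgression or heteroplasmic recombination would produce).
Defaults, chosen to be realistic for that regime and fixed before any
acceptance measurement:

| parameter | `laureae-like` | `reduced` |
|---|---|---|
| loci | 243 | 240 |
| planted conflict loci | 6 | 6 |
| locus lengths | log-uniform 100–3000 bp | uniform 200–400 bp |
| planted locus lengths | log-uniform 500–2000 bp | uniform 700–900 bp |
| majority focal branch | 0.002 | 0.001 |
| minority focal branch | 0.03 | 0.03 |
| terminal / stem branches | 0.004 / 0.003 | same |
| model | GTR, π AT-rich (38% GC), α=0.5, p_inv=0.2 | same |

The long minority focal branch is what concentrates discordant sites in
the planted loci; with both focal branches short and equal no method can
separate planted loci from background, because the information simply is
not in the data. The `reduced` preset is the desk-scale condition used
by the validation experiments (7 taxa, ~75 kb total).

Synthetic plastomes carry a plastome-shaped inventory (78 CDS, 30 tRNA,
4 rRNA unique genes; 13 IR-duplicated; 16 one-intron and 2 two-intron
genes), region-specific GC (IR 44%, LSC 38%, SSC 34%), and an exact
planted IR whose flanking bases are pinned so chance extension cannot
shift the true boundaries.

**What the generator does not emulate:** indels and alignment error
(alignments are simulated gap-free; masking is exercised with
constructed gaps), coalescent gene-tree variation (ILS is represented
only by topology planting), rate variation among loci beyond locus
length, base-composition heterogeneity among lineages, and real
annotation noise. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted signal under the stated
regime — not that real plastome conflicts of arbitrary origin will be
equally clean.

## Validation experiment sizes

The validation suite (and `scripts/acceptance.py`) uses: 100 random 4–6
taxon instances of ≤200 sites against the enumeration oracle; 20 seeds
of the `reduced` planted-conflict experiment; 500 null trials of 1500
sites for KH calibration (large enough that the test's asymptotic
calibration applies); 200 trials each for SH conservatism and the AU/KH
null-rate comparison. These sizes give binomial Monte-Carlo errors of
1–2 percentage points on the reported rates.

## Known limitations

* No tree search, no bootstrap support values, no partitioned joint
  models across loci, no codon models, no AIC-style model selection.
* The AU implementation is the standard two-parameter multiscale fit; it
  inherits the method's slight near-null liberality and its p-values on
  identical inputs can differ from other implementations at the third
  decimal depending on scale sets and tie handling.
* IR detection assumes a single dominant inverted-repeat pair; plastomes
  with drastically reduced or lost IRs raise a structure error rather
  than guessing.
* The branch-length optimiser is derivative-free and robust rather than
  fast; it is sized for hundreds of kilobases on a handful of taxa, not
  for hundreds of taxa.
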