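# Methods

This note documents the models and procedures implemented in `paleofoam`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Distance model

Pairwise distances are computed under the Kimura two-parameter (K2P)
model. With `P` and `Q` the observed transition and transversion
proportions over the compared sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and the variance follows Kimura's delta-method formula
(`c1 = 1/(1-2P-Q)`, `c2 = 1/(1-2Q)`, `c3 = (c1+c2)/2`,
`var = [c1²P + c3²Q - (c1P + c3Q)²]/n`). The model assumes equal base
frequencies and a single transition/transversion ratio across sites.
When the log arguments become non-positive the pair is saturated: the
estimator raises an explicit error instead of returning NaN or infinity,
so dating can never silently consume a nonsense distance.

Gap handling is pairwise deletion: any column with a gap, `N`, or other
IUPAC ambiguity code in either sequence is dropped from that pair's
comparison. Pairwise deletion is the common default for two-sequence
comparison; complete deletion would discard information in multi-copy
sets, and probabilistic resolution of ambiguity codes would make the
estimates seed-dependent. Ambiguity codes are therefore missing data,
never fractional matches.

## Invasion dating

Endogenous copies are assumed to evolve neutrally at the host rate after
integration (a strict clock). The default rate prior is the typical
mammalian neutral rate, mean 2.2e-9 substitutions/site/year, sd 0.1e-9,
used as a proxy when the host's own rate is unknown — for slowly evolving
hosts this makes the ages conservative (too young), and duplication ages
are in any case lower bounds on the invasion age.

**Pairs.** `t = d/(2r)`; the 95% interval propagates the distance
variance and the rate sd by the delta method
(`var(t) = var(d)/(2r)² + (d/2r²)²·sd²`), as a normal interval truncated
at zero. With both variances zero the interval collapses to the point.

**Sets of ≥ 3 copies.** The point estimate is the root height of a UPGMA
tree on the K2P distance matrix, divided by the rate mean. This is a
deliberate methodological substitution for a Bayesian strict-clock MCMC
(the standard tool for such datasets): a full phylogenetic sampler is out
of proportion for a desk-scale estimator, and for small intra-set
divergences (d ≤ 0.1) the UPGMA/K2P root height approximates the
clock-tree root height well. The interval is *not* an HPD: it combines
non-parametric bootstrap over alignment columns with rate draws from
Normal(mean, sd) truncated positive, taking the 2.5/97.5 percentiles of
bootstrap-age/rate ratios. Coverage of this interval is checked by
simulation (95% intervals cover a 19.3 My truth in ≥ 90% of seeded runs).

**UPGMA.** Size-weighted average linkage; node heights are half the
merge distance; equally close pairs are merged in lexicographic order of
their lowest leaf labels, so the tree is deterministic. Output is
ultrametric by construction (asserted to 1e-10 in tests). UPGMA is
written in-house because this tie-break contract is part of the
estimator's reproducibility guarantee; its heights are cross-checked
against SciPy's average-linkage clustering in the test suite.

## Consensus, defects, duplicate sets

**Consensus.** Per column of the copy alignment, the plurality non-gap
base is called if its support (fraction of non-gap characters) reaches
`min_support` (default 0.5); tied pluralities become the IUPAC code of
the tied bases, insufficient support becomes the code covering all
observed bases. Ambiguity is preferred to arbitrary tie-breaking so the
consensus records what the copies actually agree on. Columns gapped in a
majority of copies are insertions in a minority, not element sequence,
and are dropped. The result carries a per-column support vector and the
kept-column index map.

**Defect annotation.** Premature stops are TAA/TAG/TGA codons read in
frame 0 of the declared ORF span, excluding the terminal codon; on the
minus strand the span is reverse-complemented first. Frameshifts are
reported only when a pairwise alignment to an intact homolog is supplied:
indel runs whose length is not a multiple of 3. All coordinates are
0-based, half-open.

**Duplicate sets.** Two contigs join a set when either flank pair (left
with left, or right with right) aligns at identity ≥ 0.90 over ≥ 100 bp
(both configurable); grouping is single-linkage, so a set is a connected
component. The default comparison is best ungapped sliding identity
(deterministic, no alignment heuristics); a gapped local-alignment score
is available behind a flag for flanks with indels. Unrelated flanks sit
near 25% identity, far below any sensible threshold. Note the regime of
validity: flank identity falls as 2rt, so at the default threshold the
method is reliable for duplications younger than ~20 My at the mammalian
rate, and interior flank indels can break linkage earlier; the simulator
recovery tests therefore use recent duplications (< 2% flank divergence).

## Codivergence test

Congruence is assessed on rooted trees: every clade (leaf set under a
branch) of the virus tree, with tips translated through the virus→host
tip bijection, must be a clade of the host tree and vice versa.
Polytomies must match exactly — "same topology" is the precondition of
the branch pairing, and a soft polytomy cannot be paired branch-for-
branch. On failure the discordant clades are reported. On success each
shared clade pairs one host branch (duration, My) with one virus branch
(substitutions/site); for a rooted binary tree on n tips this gives 2n-2
pairs.

The regression of virus length on host duration is ordinary least
squares *with* an intercept (forcing through the origin is a stronger
assumption than the data warrant, since rooting error and basal-branch
age assignment both displace the origin; a through-origin fit is
available behind a flag). Significance is the two-sided test of zero
slope (equivalent to the F-test on 1 and n-2 df), plus an optional
permutation p-value: virus lengths are shuffled across branches
(default 10,000 times, seeded) and permutations with R² at or above the
observed value are counted with add-one correction. Branch pairs are not
phylogenetically independent — shared paths induce correlation — so the
analytic p-value is anti-conservative in principle; the permutation test
randomizes assignments under the same dependence structure and is the
one to quote when the two disagree.

**Midpoint rooting** places the root halfway along the longest
leaf-to-leaf path, computed from the path definition (all leaf pairs,
ties broken by leaf labels); a stem edge above the root is on no
leaf-to-leaf path and is ignored. Total branch length and all leaf-to-
leaf path lengths are conserved. The implementation is validated against
a brute-force all-pairs oracle on random 10-leaf trees.

**Host tree fixture.** The packaged six-host tree (coelacanth + five
foamy-virus-carrying mammals) uses approximate divergence times from
standard vertebrate timescales: coelacanth/tetrapod 407 My (earliest
coelacanth fossils), placental root 100 My, primate/laurasiatherian
split 96 My, cat/(horse,cow) 84 My, horse/cow 78 My. The basal branch
durations follow from treating the root as the 407 My split; these times
are configuration, exposed for substitution, not inferences made here.

## Synthetic data generator

The simulator produces data under exactly the assumptions the estimators
make, which is what makes recovery tests meaningful and also bounds what
they show.

* **Substitutions** follow the K2P process with configurable
  transition/transversion rate ratio kappa (default 2.0, a typical
  nuclear-genome value). Site independence, no rate heterogeneity across
  sites, equal base frequencies. Expected distance after time t is
  exactly `rate × t` (the closed-form transition probabilities are used,
  not a small-rt approximation).
* **Codivergence** clones the host topology; each virus branch length is
  `viral_rate × duration × m` with `m` a lognormal multiplier of mean 1
  and log-sd `rate_noise_sd` (0 = strict clock; the lognormal is the
  standard relaxed-clock-style perturbation). Branch lengths are set to
  these values exactly and tip sequences are then evolved along them, so
  with zero noise the branch-length regression is exactly linear
  (R² = 1 to numerical tolerance) while sequence-estimated distances
  scatter realistically.
* **Endogenization** inserts a provirus carrying one intact ORF between
  random host flanks, decays all copies at the host rate, duplicates the
  whole locus (flanks included) at the configured times, and cuts each
  copy into overlapping fragments (uniform breakpoints, minimum contig
  300 bp, 100 bp overlap). Indels are Poisson events at `indel_rate`
  (default 2e-11 events/site/year — a few events per copy over tens of
  My, enough to produce frameshifts; not calibrated to any measured
  genome) with geometric(0.5) lengths capped at 10 bp, equally likely
  insertion or deletion. All copies share one column space, so the
  emitted locus alignment is the true alignment and the truth file
  (ages, copy genealogy, per-copy stop/frameshift counts, duplicate-set
  membership, fragment coordinates) is exact by construction.

What the generator does **not** emulate: rate variation across sites or
lineages (beyond the codivergence noise knob), selection on residual
ORFs, recombination and gene conversion between copies, CpG
hypermutability, sequencing error, and realistic WGS assembly artifacts.
Passing recovery tests therefore demonstrate correctness of the
estimators under their own model, not robustness to these violations —
on real data the K2P/strict-clock assumptions are the dominant source of
unmodeled error, and ages should be read as order-of-magnitude lower
bounds.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere, including sidecar tables.
* Saturation, invalid spans, non-bijective tip maps and stale branch
  mappings raise typed errors; no silent NaN propagation.
* Age intervals are truncated at zero (ages are non-negative); the
  clock-set point estimate is clamped into its own bootstrap interval in
  the rare replicate where percentile noise would exclude it.
* Problem sizes in the test suite (10 kb pair replicates, 5 kb
  duplication sets, 100-run coverage experiments, bootstrap 200 where a
  distribution tail is not the target) were chosen as the smallest sizes
  at which Monte-Carlo error is comfortably below the tolerances being
  asserted.
* Seeds are explicit in every stochastic API and recorded in the
  pipeline manifest; identical config + seed reproduces outputs
  byte-identically.

## Known limitations

* The clock-set interval is a bootstrap/rate-draw composite, not a
  posterior HPD; it approximates but does not reproduce Bayesian
  strict-clock intervals.
* UPGMA assumes clock-like divergence within a duplicate set; strong
  rate asymmetry between copies biases the root height.
* The congruence test requires exact topology match; it does not attempt
  event-based reconciliation (duplications, host switches, losses).
* `identify_duplicate_sets` with ungapped sliding identity loses
  sensitivity when flanks contain interior indels; use the gapped flag
  for older duplications.
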