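# Methods

## The problem

Thermophilic filamentous fungi (growth optima above 50 °C) sit on short
branches next to mesophilic relatives, so the mutational path by which
their proteomes adapted to heat can be read directly off a species tree:
reconstruct ancestral protein sequences per alignment column, count the
amino-acid substitutions on each branch, and ask whether particular ordered
changes (lysine→arginine is the canonical example) are over-represented on
the branches where thermophily was gained. `thermopath` implements that
procedure — generalized-parsimony reconstruction, branch-specific binomial
bias tests over all 190 unordered amino-acid pairs, a per-pair score
`S = −log10 P`, and per-mutation adaptive/neutral calls — together with a
simulator that generates data with planted biases so every statistical
property of the pipeline can be measured against ground truth.

## Ancestral reconstruction and unambiguous events

Reconstruction is generalized (Sankoff) parsimony on the fixed rooted
binary species tree, run column by column (vectorized over all columns of
an alignment). Two step-cost presets are first-class:

* `unit` (default): every substitution costs 1 (Fitch-equivalent; verified
  against an independent Fitch implementation).
* `genetic_code`: cost(X, Y) = minimum number of nucleotide differences
  over all codon pairs encoding X and Y (values 1–3), the flavor of
  protein-parsimony programs that weight changes by codon accessibility.

For every internal node the exact MPR set — the states the node takes
across *all* minimum-cost labelings — is computed by a subtree/outside
dynamic program. A substitution X→Y is counted on a branch only when it is
**unambiguous**: both endpoints of the branch have singleton MPR sets and
they differ, which is equivalent to requiring that every minimum-cost
labeling changes state on that branch, always in the same direction. This
is the strictest reading of counting "only unambiguous" steps; it is
anchored in the test suite to an independent branch-and-bound enumeration
of all minimum-cost labelings over the full 20-state alphabet.

Missing data (`-` and `X`) at a leaf is the full state set; a branch into a
missing leaf can never yield an unambiguous event (a no-change completion
always exists). Columns where every leaf is missing are skipped and
reported.

## Bias test

For one focal branch (or a pooled branch-label class) and each of the 190
unordered pairs {X, Y}, let n_XY and n_YX be the unambiguous event counts.
Under a symmetric process the two directions are equally likely, but
clade-wide biases exist, so the expected probability of the X→Y direction
is calibrated on the background (mesophilic) branches:

    p_expected = (b_XY + c) / (b_XY + b_YX + 2c),   c = pseudocount (default 1)

The test is the exact two-sided binomial test of n_XY successes in
n_XY + n_YX trials at p_expected, two-sided by minimum-likelihood summation
(sum of pmf(k) over all k no more likely than the observed count; a doubled
one-sided variant is available). Pairs with zero informative events are
flagged insufficient. Default α = 0.05 with no multiple-testing correction;
Bonferroni and Benjamini–Hochberg are available by flag. A cross-branch
consistency histogram counts, per ordered direction, how many focal
branches show it significantly.

## Score S and mutation calls

For every significantly biased ordered direction X→Y, the score

    S = −log10 P(K ≥ n_XY | n = n_XY + n_YX, p = p_background)

is computed from the focal counts, where p_background is the (pseudocounted)
X→Y share over the **whole tree** — the two-background design keeps
significance gating tied to the mesophilic background while the score
measures the excess against the tree-wide average. The upper-tail
probability is used rather than the point probability so that perfect
agreement with the background yields S ≈ 0 instead of penalizing large
counts; tail convention and logarithm base are configurable and echoed into
every run manifest.

A reconstructed mutation X→Y on a thermophily-gain branch then receives
+S if X→Y is significantly biased, −S if Y→X is, and is otherwise not
scored. On the thermophily-loss branch the default (`reversed`) mode labels
mutations that undo a gain-direction bias as `destabilizing`. Scored
positions at or above the threshold S ≥ 1.3 (p ≤ 0.05 on the log10 scale;
configurable) are predicted adaptive, with deterministic
(protein, column) tie-breaking.

## Composition analyses

Frequencies are counted over aligned positions with no gap in any species;
ancestral entities contribute only columns whose reconstructed state is
unambiguous. On the profiles sit: residue-set sums (IVYWREL = I, V, Y, W,
R, E, L, the set whose summed frequency tracks growth temperature in
prokaryotes); a pooled two-proportion z-test of one species against the
pooled mesophilic background; Welch t-tests between thermophile and
mesophile entity groups (ancestral nodes included as entities); Pearson
(default) or Spearman correlation of per-residue frequencies with optimal
growth temperature; per-residue normalization to mean 0 / population-sd 1
across entities (zero-variance residues emitted as zeros and flagged); and
GC content at third codon positions overall and per encoded residue, which
lets the lysine/arginine bias be checked for independence from GC drift.
The z-test pools positions across all ortholog alignments (per-ortholog
averaging is the natural alternative; pooling matches counting "in all
aligned positions").

## The simulator

Each column evolves independently as a continuous-time Markov chain on the
20 amino acids. The baseline is uniform exchangeability and uniform
stationary frequencies scaled to `baseline_rate` expected substitutions per
site per unit branch length (default 1.0). A planted bias multiplies the
instantaneous rate of one ordered change on branches carrying a chosen
label; the modified row is renormalized to the baseline leaving rate, so
the bias redistributes direction without changing the overall rate — the
planted directional excess is then the *only* asymmetry in the process, and
detection power is attributable to the statistic. Biases act at full
multiplier on a per-protein random subset of "adaptive" columns
(`adaptive_fraction`) and optionally at a weaker multiplier elsewhere.

Because all rows share one leaving rate, the number of events on a branch
is Poisson(rate × length) and the embedded jump chain is simulated
vectorized across columns; a per-column Gillespie fallback covers
user-supplied exchangeabilities with unequal row sums. Every realized event
is logged; replaying the root sequence through the log reproduces every
leaf exactly, and this invariant is tested. Gaps are not simulated by
default (an optional gap-injection rate marks random cells `-` to exercise
gap handling; indel evolution is out of scope). Root states are drawn from
the stationary distribution of the *unbiased* matrix, since biases are
branch-local.

`simulate_tree` produces a random rooted binary topology in which the
thermophiles form a clade grafted into a random mesophile branch, with the
clade's branches labeled `focal_gain` (optionally one pendant branch
`focal_loss`, whose species reverts to a mesophile phenotype). Branch
lengths are Gamma(shape 4) with mean `branch_scale`: a resolved species
tree has no near-zero branches, which an exponential draw would produce in
quantity. OGT values are drawn uniformly (thermophiles 50–60 °C,
mesophiles 20–35 °C).

## Canonical study conditions

The canned experiments in `thermopath.experiments` fix the study regime the
simulator emulates:

| parameter | value | rationale |
| --- | --- | --- |
| tree | 15 mesophiles + 5-leaf thermophile clade | a 20-species class with nine thermophily branches |
| branch_scale | 0.15 subs/site | close relatives; total tree length ≈ 5–6 |
| planted bias | K→R × 5 on `focal_gain` | single-pair directional excess |
| adaptive_fraction | 0.2 | minority of positions carry the signal |
| data size | 200 proteins × 200 columns | 40,000 columns per run |

The calibration, power and recovery experiments consume the generator's
*logged* event stream rather than reconstructed events: they measure the
statistical machinery (expected-ratio calibration, exact binomial scan,
scoring, ranking) against exact ground truth, while reconstruction
correctness is established separately against exhaustive enumeration. At
realistic divergences parsimony's strict unambiguity criterion recovers
roughly half of the true events (and multiple hits diffuse part of a
planted single-pair excess into neighboring pairs), so end-to-end detection
through reconstruction — exercised by the integration tests and the
pipeline runs — is correspondingly more conservative than the event-stream
numbers.

Measured under these conditions (recomputed by `scripts/acceptance.py` and
the acceptance tests): the null type-I fraction of significant pairs at
α = 0.05 over 500 focal-branch scans with ≥ 50 events per tested pair sits
near 0.04 (the exact test is mildly conservative at these counts); the
planted K→R bias is detected, with the correct direction and S > 0, in
essentially every seed; and planted adaptive positions out-rank non-planted
scored positions (Mann–Whitney, planted group restricted to positions
carrying a planted-pair change, per the recovery definition above).

## What the simulator does not emulate

Uniform exchangeability and stationary frequencies rather than an empirical
replacement matrix; no rate variation across sites or proteins; no indels
(gap injection is missingness, not evolution); a single planted-bias
mechanism rather than correlated, structure-mediated selection; no
alignment error (columns are true homologies by construction). Passing
tests therefore demonstrate the correctness and calibration of the
counting and testing machinery under a controlled null and a controlled
alternative — not that real proteome-scale data would show biases of the
planted magnitude.

## Numerical choices and degenerate inputs

Exact binomial p-values by direct pmf summation with a 1e-8 relative
tolerance for pmf ties; p_expected kept inside (0, 1) by the pseudocount
(a zero-pseudocount, zero-count background is flagged undefined rather
than guessed); upper-tail probabilities floored at 0 so S ≥ 0; zero-variance
composition columns flagged rather than divided by; Welch t-tests with both
group variances zero return p = 1 for equal means and p = 0 (flagged) for
different means; constant OGT vectors make correlations undefined and
flagged; all ranking ties break deterministically by (protein, column); all
randomness flows from one integer seed through `numpy.random.default_rng`,
and identical configurations produce byte-identical outputs (checksummed in
the run manifest).

## Known limitations

Parsimony undercounts on long branches and cannot see multiple hits; the
strict all-labelings unambiguity rule trades recall for precision of event
direction. The binomial test treats the calibrated p_expected as fixed;
with sparse backgrounds its sampling noise inflates the realized type-I
rate above nominal (visible when background branches carry few events —
pool more background or raise the pseudocount). Scores are constant per
ordered pair, so within a pair the ranking of positions carries no
information beyond the sign; distinguishing adaptive from hitchhiking
same-pair changes requires evidence outside this model.
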