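# Methods

This note documents the models implemented in `phylocov`, the default
parameters and the reasons behind them, what the synthetic data generator can
and cannot claim to be realistic about, and the numerical conventions used
throughout.

## 1. Trees and dating

Species trees are rooted, with every internal node carrying an age in million
years (My) that strictly exceeds the ages of its children (leaves default to
age 0, i.e. extant taxa). Branch lengths in the input newick are interpreted
as durations and converted to ages; alternatively an explicit node-age table
can be supplied, in which case the table takes precedence over newick lengths
(with a warning). Gene trees are rooted and binary; multifurcations in the
input are resolved left-to-right with zero-length edges, and unifurcations are
suppressed. The species of a gene-tree leaf defaults to the suffix after the
last underscore in its label (`ENSP0001_Homo_sapiens`-style labels need an
explicit mapping table).

## 2. Strict reconciliation (LCA mapping)

Each gene-tree node `v` is mapped to `M(v)`, the last common ancestor in the
species tree of all species below `v`. A node is a **duplication** iff
`M(c) = M(v)` for at least one child `c`; otherwise it is a speciation.
**Losses** are attributed per gene-tree edge `(v, c)`: walking the species
path from `M(c)` up to `M(v)`, one loss is charged to every child branch of
each traversed species node that the lineage passed without diversifying into
(for a speciation, the intermediate nodes strictly between `M(c)` and `M(v)`;
for a duplication additionally `M(v)` itself when `M(c) ≠ M(v)`). This is the
classical parsimony reconciliation: the test suite verifies by exhaustive
enumeration of all valid maps that it attains the minimum duplication count
and the minimum loss count simultaneously.

Each duplication carries a **species-overlap score** `|A ∩ B| / |A ∪ B|`,
where `A` and `B` are the species sets below its two children. A value of 1
means both copies are retained everywhere; values near 0 flag dubious
duplications that imply massive complementary loss. Per-branch summaries
report the mean and the *population* standard deviation (dividing by `n`, not
`n − 1`), because the set of duplications at a node is treated as the complete
population of interest, not a sample.

## 3. Gain/loss characters and Dollo parsimony

Two character-set flavors are built from a reconciled forest:

* `families` — one presence/absence character per gene family (single-gene
  families are distinguished as `singleton` characters);
* `with_duplications` — additionally one character per duplication node,
  present in the species that retain a descendant of the post-duplication
  copy (the child subtree listed second under deterministic ordering; which
  copy is "new" is not observable, so a fixed convention is used).

A character's **origin** is the species-tree node its gene-tree root maps to;
the gain is charged to the branch above that node. Losses are placed by
**Dollo parsimony**: one loss on each maximal absent subtree inside the
origin clade. This placement is the unique minimum, which the tests confirm
against exhaustive subset enumeration. Conservation holds exactly by
construction: on every branch, `content(child) = content(parent) + gains −
losses`, and the content at a leaf equals the species' column sum in the
character matrix.

A branch-length-aware loss placement (penalising losses on short branches) is
deliberately **not** the default: the published analysis pipeline's exact
likelihood is not specified, and a deterministic, oracle-verifiable rule was
preferred over a guess.

## 4. The orphan-duplication screen

A duplication mapped to a focal species-tree node (the basal eutherian node
in the motivating study) with a single "orphan" species on one side is
suspicious: taken literally it implies one ancient duplication followed by
independent losses in nearly every other lineage. Hits are tabulated per
orphan species under five nested criteria:

| criterion    | requirement                                             |
|--------------|---------------------------------------------------------|
| `isolated`   | one species alone on one side of the duplication        |
| `vs5`        | … and **more than 5** species on the other side         |
| `vs5_no_sp`  | … and the orphan species absent from the other side     |
| `vs10`       | … and more than 10 species on the other side            |
| `vs10_no_sp` | … and absent from the other side                        |

Thresholds are strict inequalities. A duplication whose two sides are both
singletons yields two hits (each species orphan once) under `isolated` only.
Species without hits still appear in the cohort table with zero counts — a
zero is evidence in the rank test, not missing data.

Cohorts (low- vs high-coverage genomes) are compared per criterion with a
**one-tail Mann-Whitney test**: `U = Σ 1[x > y] + ½ Σ 1[x = y]` over all
pairs, and `P = 1 − Φ((U − n₁n₂/2)/σ)` with the tie-corrected standard
deviation and **no continuity correction** — this combination reproduces the
published P-values (0.016, 0.016, 0.005, 0.014, 0.005) at three-decimal
rounding, which was verified before the implementation was frozen. An exact
method (full enumeration of group assignments, Monte-Carlo above 2×10⁶
combinations) is available for small samples; exact and normal P agree within
0.005 at the published cohort sizes. No multiple-testing correction is
applied across the five criteria, matching the original analysis.

## 5. Low-coverage degradation model

Low-coverage annotation damage is emulated by replacing a contiguous stretch
of residues with `X` in each protein of a targeted species. The stretch
length is `round(f·L)` where `f ~ Normal(μ, δ)` truncated to [0, 1] **by
resampling** (not clipping — clipping would bias the realised mean away from
μ); the stretch start is uniform over the valid positions. Published profiles
are bundled: chimpanzee (μ = 9%, δ = 3%), mouse (12%, 3%), cow (15%, 3%).
At 2,000 sequences of length 500 the realised mean masked fraction matches μ
within 0.2 percentage points.

Alignment columns with **more than 10%** gap characters are discarded; if
that would remove more than one third of the columns, the threshold is
relaxed in steps of 0.01 until at least two thirds survive.

## 6. Synthetic ground-truth generator

`simulate_families` runs a birth–death gene-family process along the dated
species tree: per-gene duplication and loss rates (events per gene per My),
waiting times exponential, plus an optional per-branch origination rate for
new families. Every event is logged with its true branch, so inference can be
scored against the truth. `simulate_sequences` evolves protein sequences down
the gene tree under a uniform 20-state model: over a branch of duration `t`
each site is independently replaced with probability `1 − e^{−rt}` by a
residue drawn uniformly from the other 19.

`run_scenario` runs the paired experiment: one simulated dataset, two
analysis arms. The **clean** arm re-infers each gene tree from the simulated
sequences; the **degraded** arm first applies the degradation profile to the
designated species, then re-infers from the damaged sequences. Both arms use
identical pipeline settings, so any difference between them is attributable
to the degradation alone. Re-inference is Poisson-corrected p-distance
(`d = −ln(1 − p)` on the sites where neither sequence has `X`) followed by
neighbor joining and midpoint rooting.

### Default study conditions

The defaults are the study conditions and were fixed a priori, before any
outcome was inspected:

| parameter         | default | rationale                                         |
|-------------------|---------|---------------------------------------------------|
| `n_root_families` | 500     | enough events per branch for stable ratios        |
| `dup_rate`        | 0.001   | ≈ mammalian per-gene duplication rate, /gene/My   |
| `loss_rate`       | 0.001   | balanced turnover; keeps family sizes stationary  |
| `orig_rate`       | 0.0     | scenario families predate the root, phylome-style |
| `seq_length`      | 300     | typical protein length                            |
| `subst_rate`      | 0.001   | /site/My; ~26% divergence human–mouse, plausible  |
| degraded species  | Chimp 9%, Mouse 12%, Cow 15%, δ = 3% | the published profiles |

The species tree is a compact 8-taxon eutherian tree (Human, Chimp, Mouse,
Rat, Dog, Cow, Tenrec, Opossum) with textbook divergence times; the "basal
eutherian" branches are Eutheria and Boreoeutheria.

### Realism and limitations

* Rates are constant per gene and homogeneous across families and branches;
  real gene families show rate heterogeneity and bursts.
* The substitution model has no site-rate variation, no amino-acid exchange
  preferences, no indels; the alignment is implicit (simulation preserves
  positional homology), so alignment error — a real contributor — is absent.
* Degradation replaces residues in annotated proteins; it does not model
  genes missing entirely from a low-coverage assembly, fragmented gene
  models, or chimeric annotations.
* Tree re-inference uses distance NJ rather than maximum likelihood; this is
  the cheapest method that reproduces the qualitative artifact (masked
  sequences → distorted distances → misplaced branches → spurious ancient
  duplications with compensating losses).
* A duplication whose two copies survive only in disjoint descendant clades
  is invisible to LCA reconciliation (hidden paralogy), so "every simulated
  duplication is recovered" holds only for duplications with surviving
  descendants of both copies whose LCA placement is preserved; with losses
  switched off, recovery is exact and per-branch.

## 7. Numerical conventions

* Distances with fewer than 20 comparable (non-`X`) sites, or with `p ≥ 1`,
  are invalid; invalid entries are imputed as 1.05 × the largest valid
  distance in the matrix so NJ still sees a finite, maximal dissimilarity.
* Midpoint rooting falls back to the unrooted tree's default root in the
  rare degenerate case where skbio's midpoint rooting fails.
* All randomness flows through `numpy.random.default_rng` with explicit seed
  sequences (`[seed, stream]`), so families, sequences and degradation use
  independent, reproducible streams; derived integer seeds stay below 2³¹.
* Population (not sample) standard deviation in per-branch score summaries.
* Gain-ratio comparisons report NaN where the denominator branch has zero
  gains rather than inventing a value.
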