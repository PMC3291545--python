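# Methods

## Site prediction model

A predicted hydration site is a consolidated cluster of docked water-oxygen
positions. The pipeline assumes the docking engine samples the pocket's
favourable water positions redundantly across independent runs, so that true
sites appear as tight multi-pose clusters and noise as isolated weak-scoring
poses. Only protein–water interactions inform the poses; water–water
cooperativity is not modelled, which in real pockets shifts some sites by a
few tenths of an ångström and can split one experimental water between two
predictions.

Parameters (all configurable via `ClusterParams`):

| parameter | default | meaning |
|---|---|---|
| `score_cutoff` | −0.6 kcal/mol | minimum acceptable pose score; at weaker scores placements are statistically indistinguishable from random placement in the sterically allowed volume |
| `round1_cutoff` | 0.5 Å | first single-linkage round; removes overlapping duplicates and curbs chaining |
| `round2_cutoff` | 1.6 Å | second round over the round-1 means; ~the van der Waals radius of water |
| `runs_expected` / `per_run_cap` | 3 / 20 | pooling convention: three independent runs at the engine's 20-mode cap, ≤60 poses |

The published protocol prints the score cutoff as a magnitude (0.6 kcal/mol);
since docking scores are negative-favourable and the random-baseline
comparison identifies scores below about −0.5 kcal/mol as better than random,
the filter keeps poses with score ≤ −0.6. Filtering precedes clustering.

Single-linkage at a distance threshold equals connected components of the
distance-threshold graph; the implementation uses
`scipy.cluster.hierarchy.linkage(method="single")` + `fcluster`, and the test
suite checks it against an independent brute-force union-find oracle. A
round-2 site position is the unweighted mean of its round-1 cluster means
("mean of means"): the round-1 means are the objects the second round
clusters, so they enter the average with equal weight. A pose-weighted
variant is available (`round2_position="pose_weighted"`). Output ordering
breaks ties by member count, then best member score, then lexicographic
position; single-pose clusters are legitimate sites (no minimum cluster
size). Given a pose list the pipeline is fully deterministic.

## Site descriptors

**Hydrogen-bond term.** For the water oxygen and each donor/acceptor partner
atom j, the pair value is a linear ramp on the van der Waals surface distance
d = |r| − (R_O + R_j): 1 for d ≤ −0.7 Å, 0 for d ≥ 0. The ramp endpoints and
the per-element radii (C 1.9, N 1.8, O 1.7, S 2.0 Å, metals 1.2 Å …) follow
the docking engine's published scoring function and are configuration values
(`ScoreParams`). The water acts as both donor and acceptor, so every polar
atom is a potential partner and no angular term is applied.

**Water energy.** E = 1.77 − 2.58·HB kcal/mol. The coefficients come from
refitting the hydrogen-bond term against thermodynamic-integration water
binding free energies; `model_selection` reproduces the mining procedure that
produced them (below). E > 0 means the water is predicted less stable than
bulk; each saturated hydrogen bond contributes −2.58 kcal/mol.

**Hydrophilicity / lipophilicity.** Σᵢ pᵢ·exp(−rᵢ/d₀) over protein, cofactor
and ion atoms within 4 Å, with d₀ = 1 Å. The exponential weight reflects the
roughly exponential distance decay of hydrophobic effects; it is injectable
(`ScoreParams.weight`) so alternative kernels can be swapped without touching
callers. For hydrophilicity pᵢ is a per-atom-type hydration propensity —
the empirical fraction of surface-exposed occurrences of that atom type
carrying an ordered water. The cited propensity survey does not tabulate its
values in a form we can ship, so `data/propensities.tsv` carries
*representative defaults* that preserve the ranking of atom classes (charged
O/N > hydroxyl > amide > backbone > sulfur); they are config data and should
be replaced with a published table for production use. Cofactor atoms map to
the most similar protein atom class (element-level fallback, logged); ions
take the table maximum, reflecting their outsized hydration free energies.
For lipophilicity pᵢ is 1 for carbon and 0 otherwise, a deliberate working
hypothesis rather than a fitted quantity. Ligand atoms are excluded from both
sums: the descriptors characterise the *apo* environment that the classifier
must judge without ligand knowledge.

## Energy-model mining (`model_selection`)

All 2⁸−1 = 255 non-empty subsets of an 8-term scoring-function library are
fit by OLS with intercept and ranked by AIC in the Gaussian profile form
n·ln(RSS/n) + 2(k+1), k = |subset|+1 (the +1 counts the profiled-out noise
variance; the full-likelihood dialect differs by an additive constant and
never changes a ranking). The 30 lowest-AIC models enter leave-group-out
cross-validation — each fold holds out all measurements of one conserved
water — and the model with the lowest mean absolute held-out error wins,
refit on all data. "Mean error" is implemented as mean absolute error; RSS is
floored at machine-precision scale so exact fits share one AIC base and rank
by the parameter penalty alone, and CV errors equal to within 10⁻⁹ count as
ties (broken to the smaller subset, then name order).

The default term library is the engine's five non-torsional empirical terms
(gauss1, gauss2, repulsion, hydrophobic, hbond) plus force-field vdW,
electrostatic and desolvation terms; torsional terms do not apply to a rigid
water, and the force-field hydrogen-bond term is dropped as redundant with
the empirical one. The library is pluggable — the procedure, not the term
identities, is the contract.

On simulated data (n = 54 in 11 groups, single-term truth, 1.5 kcal/mol
noise) the true term enters the selected subset in effectively every seed,
but the *exact* singleton subset wins only a minority of seeds: among the
top-30 candidates many supersets are CV-tied to within noise, and picking the
minimum is itself noisy. Tests therefore assert term recovery (membership),
with exact recovery asserted only in the zero-noise limit where it is
deterministic.

## Displacement labelling and classification

Labels are retrospective: sites predicted in the ligand-stripped pocket are
compared against the bound complex. Conserved ⇔ within 1.5 Å of a complex
crystal water; else displaced ⇔ within 1.5 Å of a ligand heavy atom, with
polarity decided by the nearest such atom's donor/acceptor role (the rule
when several atoms overlap a site); else ambiguous, excluded from training
and from accuracy denominators. The 1.5 Å cutoff matches both the acceptable
prediction error and the van der Waals radius of water.

The classifier is bagging over CART trees on the three descriptors. Tree
fitting is delegated to `sklearn.tree.DecisionTreeClassifier` with
rpart-like settings — Gini impurity, minimum leaf size 5, no depth cap, no
pruning (all configurable) — while the bagging loop, bootstrap-index
bookkeeping, leaf-proportion averaging and JSON serialization are native to
this package, so trained models round-trip through versioned JSON without
pickles and predictions are reproducible bit-for-bit from a seed. A class's
probability is the mean over trees of the training-class proportions in the
leaf containing the query. Two binary models run in cascade (conserved vs
displaced; polar vs non-polar given displaced); chained probabilities
multiply. Validation is leave-protein-out: one fold per protein, accuracy by
argmax class, reported both fold-equal and pooled over waters (the two can
differ when proteins contribute unequal water counts; both are returned).
Confidence is summarised by max-probability bins [0.5,0.6)…[0.9,1.0].

## Evaluation machinery

Consensus waters: waters from different pre-aligned replicate structures
chained by single linkage at 1 Å; groups spanning ≥2 structures are consensus
(represented by the group mean), the rest singletons. Matching of predictions
to experimental waters is greedy closest-pair, one-to-one — this reproduces
the observed phenomenon that an experimental water lying between two
predictions yields one true positive and one false positive. TP counts
matched consensus waters; FP counts predictions matching nothing, consensus
or singleton, making the FP rate an upper estimate (some "false" positives
may be real but crystallographically unresolved waters). The hydration-shell
filter (3.0 or 3.3 Å from the protein) restricts the consensus set before
matching. The random baseline samples uniformly without replacement from
grid nodes of the binding-site box (full side 15 Å, centred on the ligand
centroid) that are clash-free against every heavy atom at van der
Waals-sum distance — an internal proxy for the "sterically allowed volume"
that avoids a dependency on external affinity-grid binaries.
Displacement-propensity profiles report, per ligand atom class (donor,
acceptor, aromatic/non-aromatic carbon; elements O/N/C), the cumulative
fraction of atoms within each distance of the nearest displaced site;
classes with no atoms are omitted.

## Synthetic fixtures

The generators emulate the study's data geometrically, not chemically: a
pocket is a shell of pseudo-atoms (donors N at 2.65 Å, acceptors O at 2.60 Å
— inside the ramp's saturation distance — and carbons at 3.5–3.9 Å, inside
the 4 Å environment radius) on well-separated directions around planted
sites spaced 8 Å apart. Pose scores draw from Normal(−1.5, 0.3) kcal/mol for
planted poses and Normal(−0.3, 0.2) for decoys, deliberately straddling the
−0.6 cutoff so the filter is exercised in both directions. Replicate
structures jitter consensus sites with σ = 0.3 Å *bounded at half the 1 Å
merge radius* (rejection sampling): by the consensus definition a planted
"consensus" water whose copy drifted out of capture range would not be
consensus at all, so the bound makes the planted plan ground truth by
construction, as copies of a well-ordered water in replicate crystal
structures are. Complex fixtures place ligand oxygens on polar-overlap sites
and carbons on non-polar ones; remaining sites become conserved crystal
waters. The classifier dataset (`make_protein_dataset`, default 20
"proteins" of 8 sites) varies pocket composition with the planned fate —
conserved sites polar-rich, non-polar-displaced sites carbon-lined — so the
three descriptors separate classes the way buried vs exposed real waters do.

What passing these tests shows: the pipeline's algorithms (filtering,
clustering, scoring arithmetic, mining, bagging, evaluation accounting) are
correct and deterministic. What they do not show: accuracy on real proteins,
where water networks, protonation, coordinate error and genuinely ambiguous
density have no synthetic counterpart; the planted-site recovery and >90% CV
accuracies are properties of the separable fixtures, not forecasts for
crystal structures.

## Numerical choices and limitations

- All distances are Cartesian ångströms between oxygen positions; pose
  hydrogens are ignored throughout (every protocol distance is
  oxygen-to-oxygen).
- PDB reading takes the first model and the first altloc; no occupancy
  resolution, no mmCIF, no protonation assignment.
- Problem sizes in the test and acceptance suites (≤100-point clustering
  instances, 50 mining seeds, 20-protein CV) were chosen as the smallest
  sets that make the statistical assertions stable.
- The docking engine itself is out of scope: the package consumes its
  multi-model output format and emulates it synthetically.
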