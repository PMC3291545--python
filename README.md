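# waterplace

Ordered water molecules in protein binding pockets mediate ligand binding:
some are conserved when a ligand binds, others are displaced — and whether a
water can be displaced, and by what kind of chemical group, matters directly
for lead optimisation. `waterplace` predicts hydration sites from ensembles
of docked water poses, scores each site, and assigns probabilistic
conserved/displaced classifications, for structural bioinformaticians and
computational medicinal chemists working from docking output.

## Method

**Site prediction.** A single water molecule is docked repeatedly into the
binding site (three independent runs, up to 20 modes each, pooled to at most
60 poses). Poses scoring worse than −0.6 kcal/mol are discarded — at weaker
scores a placement is no better than random. The surviving oxygen positions
are consolidated by two rounds of single-linkage clustering: first at 0.5 Å
(removing near-duplicates and suppressing chaining), then clustering the
resulting means at 1.6 Å (about the van der Waals radius of water). Each
final cluster mean is a predicted hydration site.

**Site scoring.** Three descriptors summarise a site's environment:

- *Hydrogen-bond term* `HB = Σ_j ramp(d_j)`, summing over donor/acceptor
  partner atoms j, where `d_j` is the van der Waals surface distance and the
  pair value ramps linearly from 1 (d ≤ −0.7 Å) to 0 (d ≥ 0).
- *Water energy* `E = 1.77 − 2.58·HB` kcal/mol — the hydrogen-bond term refit
  against calculated water binding free energies, found by all-subsets linear
  modelling over 8 docking scoring-function terms (255 models), AIC ranking,
  and leave-group-out cross-validation (`model_selection` reproduces this
  mining procedure).
- *Hydrophilicity* `Σ_i h_i·exp(−r_i/d₀)` and *lipophilicity*
  `Σ_i l_i·exp(−r_i/d₀)` over atoms within 4 Å (d₀ = 1 Å), with `h_i` an
  atom-type hydration propensity and `l_i` the carbon indicator.

**Displacement classification.** Sites predicted in the ligand-stripped
pocket are labelled against the bound complex (conserved within 1.5 Å of a
crystal water; displaced within 1.5 Å of a ligand atom, polar vs non-polar by
the nearest atom's hydrogen-bonding role). Bagged classification trees on the
three descriptors return class probabilities as the mean of leaf class
proportions across the ensemble, validated by leave-protein-out
cross-validation.

## Worked example

Everything runs on synthetic fixtures, so no downloads are needed:

```sh
waterplace synth --out demo --seed 7
waterplace predict --poses demo/run1.pdbqt --poses demo/run2.pdbqt \
                   --poses demo/run3.pdbqt --out demo/sites.pdb
waterplace evaluate --predicted demo/sites.pdb \
                    --structures demo/rep1.pdb --structures demo/rep2.pdb \
                    --structures demo/rep3.pdb
```

`synth` plants 3 hydration sites in a pseudo-pocket and writes three docking
runs (60 poses) plus replicate "crystal" structures. `predict` reports

```
60 poses -> 46 after filter -> 4 sites
```

(45 favourable planted poses plus one decoy slipped under the −0.6 kcal/mol
cutoff), and `evaluate` compares the predictions to the consensus waters of
the replicates:

```json
{
  "n_consensus": 3,
  "n_predicted_consensus": 3,
  "tp_rate": 1.0,
  "n_false_positives": 1,
  "mean_error": 0.4558629837040808,
  ...
}
```

All 3 planted consensus waters are recovered to a mean error of 0.46 Å; the
surviving decoy is the one false positive. Scoring the sites against the
pocket (`waterplace score --sites demo/sites.pdb --receptor demo/pocket.pdb
--out demo/scored.csv`) gives

```
     x      y      z  hbond_term  energy  hydrophilicity  lipophilicity
-0.018  8.091  0.255       2.934  -5.800           0.096          0.106
 0.031 -0.075  7.550       2.659  -5.089           0.103          0.085
 0.079 -0.463 -0.026       3.000  -5.970           0.122          0.092
-1.677  4.254 -2.905       1.000  -0.810           0.019          0.000
```

The three planted sites make ~3 hydrogen bonds each (E ≈ −5 to −6 kcal/mol,
strongly bound); the decoy site makes one marginal contact (−0.81 kcal/mol).
Energies below zero indicate a water more stable in the pocket than in bulk
under this model — the decoy would be a prime displacement candidate.

The library mirrors the CLI: `predict_sites`, `score_sites`, `label_sites`,
`train_bagged_trees`, `select_model`, `find_consensus`, `evaluate`, and the
`synth` generators are all importable from `waterplace`.

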