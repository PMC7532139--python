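# sdefc — static, dynamic and entropic functional connectivity

`sdefc` is a Python library for analyzing how an acute drug changes brain
functional connectivity in placebo-controlled within-subject fMRI designs.
Each participant contributes four *design cells* — (placebo, drug) × (first,
second scan half) — and the package asks, for every pair of brain regions
and every resting-state network, whether the drug changed the strength,
variability or unpredictability of their coupling.

Three per-edge measures are computed from region timeseries:

- **sFC** — static functional connectivity: Pearson *r* between two nodes'
  timeseries, analyzed as Fisher *z* = arctanh *r*;
- **dFC** — dynamic functional connectivity: the variance over time of the
  edge's conditional-correlation series *R_t*, estimated with a bivariate
  DCC(1,1)-GARCH(1,1) model (two-stage Gaussian quasi-maximum likelihood,
  no sliding windows);
- **eFC** — entropic functional connectivity: the histogram approximation
  to the differential entropy of *R_t*,
  *H* = −Σᵢ *f*(*xᵢ*) ln(*f*(*xᵢ*)/*w*(*xᵢ*)), in nats (60 bins by default).

Downstream, edges are averaged into the 8 within-network and 28
between-network interactions of the canonical 8-network scheme, each
interaction gets a 2×2 within-subject drug-by-time ANOVA (partial η²,
Holm-Bonferroni over the 36 interactions), single edges are mapped with a
conservative two-stage threshold (Bonferroni one-sample *t*, then paired
contrasts), and connectome-based classification — PLS discriminant analysis
under leave-two-participant-out cross-validation (C(12,2) = 66 folds,
chance = 25%) — scores each measure and interaction by its *d′* =
Φ⁻¹(hit) − Φ⁻¹(false alarm) for detecting the drug-first-half cell.

A synthetic study generator with known block-correlation ground truth,
AR(1) temporal smoothness, participant random effects and optional
time-varying correlation regimes drives all calibration and recovery tests.
See `docs/methods.md` for the full model account.

## Worked example

`examples/04_classification.py` simulates the default study (12
participants, 40 nodes, 400 timepoints per half) with an acute
default-mode-network reduction of 0.10 Fisher-z injected only in the
drug-first-half cell, then classifies the four cells from whole-brain sFC
and sweeps the 36 network-interaction models:

```
$ python examples/04_classification.py
whole-brain sFC: 66 folds, accuracy = 36.4% (chance 25%), d' = 1.35 (hit 0.62, fa 0.15)

confusion matrix (rows = true cell, columns = predicted):
                placebo_first  placebo_second  drug_first  drug_second
placebo_first              31              59          23           19
placebo_second             46              39          10           37
drug_first                 12              16          82           22
drug_second                18              48          26           40

top 5 of 36 network-interaction models by d':
    interaction  d_prime_raw  accuracy
      within:DM     1.935733  0.399621
    within:LatV     1.187565  0.337121
between:SM-LatV     1.032257  0.259470
between:FP-LatV     0.777549  0.331439
    within:SubC     0.777439  0.323864
```

Read: the drug-first-half cell is by far the best-classified row (82 of 132
correct — the acute effect is the most distinct state), confusions
concentrate among the no-effect cells, and the within-DM model tops the d′
ranking with a clear margin — the sweep correctly localizes the injected
signal. Exact numbers vary with the seed.

The other examples cover the generator (`01`), the three measures and
regime detection (`02`), and the network statistics (`03`).

## Command-line pipeline

The same stages are scriptable from a shell, all I/O as diff-able TSV:

```bash
sdefc simulate     --out data --participants 12 --timepoints 400 --seed 1
sdefc connectivity --data data --out conn --measures sfc,dfc,efc
sdefc networks     --conn conn --scheme data/network_map.tsv --out net
sdefc classify     --conn conn --scheme data/network_map.tsv --out cls
sdefc report       --networks net --classify cls --out summary.txt
```

Reruns with the same seed and config are byte-identical.

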