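# bnetbench

Benchmarking a simple net-block score against biophysical-model outputs for
ion-channel cardiac toxicity prediction.

## The problem

Drugs that block cardiac ion channels — above all the hERG potassium channel
carrying I<sub>Kr</sub> — can delay ventricular repolarisation, prolong the QT
interval and trigger Torsades de Pointes (TdeP), a potentially fatal
arrhythmia. Safety pharmacology increasingly screens compounds against a panel
of channels, and the open question is how best to combine a multi-channel
block profile into one torsadogenic-risk metric: feed it through a detailed
biophysical action-potential model and read off the change in APD90, or use a
simple linear score?

This package implements the evaluation pipeline for that comparison, for
safety-pharmacology modellers and method benchmarkers:

1. **Pore-block transform.** With a drug's half-maximal inhibitory
   concentration IC50 and its effective free therapeutic plasma concentration
   (EFTPC), the fraction of current blocked under a single-site pore-block
   model is

   block = 1 / (1 + IC50 / EFTPC),

   so a drug at its IC50 blocks half the current. (The conductance-scaling
   contract g → g·(1 − block), by which block enters a cell model, is also
   provided.)

2. **The net-block score.** B<sub>net</sub> is the net difference in block
   between repolarising and depolarising currents,

   B_net = Σᵢ Rᵢ − Σⱼ Dⱼ,

   with Rᵢ over the measured repolarising currents {I<sub>Kr</sub>,
   I<sub>Ks</sub>, I<sub>to</sub>} and Dⱼ over the depolarising set
   {I<sub>CaL</sub>, I<sub>Na</sub> peak, I<sub>Na</sub> late,
   I<sub>K1</sub>}. Restricting the usable channels to {I<sub>Kr</sub>}
   recovers plain hERG block, the naive benchmark, as a special case.

3. **Risk labels.** CredibleMeds categories map to binary labels under two
   schemes: the joint QT/TdeP scheme (positives = Known Risk, Possible Risk)
   and the TdeP-only scheme (positives = Known Risk).

4. **Classification evaluation.** Each scalar metric — B<sub>net</sub>, a
   biophysical model's percent change in APD90 (consumed as precomputed
   columns; the cell models themselves are out of scope), or hERG block — is
   fit one at a time by univariate logistic regression and assessed by
   leave-one-out cross-validation: train on n−1 compounds, predict the held
   out one, and summarise the pooled out-of-sample probabilities as a ROC AUC
   (Mann–Whitney, ties counted half).

A synthetic-data generator produces compound panels with the statistical
shape of published screens (activity concentrated on I<sub>Kr</sub>, then
I<sub>CaL</sub>; log-spread IC50s and EFTPCs; labels drawn from a logistic
link on the true B<sub>net</sub>), so the whole pipeline is testable without
any external data. See `docs/methods.md` for model details and limitations.

## Worked example

```bash
bnetbench synth --n 200 --channels seven --seed 20260920 --out results/demo
bnetbench evaluate --input results/demo/synthetic_seven_precomputed.csv \
    --dialect precomputed --scheme QT_TdeP --channels seven --out results/demo
```

prints (abbreviated):

```
                     dataset  scheme     metric  n_compounds  n_positive  loocv_roc_auc
synthetic_seven_precomputed QT_TdeP       bnet          200          82          0.845
synthetic_seven_precomputed QT_TdeP  ord_apd90          200          82          0.852
synthetic_seven_precomputed QT_TdeP   tt_apd90          200          82          0.820
synthetic_seven_precomputed QT_TdeP herg_block          200          82          0.632
```

Reading: on a 200-compound seven-channel synthetic panel, 82 compounds are
QT/TdeP-positive; the multi-channel metrics (B<sub>net</sub> at AUC 0.845 and
the stand-in ΔAPD90 columns, which are noisy monotone transforms of
B<sub>net</sub>) rank risk far better than hERG block alone (0.632) —
the qualitative pattern the pipeline is built to measure. The same numbers
come from the scripted analyses `analysis/01_generate_panels.py` …
`analysis/04_link_recovery.py`, which also write per-channel block summaries
and a link-parameter recovery table under `results/`.

The equivalent Python API:

```python
import bnetbench as bb

records, categories = bb.generate(bb.GeneratorConfig(n_compounds=200, seed=1))
profile = bb.blocks_for_compound(records[0])
score = bb.bnet(profile)            # BnetResult(compound=..., bnet=..., ...)
```

Real data in either CSV dialect (raw `*_ic50_uM` + `eftpc_uM` columns, or
precomputed `*_block_pct` + `Ohara3/TenTusscher3/OharaAll/TenTusscherAll`
ΔAPD90 columns) is read with `bb.read_ic50_dataset` /
`bb.read_precomputed_dataset`; channel headers are matched case-insensitively
through an alias map (hERG, Cav 1.2, Nav1.5 peak/late, Kir2.1, Kv4.3,
KCNQ1 + KCNE1).

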