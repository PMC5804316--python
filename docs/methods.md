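# Methods

## Pore-block model

Per channel, fractional block at the effective free therapeutic plasma
concentration (EFTPC) is `1 / (1 + IC50/EFTPC)` — a single-site binding curve
with Hill coefficient fixed at 1. No Hill exponent is exposed and no
concentration–response sampling over multiples of the EFTPC is performed: the
evaluation is at 1× EFTPC only. The form implies two identities the tests
assert: half-block exactly at IC50 = EFTPC, and invariance to a common
rescaling of the two concentrations (so µM vs nM is irrelevant as long as
both are in the same unit). Both IC50 and EFTPC must be strictly positive; a
missing IC50 means "not measured" and is carried as absence, never as zero
block, so reporting can distinguish an inactive compound from an untested
channel. Censored entries (IC50 above an assay's top concentration) are
likewise expected to arrive as absent cells.

## The net-block score

`B_net = Σ R_i − Σ D_j` over measured fractional blocks, with the
repolarising set {IKr, IKs, Ito} and the depolarising set {ICaL, INa peak,
INa late, IK1}. Two deliberate choices:

- **IK1 sits in the depolarising sum.** Conventionally IK1 is a repolarising
  (inward-rectifier) current; the score is nonetheless defined with IK1 on
  the depolarising side, and this package implements that definition
  verbatim. The role map lives in `ChannelRegistry` precisely so a
  sensitivity analysis can reassign IK1 without touching scoring code; the
  default is not "corrected".
- **Unmeasured channels contribute 0** (not an error), so three-channel
  assay panels score under the same operation as seven-channel panels, and a
  `usable` channel mask expresses model-capability restrictions: the
  three-channel model variants use {IKr, INa peak, ICaL}; the TT-like
  variant lacks a late sodium current and therefore uses six of the seven.

B_net is computed on the fraction scale (internally all block is in [0, 1];
percent appears only in files). Logistic-regression ROC AUC is invariant to
this positive scaling, so no results depend on it. The score is unweighted
and kinetics-free by design; state-dependent or kinetic block models are out
of scope.

## Classification evaluation

Each metric is evaluated univariately: `logit P(positive) = a + b·x` with a
free intercept, fit by maximum likelihood (Newton–Raphson with step-halving,
tolerance 1e-8 on the log-likelihood change, at most 100 iterations).
Complete or quasi-complete separation — for a univariate predictor, every
positive x on one side of every negative x — is detected before fitting and
handled by refitting with a small quadratic penalty on both coefficients
(λ = 1e-6), flagged `penalised`. Within a fold this preserves the
probability ordering of the limiting MLE, which is all the AUC consumes. A
constant predictor yields slope 0 with the intercept at the empirical
log-odds. Leave-one-out cross-validation trains on n−1 compounds and
predicts the held-out compound; folds whose training labels collapse to a
single class fall back to the training positive rate, so no fold is ever
dropped. The pooled out-of-sample probabilities are summarised as a
Mann–Whitney ROC AUC with the midrank tie rule (tied pairs count half),
which makes the label-complement identity `AUC(s, 1−y) = 1 − AUC(s, y)`
exact.

**A leave-one-out caveat the tests document deliberately.** Probabilities
from different folds are not exactly rank-comparable: a held-out positive is
predicted by a model trained with one fewer positive, which biases its
probability downward relative to held-out negatives. In the extreme, a
constant metric has LOOCV AUC exactly 0 (every fold predicts its training
positive rate, which is lower by 1/(n−1) exactly when the held-out compound
is positive), and a perfectly separating metric on six compounds scores 8/9
rather than 1 because the two boundary folds train on mirror-image sets. At
the panel sizes used here (n ≥ 150) the artifact is negligible, but it is
why small-n LOOCV AUC values should not be over-read, and why the test suite
freezes the exactly-derived small-n values instead of the idealised ones.

## Risk labels

CredibleMeds categories: KR (known TdeP risk), PR (possible risk / known QT
risk), CR (conditional risk), NR (not listed — compounds absent from the
database map to NR). The joint QT/TdeP scheme labels {KR, PR} positive; the
TdeP-only scheme labels {KR} positive, so TdeP positives are always a subset
of QT/TdeP positives. Category strings are accepted case-insensitively with
the long names ("Known Risk") as aliases.

## Synthetic data generator

The generator emulates the statistical shape of published screening panels,
not real pharmacology:

- **Activity pattern** (per-channel probability a compound is active):
  IKr 0.90, ICaL 0.55, INa_late 0.40, INa_peak 0.30, IKs 0.15, Ito 0.15,
  IK1 0.10 — activity concentrated on IKr, with ICaL the next most common
  target and notable late-sodium activity, the pattern seen in full-panel
  screens. Three-channel mode restricts to {IKr, ICaL, INa_peak}, the shape
  of the older assay panels.
- **Concentrations:** IC50s log-uniform on 10^[−2, 2] µM per active channel;
  EFTPC log-uniform on 10^[−2, 1] µM. These spans spread fractional block
  over essentially (0, 1), matching the wide block distributions such panels
  show.
- **Label model:** risk ~ Bernoulli(expit(α + β·B_net)) with defaults
  α = −1, β = 3 and B_net computed through the real pore-block/scoring
  pipeline — the label driver is the quantity the evaluation claims is
  informative, which makes parameter recovery and the discrimination
  ordering well-posed. Categories are drawn conditional on risk (positive →
  KR 0.7 / PR 0.3; negative → CR 0.2 / NR 0.8) so the two schemes genuinely
  differ on synthetic data.
- **ΔAPD90 stand-ins:** when the precomputed dialect is written, the four
  model-variant columns are noisy linear transforms of the capability-masked
  B_net (gain 40 or 35 percent per unit net block, Gaussian noise SD 4).
  They preserve the monotone relation to net block that the evaluation
  exercises and make no biophysical claim; nothing about real cell-model
  error structure is represented.

One `numpy.random.default_rng(seed)` instance drives a generation; no global
random state is touched, and a fixed seed reproduces the panel bit-for-bit.

What passing tests therefore show: the pipeline's arithmetic, estimators and
orderings are correct under the assumed data-generating process. What they
do not show: anything about real compounds — real IC50 panels have assay
noise, censoring, correlated channel activities and labels that are not a
logistic function of net block.

## Numerical and design choices

- Block is a fraction internally; files carry percent (the supplementary-
  data dialect). Reading divides by 100, writing multiplies; round-trips are
  exact to one multiply/divide at double precision, and the raw-IC50 dialect
  round-trips bit-exactly (shortest-representation floats, `round_trip`
  parsing).
- Quartile convention in block summaries: linear interpolation of order
  statistics (numpy's default), checked against brute-force rank
  computation.
- Evaluation cells with single-class labels are recorded as unavailable
  rather than aborting the table; per-fold events (separation fallbacks,
  single-class folds) are logged and counted per cell.
- Each run writes a manifest (input SHA-256, dialect, scheme, metrics,
  channel mode, seed) alongside its table; identical inputs and
  configuration produce byte-identical outputs.
- Problem sizes in the scripted analyses: 200-compound panels for the
  evaluation tables, 1000 compounds for link recovery, 20 replicate seeds of
  150 compounds for the B_net-vs-hERG margin — sizes at which LOOCV fold
  effects and Monte-Carlo error are small relative to the effects measured.

## Known limitations

- The biophysical cell models themselves are not simulated; their ΔAPD90
  outputs enter only as precomputed columns (real data) or documented
  stand-ins (synthetic data).
- No confidence intervals on AUC are produced, and no multivariable or
  machine-learning classifiers are included: the evaluation compares scalar
  metrics one at a time.
- Binding kinetics, state-dependence and multi-concentration
  exposure–response are outside the model.
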