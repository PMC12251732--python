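# Methods

## Overview

`coopfall` predicts fall risk for adults aged 60+ by stacking two base
models — a fuzzy-logic model over vital signs (AI1) and a deep belief
network over Activities of Daily Living (AI2) — under a random-forest
meta-classifier, and evaluates the stack against the Morse Fall Scale
(MFS). This note records the modelling assumptions, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## AI1: Mamdani fuzzy model over vital signs

Inputs are one sample per participant of systolic and diastolic blood
pressure (mmHg), pulse pressure (systolic − diastolic, mmHg), heart
rate (bpm) and SpO2 (%). Each variable carries three trapezoidal
membership functions placed on conventional adult clinical bands
(e.g. SpO2 ≥ 95 normal, 90–94 low, < 90 critical; systolic
hypo-/normo-/hyper-tensive at 90–100/130–140 mmHg shoulders;
brady-/normo-/tachy-cardic heart rate at 50–60/95–105 bpm). Degrees
are piecewise-linear interpolants in [0, 1].

Inference is Mamdani min/max: a rule's strength is the minimum of its
antecedent degrees, and each output term's activation is the maximum
strength over the rules naming it. The aggregated output set is
defuzzified by centroid on a [0, 1] severity axis carrying five
equal-width terms centred at 0.1/0.3/0.5/0.7/0.9 (shoulder trapezoids
at the ends); the crisp score is banded at the midpoints 0.2/0.4/0.6/
0.8 into Normal < Low < Moderate < High < Emergency. Mamdani min/max
with centroid defuzzification is the de-facto default when an
inference operator is not otherwise fixed.

The shipped rule base (`data/default_rules.txt`, 111 rules) is a
synthetic stand-in constructed from those clinical bands: 81 rules on
the full systolic × diastolic × heart-rate × SpO2 grid, 27 on the
pulse-pressure × heart-rate × SpO2 grid — severity graded by the
number of out-of-band signs, critically low SpO2 always Emergency —
plus 3 shock-pattern overrides (critical SpO2; hypotension with
tachycardia; hypotension with narrow pulse pressure). The file format
(`IF var IS term AND … THEN risk IS level`, `#` comments) lets users
swap in any clinically curated base without touching code. Missing or
inconsistent vitals are hard errors, never imputed: in a safety
context a silent default is worse than a refusal.

Degenerate inputs: if no rule fires at all the engine raises a
dedicated error and the caller decides the fallback; the shipped base
covers the full input space, so this arises only with user-supplied
partial bases.

## AI2: deep belief network over ADLs

The behavioural input is a sequence of activity bouts (label +
duration). Features are the per-activity time fractions multiplied by
fixed significance weights — sitting 0.2, standing 0.4, walking 0.6,
running 0.8, jumping 1.0 — giving a 5-vector in the unit hypercube.
Sedentary-heavy mixes are the high-risk signature.

The network is a stack of Bernoulli RBMs (default 5 → 16 → 8)
pretrained greedily with CD-1 (50 epochs, learning rate 0.01), with
real-valued [0, 1] features treated as Bernoulli probabilities — the
simplest faithful choice at this input scale; Gaussian visible units
would add variance parameters the data cannot constrain. A 3-class
softmax head is then fine-tuned end to end by backpropagation on
cross-entropy with Adam (200 epochs, moment decay 0.9/0.999,
full-batch at cohort scale). The Adam step defaults to 1e-2: at
desk-scale cohort sizes a 1e-3 step leaves the net effectively at its
initialization after 200 epochs (chance-level accuracy on cleanly
separable activity mixes), while 1e-2 fits those mixes exactly and
recovers a noiseless mix → risk mapping at ≥ 95% held-out accuracy
(n = 200). All hyperparameters are exposed in `DBNConfig`; training is
fully determined by the seed.

Prediction is the argmax of the softmax; exact ties are broken toward
the lower severity and logged — at genuinely equal evidence the model
should not raise an alarm, and the log preserves the information.

Raw accelerometry is out of scope: bouts are the input contract, and
activity recognition belongs to the data-acquisition layer.

## Comparators and the meta-model

Score fusion maps levels to weights (AI1: 0.2/0.4/0.6/0.8/1.0; AI2:
0.33/0.66/0.99), averages the pair, and bands the mean at ≤ 0.40 /
≤ 0.80 / > 0.80. The band specification leaves a printed gap between
0.40 and 0.41; the implementation closes it with half-open intervals
so every score in [0, 1] is classifiable (0.405 is Moderate). Rule
fusion keeps agreed categories and otherwise takes the higher severity
on the shared scale, so Emergency always dominates. Decision-tree
fusion is an ordered first-match rule list; a `weighted` flag selects
between the strict rows and the adaptive rows that emit hyphenated
in-between labels ("Moderate-High", "Low-Moderate") for borderline
pairs — both row sets are preserved verbatim, and hyphenated labels
are a distinct label set with a documented projection (higher
component) used only for ordinal comparisons. Pairs covered by no row
fall through to rule fusion, logged.

The meta-model maps levels through the second weight table (AI2: 0.4/
0.6/0.8), computes S_combined = (W_AI1 + W_AI2)/2 — attainable range
exactly [0.3, 0.9] — and bands it with the same half-open thresholds.
The learned layer is a random forest (scikit-learn) with 100 trees,
max depth 10, min_samples_split 4, full-size bootstrap resamples, and
no feature subsampling (there are only two features, the two mapped
weights — deliberately no extra covariates). Final prediction is the
plurality of per-tree votes; ties break toward lower severity and are
logged. Training labels come from MFS levels; when MFS labels are not
available the trainer falls back to labels generated by the threshold
rule itself (flagged in output) — this fallback is also what the
10-row reproduction uses, since the published training cohort is not
available.

The forest artifact stores the training set, configuration and seed
and refits on load; training is deterministic given the seed, so a
reloaded model makes bitwise-identical predictions. This keeps the
artifact human-readable JSON rather than serialized tree internals.

## Evaluation

MFS totals (0–125) are thresholded at < 25 / 25–45 / > 45 into Low /
Moderate / High; both endpoints 25 and 45 read as Moderate
("between … and" inclusive). Numeric equivalents 0.3/0.6/0.9 place MFS
levels on the model's score axis. Binary scoring takes positive =
{Moderate, High}: this "at-risk vs not-at-risk" split is the
convention the package adopts, and on the embedded 10-row comparison
it yields TP = 6 (P1, P2, P4, P6, P7, P10) and FN = 1 (P8). Metrics
are accuracy (TP+TN)/n, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), rounded half-up to two decimals; zero-denominator ratios
are reported as not-applicable, never 0.

Two evaluation quantities on the embedded comparison deliberately
coexist without reconciliation. The table itself yields TN = 2 and
FP = 1 (P3 is predicted Moderate against an MFS Low), while the
published confusion counts are TN = 3, FP = 0; no binarization of the
printed rows reproduces the latter. The package reports the
table-derived counts as measured, and separately reproduces the metric
arithmetic from the published counts (accuracy 90.00%, sensitivity
85.71% = 6/7, specificity 100%). Multi-class exact-match agreement on
the table is 7/10 (mismatches P3, P4, P8) and is reported alongside
the binary metrics.

## Synthetic cohorts

The generator (`cohort.py`, profiles in `data/profiles.yaml`) emulates
a risk-stratified geriatric cohort with three latent classes. Vital
signs are truncated normals per sign; systolic pressure is generated
as diastolic + pulse pressure so the ordering invariant holds with
probability 1. The low-risk class centres at normotensive/normoxic
values (SpO2 ~ N(97, 1) truncated to [94, 100]), the high-risk class
at hypotensive, tachycardic (HR ~ N(105, 10)) and desaturated values.
ADL bouts draw activities i.i.d. from a class mix (sedentary share
rising with risk) with gamma bout lengths (shape 4, mean 60 s) over a
75-hour horizon — the three-day continuous-monitoring span typical of
long-term movement studies; the last bout is truncated so total time
is conserved exactly. MFS scores are uniform integers within the
class's band, fall-history counts Poisson at a class rate, ages
uniform 60–90. All parameters are synthetic stand-ins — the source
clinical datasets publish no per-class distributions — and live in the
YAML file, clearly marked.

Indirect pairing merges one vital-sign participant and one ADL
participant into a single evaluation record when age matches exactly,
fall-history counts match exactly (a ±1 tolerance flag is available),
and the MFS level is identical; matching is greedy one-to-one and
unmatched ids are reported. "Comparable health condition" beyond these
three keys is not operationalized, because no further criterion is
specified anywhere.

What passing tests on these cohorts shows — and does not. The
generator's classes are cleanly separated by construction, so
end-to-end accuracy near 100% demonstrates that the pipeline wiring,
feature construction and training recover a known signal, not that the
models reach any particular accuracy on clinical data. The two
external-data standalone accuracies quoted for the base models are not
reproducible from this package and are not claimed by it.

## Numerical conventions and problem sizes

Centroid integration uses a 1001-point trapezoid grid on [0, 1]
(membership functions are piecewise linear, so error is O(h²) and far
below the 0.2-wide band resolution). Metric rounding is half-up
(`decimal`), matching two-decimal reporting. Forest and DBN training
are seeded; every CLI command takes `--seed`. Default experiment sizes
— 30 training participants, 10 evaluation rows, n = 200 for the
recovery properties, 100 random samples for the engine-vs-oracle check
— are the package's reference problem sizes and run in seconds.

## Known limitations

* The shipped rule base is a clinically-banded synthetic stand-in, not
  a validated clinical artefact; per-deployment curation is expected.
* One vital-sign sample per participant: no temporal modelling of
  vital-sign trajectories.
* The DBN consumes the aggregate activity mix; bout ordering and
  circadian structure are discarded.
* The meta-model sees only two scalar features; its forest is
  expressive far beyond what that space requires, which is harmless
  but means the threshold rule is usually what it learns.
* Jumping is included in the generator's mixes (configurable); cohorts
  without it exercise only four of the five activity weights.
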