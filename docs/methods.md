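# Methods notes

This note records the scientific model behind the package, the defaults and
their rationale, the numerical conventions, and what the synthetic cohort
does and does not establish about real data.

## Clot-trace model and parameter extraction

A ROTEM channel is a sampled series of clot firmness (mm, unsigned — the
two-sided TEMogram is folded) against seconds from assay start. Irregular
sampling is accepted; timestamps must be strictly increasing after exact
duplicates are dropped.

- **CT** is the first time the amplitude reaches a threshold, linearly
  interpolated between the bracketing samples. The 2 mm threshold is the
  universal ROTEM convention (configurable), as is the **CFT** band of
  2→20 mm. CFT is reported as absent when 20 mm is never reached, which is
  the routine outcome for post-ristocetin clots of healthy subjects.
- **MCF** is the maximum recorded amplitude.
- **AUC30** integrates the first-difference velocity curve from test start
  to 30 min. The velocity is taken piecewise-constant on each sampling
  interval (no smoothing — every smoothing kernel that conserves mass leaves
  the integral unchanged) and integrated exactly, with the final interval
  clipped at 30 min. Consequently the fundamental-theorem identity
  `AUC30 = scale × amplitude(30 min)` holds to float rounding for any trace
  starting at 0 mm, and the value is invariant under collinear refinement of
  a piecewise-linear trace. Traces shorter than 30 min raise an error;
  nothing is extrapolated.
- The **device scale factor** (default 100) maps the integral onto the
  magnitudes a ROTEM delta prints. The device's true normalization is not
  public; the choice is harmless because every downstream statistic is a
  ratio of AUCs and therefore exactly scale-invariant (a tested property).

## The Ricotem statistics

`Ricotem− = AUC_rico/AUC_extem × 100` and
`Ricotem+ = (AUC_rico − AUC_rico+haemate)/AUC_extem × 100`.

Ricotem+ is signed and never clamped: a subject whose post-ristocetin AUC
*rises* after VWF supplementation gets a negative score, which classifies
as low effect. Boundary conventions: Ricotem− ties go to **normal**
(conservative screening side, since low Ricotem− is the healthy signature);
Ricotem+ ties go to **high** (the high-responder band is defined
inclusively, ≥ cut-off). Defaults are 25% (Ricotem−) and 50% (Ricotem+),
with 35% as the documented lower alternative; both are configurable. The
supplementation assay may be absent for normal responders — the stepwise
protocol does not need it — and is a reported error (naming the patient)
anywhere else.

## Laboratory phenotyping

Precedence is severity-first over the three VWF measures (Ag, RCo, CB, all
percent of a normal reference):

1. Type 3 — VWF:Ag < 3% (antigen alone decides; abnormal multimers do not
   override);
2. Type 2 — abnormal multimer pattern (supplied flag, never computed);
3. Type 1 — any measure < 30%, or bleeding history with any measure < 50%
   (bleeding is read as a within-VWD severity marker, not a stand-alone
   diagnosis);
4. mild Type 1 — all three in [30, 50), half-open so it meshes with the
   <30 and <50 rules;
5. possible VWD — one or two measures < 50% with the rest ≥ 50% (the
   narrower "exactly one" reading is subsumed; one-or-two was chosen so the
   category covers every sub-threshold pattern not already captured);
6. no VWD — all three ≥ 50%.

Isolated low factor VIII with normal VWF values (mild hemophilia A pattern)
classifies as no VWD and raises a separate advisory flag rather than a
phenotype: the assay should not claim VWD for it. With a normal multimer
flag the chain is monotone — raising all three VWF values never yields a
more severe phenotype (property-tested).

## The simulator

Amplitude model: `A(t) = M_eff (1 − exp(−(t − lag)/τ))` for `t ≥ lag`, else
0, with optional multiplicative lognormal per-sample noise of coefficient
of variation `noise_cv` (mean-one, so no systematic bias). The exponential
approach is the simplest shape with closed-form CT, MCF and AUC; no
downstream statistic depends on curve shape beyond threshold crossings and
the 30-min value.

Condition plateaus, with `M` total clot strength, `φ` the
fibrinogen-dependent fraction, `V` functional VWF activity (%), `K` the
agglutination half-saturation and `ΔV` the supplement increment:

| condition    | plateau                                   |
|--------------|-------------------------------------------|
| extem        | `M`                                       |
| fibtem       | `φ M`                                     |
| rico         | `M [φ + (1−φ)(1 − g(V))]`                 |
| rico+haemate | `M [φ + (1−φ)(1 − g(V+ΔV))] + c`          |

with `g(V) = V/(V+K)` the agglutinated-platelet fraction. The saturating
form is the simplest dose–response reproducing both regimes of interest:
strong depletion with normal VWF, near-inertness without it.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `φ` (fibrinogen_fraction) | 0.20 | ≈20% of whole-blood clot strength is fibrinogen-dependent; fixes the 80% Ricotem+ ceiling |
| `M` (mcf_total_mm) | 60 mm | mid-normal adult Extem MCF |
| `lag` | 120 s | mid-normal Extem onset |
| `τ` | 300 s | plateau ≈ reached within 30 min (99.6% at 28 min) |
| `ΔV` (haemate_increment_pct) | 200% | 0.8 IU VWF:RCo into 0.4 mL ≈ 200 IU/dL added activity |
| `c` (haemate_procoagulant_mm) | 2 mm | small additive procoagulant effect of the concentrate; models the observed AUC *rise* after supplementation in healthy samples (mechanism speculative — a documented stand-in) |
| `K` (agglutination_k_pct) | 30% | healthy subjects (V ≥ 100) sit deep in the little-effect band (noise-free Ricotem+ ≈ 7.9% at V = 100) while V ≲ 7% crosses the 50% high-responder cut-off |
| `noise_cv` | 0.05 | typical inter-channel ROTEM amplitude variability |

Two consequences worth stating plainly:

- **The model's ground-truth CT is not `lag`.** The exponential leaves the
  onset at zero amplitude, so the 2-mm crossing happens at
  `lag + τ ln(M_eff/(M_eff − 2))` (≈130 s for defaults);
  `simulate.ground_truth_ct_s` returns this closed form and it, not `lag`,
  is what parameter-recovery tests compare against (they agree to well
  under 1% at 1-s sampling).
- **Ricotem− has a floor of `φ × 100` in this model** (20% by default):
  ristocetin can never remove the fibrinogen-dependent clot fraction.
  Real healthy subjects can show Ricotem− well below 20%, so simulated
  controls typically land just above the 25% normal-responder cut-off, in
  the low-responder band — the simulator reproduces the healthy/low
  *overlap* seen in practice rather than a crisp normal-responder group.
  Tests passing on synthetic cohorts therefore validate the pipeline's
  arithmetic, classification logic and monotonicity, not the clinical
  discriminative performance of the Ricotem− gate.

`simulate_patient` draws laboratory panels from class-conditional uniform
ranges chosen strictly inside the classification thresholds (e.g. Type 3:
VWF:Ag ∈ [0.3, 2.9); mild Type 1: all three VWF ∈ [31, 49)), so the lab
classifier recovers the generating class by construction — a deliberate
identifiability choice, tested over hundreds of draws. The trace
generator's `V` is set to the drawn VWF:RCo, coupling the viscoelastic
response to the labs. Per-patient seeds derive from the cohort seed by a
fixed offset; a cohort is byte-reproducible from its spec.

What the generator does **not** emulate: platelet-count and drug effects on
platelet function, acute-phase VWF elevation, temporal drift between
conventional assays and ROTEM, Type 2 subtype structure (2B/2M/2N), and
measurement artifacts other than stationary multiplicative noise.

## Cohort statistics

- Group summaries are median, 25th/75th percentile (linear interpolation
  between order statistics, numpy default) and min/max. Other software may
  use different quantile conventions; nothing downstream depends on the
  choice.
- Mann–Whitney U: exact-distribution two-sided p (scipy) when the combined
  sample is ≤ 20 without ties, otherwise the normal approximation with tie
  and continuity correction; the result object names the path taken. The
  exact path is verified in tests against a full enumeration over all group
  assignments.
- Cut-off evaluation flags patients whose stepwise classification is
  **high** at the given Ricotem+ cut-off. Among the flagged, the proportion
  with laboratory-confirmed VWD is reported as `flagged_positive_proportion`
  — a positive-predictive quantity sometimes loosely called "specificity"
  in screening write-ups; the conventional specificity is reported
  alongside so the two cannot be conflated. With nobody flagged the
  proportion is absent (`None`), never 0/0. Lowering the cut-off can only
  grow the flagged set (property-tested on random cohorts).

## Decision support

Only the Ricotem+ branch is normative: bleeding plus Ricotem+ at or above
the cut-off appends `consider-VWF-concentrate`, always accompanied by the
Type 2B/DDAVP caveat and a research-use disclaimer. The surrounding
institutional bleeding algorithm is represented by a user-editable YAML
rule table of pass-through advisories; the shipped default contains a
single generic step and **no numeric clinical thresholds** — inventing them
is out of scope by design. `recommend` is a pure function and every action
carries a rule trace.

## Problem sizes

The default test and acceptance workloads are desk-scale by choice: traces
of 2 101 samples (35 min at 1 s), a 27-patient default cohort, a
41 × 201 noise-free sweep for the Ricotem+ ceiling, 200 subjects for the
little-effect band, 50 random cohorts for the monotone-screening property,
and 1 000 random monotone traces for the extractor-versus-scan oracle. All
complete in well under a minute each on one CPU.

## Known limitations

- The dose–response `g` and the additive procoagulant term are modeling
  stand-ins for mechanisms the assay literature has not quantified; their
  defaults are documented constants, not estimates.
- The Ricotem− floor discussed above biases simulated controls toward the
  low-responder band.
- With `noise_cv = 0.05`, the AUC of a single trace inherits a ~5% CV
  (AUC30 is a single interpolated amplitude), so extreme order statistics
  over many simulated subjects — e.g. the maximum Ricotem+ of 200 healthy
  draws — fluctuate by a few percentage points across seeds.
- Cut-off performance numbers from synthetic cohorts reflect the
  generator's class ranges, not clinical accuracy; the cohort is far too
  small (by design, mirroring a pilot-scale screen) for ROC-style cut-off
  optimization.
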