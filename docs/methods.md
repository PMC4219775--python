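# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Pooled dropout screen

**Model.** A library of `library_size` constructs (default 578, the size
of a genome-wide miR/miR-cluster library) is transduced into
`n_cells_infected` cells (default 1.8×10⁶) at MOI 0.3. Integration is
single-hit Poisson: the transduced fraction is 1 − e^(−MOI) ≈ 0.259 at
MOI 0.3 (the often-quoted "~30%" is the linear approximation MOI ≈
fraction; the dataset metadata records this). Transduced cells are
assigned to constructs multinomially according to the library
representation (default uniform; a log-normal skew can be supplied via
the `representation` field, since real library representation is rarely
stated). Each clone then grows deterministically and exponentially at
per-day relative fitness *w* (*w* = 1 neutral; the untransduced
compartment grows at *w* = 1), so stochasticity enters only through
transduction and the harvest subsample. At each timepoint (default days
4, 12, 20, 28) a sample of `cells_sampled_per_tp` cells (default 2×10⁶)
is drawn multinomially from the current population composition; a
construct's template copy number is its transduced-cell count in that
sample.

**Detection.** qPCR detection of a construct is Bernoulli with
probability `c^k / (c^k + floor^k)` for `c` template copies — logistic in
log10(c), centred at `dropout_floor` with slope `k` (default 4) decades⁻¹.
Zero copies never amplify; a floor of 0 makes any template certain to
amplify. This reproduces the qualitative "Monte Carlo effect": when mean
template numbers approach the floor, sporadic non-detection at later
timepoints manufactures false depletion calls, and raising the floor in a
neutral screen strictly increases false positives (asserted as a
direction, not a rate, since the effect's magnitude depends on the floor).

**Calling rule.** The original screen's candidate statistic is described
only by citation to prior work, so this package defines an explicit,
configurable rule with the same qualitative behaviour: a construct
detected at the reference timepoint is called depleted in a replicate
when its effective abundance (zero if undetected) is ≤
`depletion_ratio` × reference abundance (default 0.5, inclusive at the
threshold) at ≥ `min_later_tps` later timepoints (default 2). Constructs
never detected anywhere are rescued into candidacy only if a cross-line
reference saw them at its reference timepoint — the rule used to retain
putative strong inhibitors. Consensus requires positivity in ≥
`min_screens` of the replicates (default 2 of 3).

**Default planted scenario.** Five constructs at *w* = 0.85/day among 573
neutral ones, dropout floor 30 copies. At these defaults a neutral
construct yields ~900 template copies per sample, while a *w* = 0.85
clone falls to ~2% of its reference share by day 28, far below both the
ratio threshold and the detection floor; recall and false-positive
targets (≥ 0.8 and ≤ 0.05) are asserted at a fixed seed.

## GFP competition

Two populations growing exponentially at log-fitness difference *s* per
day give `p_t = p0·e^{st}/(p0·e^{st} + 1 − p0)` for the transduced
fraction, exactly linear in logit space. `fit_selection` is OLS of
logit(p) on day; observed fractions are clamped to
[pseudo, 1 − pseudo] with pseudo defaulting to half an event out of the
10⁴ flow events per measurement, so observed 0%/100% stay finite.
Percentages and proportions are auto-detected (values > 1 are treated as
percent), making *s* unit-invariant. A two-point series determines the
slope but leaves no residual degrees of freedom; its standard error is
reported as NaN and the significance-based classifier then returns
not-inhibitory rather than guessing. `classify_inhibitory` calls a
construct inhibitory when the one-sided (1 − α) upper bound of *s* lies
below the threshold (defaults α = 0.05, threshold 0/day) — a substitute
for by-eye "no change" judgements, and deliberately conservative for
underpowered fits.

The generator observes binomial(10⁴, p_t)/10⁴ at weekly intervals over 35
days, starting from p0 = 0.5 (the mixing design); estimator bias under
these conditions is below 0.002/day over 200 replicate series for
s ∈ {−0.06, −0.03, 0}.

## qPCR quantitation

Standard curves are OLS of Ct on log10(copies) over a dilution series (≥ 3
points spanning ≥ 2 decades; identical Cts are rejected as singular).
Efficiency is 10^(−1/slope) − 1, warned outside (0, 1.2]. Absolute
quantitation inverts the curve and divides by cell equivalents
(rna_input_ng × 1000 / rna_per_cell_pg; 10 ng at 12.5 pg/cell = 800
cells). Undetermined Cts (NaN) propagate as below-detection in absolute
mode; calls beneath the lowest calibration standard are flagged
below-detection rather than printed as numbers, matching the convention
of reporting "<10 copies" against the curve's calibrated range (the
lowest standard is the default threshold; it is exposed on the curve
object). For relative quantitation, Cts above 35 (or undetermined) are
assigned 35 before ΔΔCt (base-2) or ratio-to-control formulas. Replicate
Cts are averaged arithmetically before any formula.

## Target prioritization

Gene symbols are matched case-insensitively. Set 1 is the union of
hit-miR predictions over both sources; Set 2 the same for the non-hit
miRs (a miR whose overexpression failed belongs to neither group and
contributes nothing); Set 3 is genes called marginal **or** present —
marginal is deliberately included. The funnel is (Set1 ∩ Set3) \ Set2,
asserted equal to a per-gene membership oracle. Shortlisting keeps
growth-annotated survivors (genes missing from the annotation table count
as not growth-related, since the table models a manual curation the
pipeline cannot reproduce), flags those with a literature link or with
dual-source support from a single hit miR, and ranks by best (most
negative) context score, ties by best (highest) target score, then
alphabetically. Context-style scores are consumed, never computed.

**Seed scanner.** Site classes follow the TargetScan conventions:
8mer-A1 = reverse complement of miR positions 2–8 followed by an A
opposite position 1; 7mer-m8 = reverse complement of 2–8; 7mer-A1 =
reverse complement of 2–7 plus the A. The A1 adenine is a sequence
requirement on the UTR, not a pairing requirement. Coordinates are
1-based inclusive on the UTR sense strand. At a locus the longest class
wins: 7mer matches whose span lies inside an 8mer span are suppressed,
and if a degenerate miR makes both 7mer patterns identical the m8 class
takes precedence. Ambiguous bases skip the window with a warning. U and T
are interchangeable in both miR and UTR input. The planted-UTR generator
re-draws background positions until a scan reports exactly the requested
sites, so fixtures are guaranteed free of spurious matches.

## Validation-assay arithmetic

Luciferase: each well's firefly is normalized by its renilla first, and
groups are aggregated as the mean of well-level ratios (not the ratio of
means) — transfection efficiency varies per well, so the per-well ratio
is the exchangeable unit. Growth folds subtract an optional blank
(default 0) before the test/reference ratio. Flow frequencies are
fractions of all events in the supplied table under fixed, configurable
thresholds (no automated gating; viability pre-gating is assumed done
upstream); cell-cycle gating takes S = BrdU⁺ and splits BrdU⁻ events by
DNA content into subG1 / G0-G1 / G2-M. All normalizations are invariant
to global instrument gain, and frequency vectors sum to 1 to 1e-12.

The flow-event generators draw from well-separated mixtures around the
gate thresholds; they emulate composition, not optics — no spillover,
autofluorescence or gate-boundary smearing — so recovery tests validate
the frequency arithmetic, not robustness to real cytometry artefacts.

## What the generators do and do not emulate

The screen generator reproduces transduction sampling, clonal dropout
kinetics and low-template detection noise, but not PCR efficiency
variation between assays, primer cross-talk, culture bottlenecks or
fitness that varies over time; the competition generator assumes constant
*s* and perfect flow counting of 10⁴ events; the qPCR generator draws
i.i.d. Gaussian Ct noise (default 0.1 cycles) on a perfectly log-linear
curve; the prediction universe plants targets that survive the funnel by
construction, so recovery there tests plumbing, not predictive accuracy.
Passing tests therefore demonstrate the correctness of the arithmetic and
the calling logic under the stated statistical structure, not performance
on real screens.

## Problem sizes and determinism

Tests and the acceptance script run full-size screens (578 × 4 × 3), 200
series per selection coefficient for bias checks, 1,000 random sequences
for scanner cross-validation and a 1,000-gene prediction universe; the
whole suite completes in a few seconds. Every generator takes an explicit
seed; the pipeline driver fans one global seed out to per-stage seeds by
hashing stage names, and identical configurations produce byte-identical
artifacts.
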