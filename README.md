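# mirhts

Analysis pipeline for pooled gain-of-function microRNA dropout screens and
their follow-up experiments, built around the workflow that identifies
growth-inhibitory miRs in leukemia cell lines and prioritizes their mRNA
targets.

A pooled lentiviral library of miR constructs is transduced into a cell
population at low MOI; constructs carried by cells that are out-grown
deplete from the culture over time, so candidate growth-inhibitory miRs
are the constructs whose qPCR-detected abundance collapses at later
timepoints. Candidates are then validated one by one in GFP-competition
assays, their expression quantified absolutely by standard-curve qPCR,
and their candidate targets prioritized by intersecting prediction
databases with expression and growth annotations before 3'UTR reporter
experiments.

The package provides, with synthetic generators for every input so the
whole chain runs without any external data:

- **`mirhts.simulate`** — generators for screen detection tables
  (Poisson single-hit transduction at MOI 0.3, deterministic clonal growth
  at per-day fitness *w*, multinomial subsampling, logistic low-template
  detection), competition series, qPCR plates, prediction universes with
  planted true targets, and seed-site-planted UTR sequences.
- **`mirhts.screen`** — candidate calling: per-replicate depletion
  (abundance at ≥ 2 later timepoints ≤ ½ of the day-4 reference,
  non-detection counting as zero), cross-line rescue of never-detected
  constructs, 2-of-3 replicate consensus, validation-rate bookkeeping.
- **`mirhts.competition`** — two-population fitness estimation. Under
  constant selection *s* (per day), the GFP⁺ fraction follows
  `p_t = p0·e^{st} / (p0·e^{st} + 1 − p0)`, linear in logit space, so *s*
  is the OLS slope of `logit(p)` on day.
- **`mirhts.quantitation`** — standard-curve absolute quantitation
  (`Ct = b + m·log10(copies)`, efficiency `10^(−1/m) − 1`), copies per
  cell via cell equivalents (10 ng RNA ÷ 12.5 pg/cell = 800 cells), the
  Ct > 35 cap, ΔΔCt folds and ratio-to-control.
- **`mirhts.target_filter`** — the prioritization funnel
  `(Set1 ∩ Set3) \ Set2` over hit-miR predictions, non-hit-miR predictions
  and expression calls; annotation-based shortlisting with score ranking;
  a 3'UTR seed-site scanner (8mer-A1, 7mer-m8, 7mer-A1, TargetScan-style
  A1 convention, 1-based inclusive coordinates) and site-deletion
  utilities.
- **`mirhts.assays`** — normalization arithmetic for dual-luciferase
  reporters, alamarBlue growth folds, apoptosis quadrant and BrdU/DNA
  cell-cycle frequencies, densitometry and the ORF-rescue comparison.
- **`mirhts.io` / `mirhts.pipeline`** — TSV/FASTA/JSON readers and
  writers, validated YAML configuration, and an end-to-end driver that is
  byte-reproducible under a fixed seed.

## Worked example

Running the numbered drivers in order regenerates the whole analysis under
`results/`:

```sh
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_call_screen_candidates.py
python analysis/03_fit_competition.py
python analysis/04_quantify_mir_copies.py
python analysis/05_prioritize_targets.py
python analysis/06_scan_utr_sites.py
python analysis/07_validation_assays.py --seed 0
```

With seed 0 the screen stage prints

```
{
  "n_consensus_candidates": 5,
  "recall": 1.0,
  "false_positive_rate": 0.0
}
```

— all 5 planted growth-inhibitory constructs (per-day fitness 0.85 among
573 neutral ones) are recovered with no false calls. The competition stage
prints

```
empty-vector: mean s = +0.0002/day, day-35 projection 50.3% GFP+, inhibitory in 0/3 replicates
inhibitory-miR: mean s = -0.0588/day, day-35 projection 9.8% GFP+, inhibitory in 3/3 replicates
```

recovering the planted selection coefficient (−0.0582/day, the value that
carries 46% GFP⁺ to 10% in 35 days) and the neutral control. The
quantitation stage recovers the planted copy numbers per cell
(e.g. `miR-509-5p: 1909 copies/cell` against a planted truth of 1814 with
0.1-cycle Ct noise), and the site scan reports exactly the planted
7mer-m8 at 66–72 and 8mer-A1 at 759–766 of the 803-nt UTR, with
single and double deletions removing them one by one.

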