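# Methods

## Copy-number calling

Profiles are probe-level log2 tumor/reference ratios on an ordered
autosomal grid (sex chromosomes are excluded throughout; the bundled
coordinate frame is GRCh37). Calling is deliberately simple and fully
deterministic:

1. **Centering.** The genome-wide median over observed probes is
   subtracted, so "neutral" is the modal copy state of the genome. For an
   even probe count the midpoint of the two central order statistics is
   used. The offset is recorded.
2. **Thresholding.** Each probe becomes LOSS (≤ −0.2), GAIN (≥ +0.2),
   AMP (≥ +1.5) or NEUTRAL. The defaults follow common aCGH practice: ±0.2
   sits between noise and a one-copy change at realistic tumor purity, and
   +1.5 corresponds to roughly six or more copies, i.e. the high-level
   amplification regime that clinical *MYCN* assays call at ≥10 copies.
   All three are parameters of `ProfileSegmenter`.
3. **Smoothing.** An interior probe whose state differs from both
   neighbours while the neighbours agree is reassigned to their state.
   Only such singletons are smoothed; 2-probe and longer discordant runs
   survive, so the contiguity-based qualification rules below keep their
   meaning. Probes at chromosome ends have only one neighbour and are
   never smoothed.
4. **Segmentation.** Maximal runs of equal state become segments (1-based
   inclusive coordinates, SEG convention; missing probes are dropped
   first and `n_probes` counts observed probes). A chromosome with fewer
   than three observed probes is emitted as a single NEUTRAL segment with
   a warning.

This scheme is not a replacement for CBS/HMM segmentation of noisy clinical
arrays; externally segmented SEG files can be supplied instead and enter
the classification layer unchanged.

**Qualification.** A non-neutral segment counts as a chromosome aberration
when it spans ≥3 contiguous BAC probes or >3 Mb of contiguous
oligonucleotide probes, depending on the platform's probe chemistry. The
boundary semantics are exact: 3 BAC probes qualify, 2 do not; 3.5 Mb
qualifies, 2.9 Mb does not.

**Chromosome calls.** A chromosome is a *numerical* aberration
(WHOLE_GAIN/WHOLE_LOSS) when the qualifying events of a single non-neutral
state jointly cover ≥ 90% (`whole_fraction`) of its probe span — coverage
is aggregated per state, so a short noise interruption does not break a
homogeneous whole-chromosome change into a spurious segmental call. Any
other qualifying event makes the chromosome SEGMENTAL; chromosomes with
only sub-threshold blips stay NEUTRAL.

## Genome signature

* **Arm flags** (1p/3p/4p/11q loss, 1q/2p/17q gain) require a qualifying
  event of the matching state overlapping the arm by ≥ 2 Mb
  (`arm_overlap_bp`; the threshold is a package choice, exposed as a
  parameter). 17q gain is only flagged on a SEGMENTAL chromosome 17; a
  whole-17 gain is reported separately (`whole_gain_17`) because the GG-P2
  definition explicitly excludes it. AMP segments never raise arm-gain
  flags: a *MYCN* amplicon is not a segmental 2p gain.
* **MYCN amplification** is called from the profile (a qualifying AMP
  segment overlapping the MYCN locus, chr2:16.06–16.11 Mb) or from the
  clinical copy number (≥ 10 copies); either source suffices.
* **The amplicon carve-out.** A tumor whose only aberration is a MYCN
  amplicon is *silent*, and whole-chromosome tumors keep subtype NCA-only
  (and zero breakpoints) in its presence. Internally the classifier
  derives *effective* chromosome calls with MYCN-locus AMP events removed.
  Elsewhere — i.e. on a chromosome that is segmental in its own right —
  the two flanks of an amplicon each count as one breakpoint by default
  (`count_amp_flanks=False` absorbs them instead; the literature's counting
  convention is not fully specified on this point, so both are available).
* **Subtype.** Any effectively segmental chromosome ⇒ SCA; only whole
  chromosome changes ⇒ NCA-only; nothing ⇒ silent. SCA tumors are
  *typical* when any of the seven recurrent arms is flagged, else
  *atypical*.
* **Breakpoints** are the within-chromosome transitions between adjacent
  segments of different state, summed over autosomes; chromosomes whose
  effective call is NEUTRAL or WHOLE_* contribute zero, and chromosome
  ends never count. NCA-only ⇒ 0 holds by construction.
* **Genome group.** Letter S/W/P from the subtype, suffix `a`/`s` from
  MYCN; `is_gg_p2` = P ∧ 1p loss ∧ 11q loss ∧ 17q gain ∧ ¬whole-17 gain.
  Finer P1–P5/W1–W5 subindices are not defined here; only the GG-P2 flag
  is computed, and mixed whole+segmental genomes map to P (segmental
  aberrations take precedence).

## Clinical risk features

Dichotomizations are inclusive at the boundary: age ≥ 18 months, LDH
≥ 1400 U/L, ferritin ≥ 250 ng/mL, breakpoints ≥ 7, MYCN ≥ 10 copies. The
points-based ultra-high-risk score uses *strict* inequalities by contrast:
2·[age > 60 months] + 1·[LDH > 1250 U/L] + 2·[MSI > 1], where the
metastatic site index (MSI) counts distinct involved systems among the
eight collected (bone marrow, bone, distant lymph nodes, liver, lung,
skin, CNS, other; "other" counts as one system). Missing inputs propagate:
a record without LDH has no score and drops out of score-based analyses
(complete-case handling everywhere, which is why every output row carries
its own N).

## Survival analysis

Kaplan–Meier estimation, log-rank comparison and Cox proportional-hazards
fits are delegated to lifelines; the package's contract is the reporting
convention, not the estimator internals. Time is months; the 5-year rate
is the step value at 60 months (last value carried forward); its SE is
Greenwood's formula computed from the risk table. Cox fits use Efron tie
handling, 95% Wald intervals and two-sided p-values; α = 0.05; no
multiplicity correction is applied (log-rank p-values are reported
unadjusted, as is conventional in these cohort reports). Degenerate
covariates (constant after complete-case filtering) and exact duplicates
are rejected with the offending term named; non-convergence is returned as
an explicit flag, not an exception.

## Synthetic cohorts

The generator emulates the statistical structure of a 605-patient
retrospective neuroblastoma cohort; its defaults are the study conditions,
not tuning knobs:

* **Composition.** Stage fractions 12/8/18/56/6% (stages 1/2/3/4/4S); 24%
  MYCN amplification distributed so that the stage-4 MYCN-non-amplified
  subset is ~225/605 in expectation; architecture mix silent : NCA-only :
  SCA = 81 : 120 : 404. Within the stage-4 non-amplified subset the
  GG-P2s architecture is forced with a probability adjusted for its chance
  co-occurrence so the realized fraction matches the configured 30/225.
* **Genomes.** Whole-chromosome events sit on chromosomes free of the
  recurrent arms; arm events are telomere-anchored (one breakpoint each)
  except the interstitial 2p gain (two), placed clear of the MYCN amplicon
  window, which itself is sized to the probe grid so it always qualifies.
  Filler interstitial events (two breakpoints each) follow a geometric
  count with a small heavy tail, calibrated so the cohort breakpoint
  median is ~4 with a maximum ≤ 56. 11q loss is drawn anti-correlated
  with 1p loss, mirroring the two mutually exclusive segmental branches of
  real neuroblastoma genomes. Probe values are state means (−0.5 / 0 /
  +0.4 / +2.0) plus Gaussian noise.
* **Clinical covariates.** LDH and ferritin are log-normal anchored at
  medians 740 U/L and 140 ng/mL with dispersions chosen to reproduce the
  observed ≥1400 U/L (~27%) and ≥250 ng/mL (~30%) prevalences; age is
  drawn around P(≥18 months) = 0.76 in stage 4 and 0.35 elsewhere
  (overall ~0.58); missingness fractions mimic the varying per-row N of
  such registries (LDH 34%, ferritin 49%, ploidy 24%, EFS 26%).
* **Outcomes.** OS is exponential with hazard
  `baseline · exp(Σ log-HR · feature)` on the *true* features; the default
  OS log-hazards are the univariate effect sizes used as simulation truths
  (age ≥ 18 mo 3.2, LDH ≥ 1400 2.1, GG-P2s 2.0, BP ≥ 7 1.9) plus stage-4
  (2.5) and MYCN (1.8) terms for cohort realism; EFS has its own baseline
  and effect sizes and EFS ≤ OS is enforced by construction. Baselines
  (0.0008 and 0.0013 per month) and the uniform censoring window
  (12–168 months) are calibrated so the cohort lands near 70% 5-year OS,
  ~50% 5-year EFS and a ~78-month median follow-up. Because univariate
  effect sizes are compounded as independent simultaneous truths, fitted
  *univariate* HRs on the full cohort exceed their marginal inputs through
  confounding (e.g. age); the two-group arm simulator
  (`simulate_survival_arm`) is the clean single-factor recovery
  experiment, and it solves for the uniform-censoring window that yields a
  requested expected censoring fraction in closed form.
* **What it does not model.** Real probe-level autocorrelation, wavy
  baselines, tumor purity and ploidy shifts, treatment-era effects,
  mass-screening ascertainment, and any dependence between the genomic
  subgroup and clinical covariates beyond stage/MYCN (conditional
  independence is assumed). Passing recovery tests therefore demonstrates
  the correctness of the classification and survival machinery under the
  stated generative model, not performance on clinical arrays.

## Problem sizes and determinism

Everything is reproducible bit-for-bit from a config and seed (the report
metadata records both, plus a config hash). Unit tests run on reduced
grids (800–2000 probes, cohorts of 100–500) chosen so every injected event
still satisfies the qualification rules; the generator refuses probe grids
under 600 probes, where the event geometry degenerates. Recovery tests use
the default 10,000-probe platform; classifier-vs-truth concordance is
exact at zero noise and ≥95% per flag at noise SD 0.1.

## Known limitations

* The threshold segmenter assumes piecewise-constant, well-centered input;
  real arrays should be segmented externally and supplied as SEG.
* Genome-group subindices beyond GG-P2 are not implemented (their
  definitions are not part of this package's scope); a signature table can
  be post-processed with a user-supplied subindex mapping.
* The breakpoint count follows this package's transition-counting
  convention; per-chromosome caps used by some older counting schemes are
  not applied.
* Cox results assume proportional hazards; no competing risks,
  time-varying covariates or nomogram construction.
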