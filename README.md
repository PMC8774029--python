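# nbgenome

Copy-number genome classification and prognostic stratification for
neuroblastoma cohorts.

Neuroblastoma risk assessment combines clinical markers (age at diagnosis,
INSS stage, serum LDH and ferritin, *MYCN* status, DNA ploidy, metastatic
burden) with the global architecture of the tumor genome measured by
array CGH. Two genomic views matter clinically:

* **NCA vs. SCA** — tumors carrying only *numerical* chromosome aberrations
  (whole-chromosome gains/losses, "NCA only") have excellent outcomes,
  whereas any *segmental* aberration (partial-chromosome gain/loss, "SCA")
  marks higher risk. An SCA requires at least three contiguous BAC probes
  or >3 Mb of contiguous oligonucleotide probes at an altered level.
* **Genome groups (GG)** — silent (S), whole-chromosome type (W), and
  partial type (P), suffixed `a`/`s` for *MYCN*-amplified/single-copy.
  GG-P2 is the partial-type subgroup with 1p loss, 11q loss and 17q gain
  but *without* whole-chromosome-17 gain; GG-P2s (its *MYCN* single-copy
  half) is a strong adverse marker inside the hard-to-stratify stage-4,
  *MYCN*-non-amplified subset.

The number of chromosome **breakpoints** (BP: within-chromosome boundaries
between copy-number states; 0 for NCA-only genomes) is a complementary
instability marker, dichotomized at BP ≥ 7. Survival is summarized the way
these cohorts are reported: Kaplan–Meier 5-year rates ± Greenwood SE,
log-rank p-values, and Cox hazard ratios (Efron ties, 95% Wald CI), with a
points-based ultra-high-risk score (age > 5 y: 2, LDH > 1250 U/L: 1,
metastatic site index > 1: 2; maximum 5).

The package provides the full path from probe-level log2 ratios (or
pre-segmented SEG files) to these survival tables, plus a synthetic-cohort
generator that emulates the composition of a 605-patient retrospective
cohort (stage mix 12/8/18/56/6%, 24% *MYCN* amplification, breakpoint
median ~4, exponential survival under configurable log-hazard truths) with
per-tumor ground truth for recovery testing.

## Worked example

```python
import numpy as np
from nbgenome import (ProfileSegmenter, GenomeGroupClassifier,
                      TumorSpec, GeneticSubtype, generate_profile,
                      default_oligo_platform)

platform = default_oligo_platform()          # 10,000 oligo probes, GRCh37
spec = TumorSpec("T1", GeneticSubtype.SCA,
                 arm_losses=("1p", "11q"), arm_gains=("17q",),
                 n_extra_events=2)
profile, truth = generate_profile(spec, platform, noise_sd=0.0,
                                  rng=np.random.default_rng(1))
segmented = ProfileSegmenter().segment(profile)
sig = GenomeGroupClassifier().signature(segmented)
print(sig.genome_group.value, sig.is_gg_p2, sig.breakpoint_count)
```

prints

```
GG-Ps True 7
```

— the tumor is partial-type, *MYCN* single copy, satisfies the GG-P2
definition (1p loss ∧ 11q loss ∧ 17q gain ∧ no whole-17 gain), and carries
7 breakpoints: one each for the telomere-anchored 1p/11q losses and 17q
gain, two for each of the two interstitial filler events.

The same flow runs from the shell:

```
nbgenome all --seed 1 --outdir run/
```

simulates the default 605-patient cohort, classifies every profile, derives
risk features and writes the survival report under `run/report/`. In that
report the stage-4 *MYCN*-non-amplified univariate table
(`stage4_mna_univariate.csv`) contains, for example,

```
gg_p2s,other GG,OS,201,66.0,3.5,0.001002,2.079,1.331,3.247
gg_p2s,GG-P2s,OS,35,35.5,8.7,0.001002,2.079,1.331,3.247
```

a GG-P2s univariate OS hazard ratio of 2.08 (95% CI 1.33–3.25) against a
simulation truth of 2.0, with 5-year OS 35.5 ± 8.7% in the GG-P2s group —
the generator's proportional-hazards truths being recovered by the analysis
layer.

Subcommands `simulate`, `classify`, `features`, `survival` and `report`
expose the individual stages; probe tables are TSV, segmentations SEG,
clinical data CSV.

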