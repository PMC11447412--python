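# keapsense

Quantitative inference of how the KEAP1 homodimer is inactivated by oxidative
stress, for researchers studying the KEAP1–NRF2 cytoprotective pathway.

KEAP1 is the substrate adaptor of a CUL3 ubiquitin E3 ligase that targets the
transcription factor NRF2 for degradation; it functions as a homodimer and
carries cysteine residues that act as covalent stress sensors (oxidative set
Cys226/Cys613/Cys622/Cys624, electrophile set Cys151/Cys273/Cys288). In a
heterozygote carrying one sensor-dead allele (e.g. C226S/C613S), random
pairing of monomers yields w², 2w(1−w), (1−w)² fractions of WT/WT, WT/mut and
mut/mut dimers — 25% / 50% / 25% at w = ½. Two competing mechanisms make
different predictions for total cellular KEAP1 activity A under stress that
inactivates a fraction f of the WT-homodimer pool:

- **monomer inactivation** — modifying one monomer kills the dimer:
  A = (1−w)² + w²(1−f) + 2w(1−w)(1−f/2) = **63%** at w = ½, f = 0.74
  (halving rule; the exact per-monomer form uses p = 1 − √(1−f));
- **dimer inactivation** — both monomers must be modified, so heterodimers
  (whose mutant member cannot be modified) stay active:
  A = (1−w)² + w²(1−f) + 2w(1−w) = **81.5%**.

Residual activity is measured by inverting a calibration curve: a power law
log(mRNA) = β₀ + β₁·log(level/100) fitted to a graded-KEAP1 genetic series
(protein levels 100/40/19/5% of WT vs fold-induction of the NRF2 target
*Nqo1*), with a percentile bootstrap (resampling calibration points stratified
by level, and observed replicates) giving a 95% CI. The hypothesis whose
prediction falls inside the CI is selected. A companion screen classifies
human KEAP1 protein variants against the sensor residue maps and evaluates the
oxidative sensor's fail-safe redundancy (parts P1 = {226}, P2 = {613},
P3 = {622, 624}; functional while ≥ 2 parts keep a thiol).

## Worked example

Closed-form predictions for the balanced heterozygote at 74% WT-homodimer
inactivation:

```
$ keapsense predict --f-inact 0.74
{"dimer": {"contrib_het_pct": 50.0, "contrib_mut_homo_pct": 25.0,
 "contrib_wt_homo_pct": 6.5, "total_pct": 81.5},
 "monomer": {"contrib_het_pct": 31.5, "contrib_mut_homo_pct": 25.0,
 "contrib_wt_homo_pct": 6.5, "total_pct": 63.0},
 "population_pct": {"het": 50.0, "mut_homo": 25.0, "wt_homo": 25.0}}
```

Total activity is the sum of the three dimer-class contributions: mutant
homodimers stay fully active (25%), WT homodimers keep 26% of their 25% share
(6.5%), and the heterodimer term is what separates the hypotheses.

End-to-end on synthetic data (generate a cohort under monomer truth, then run
the full inference):

```
$ keapsense simulate --outdir demo --seed 1 --noise-sd-log 0.05
$ keapsense analyze --calibration-tsv demo/calibration.tsv \
    --observation-tsv demo/observations.tsv --outdir demo/out
het_stressed: monomer 62.4% / dimer 81.2% -> selected monomer
```

The analysis inferred f = 0.752 from the stressed all-WT group (estimated
activity 24.8%, CI [23.5%, 26.2%]), estimated 62.7% activity (CI [58.9%,
66.4%]) in the stressed heterozygote, and selected the monomer hypothesis —
only its prediction lies inside the CI. Full numbers are written to
`demo/out/dimer_analysis.json` / `.tsv`.

The variant screen on the bundled table of seven reported human sensor-region
variants plus ten decoys:

```
$ keapsense screen --variant-tsv demo/variants.tsv --outdir demo/out
{"electrophile_sensor_cys": 0, "non_sensor": 10, "oxidative_affecting": 7,
 "oxidative_neighbor_basic": 4, "oxidative_sensor_cys": 3}
```

Seven variants touch the oxidative sensor system (three sensor cysteines,
four neighboring basic residues), none the electrophile sensors; each single
variant leaves the fail-safe functional.

## Layout

- `src/keapsense/dimer_model.py` — dimer composition, hypothesis predictions,
  verdicts
- `src/keapsense/calibration.py` — power-law fit, inversion, bootstrap CIs
- `src/keapsense/sensor_variants.py` — variant parsing/classification,
  fail-safe and inducer-class rules
- `src/keapsense/synthetic_data.py` — seeded generators for calibration,
  cohort and variant tables
- `src/keapsense/pipeline.py`, `cli.py` — orchestration, reports, CLI
- `docs/methods.md` — model assumptions, parameter defaults, numerical choices
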