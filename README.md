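# abca4tools

A genotype–phenotype analysis toolkit for clinical cohorts with
ABCA4-associated Stargardt disease (STGD1), the most common inherited
macular dystrophy.  It is written for the clinician-bioinformatician who
has a table of patients (onset age, per-eye best-corrected visual
acuity, fundus/autofluorescence/ERG type labels), a table of their
*ABCA4* variants in HGVS notation, and in-silico splice scores for the
non-canonical intronic ones — and who wants every allele classified,
every patient placed in a genotype group, phenotype severity graded, and
all cohort-level statistics recomputed reproducibly.

## What it computes

**Variant consequence typing.** cDNA (`c.6006-3C>A`), protein
(`p.Gln1852ArgfsTer3`) and genomic CNV (`chr1:94480267-94482198del`)
notation is parsed into structured descriptors.  Protein notation
dominates when present; otherwise the intron offset *o* decides:
|*o*| ∈ {1, 2} is a canonical splice change, 3 ≤ |*o*| ≤ 20 near-splice,
|*o*| > 20 deep intronic.

**Splice decision rules.** For a non-canonical intronic variant with
SpliceAI delta scores Δ = (AG, AL, DG, DL) and a MaxEntScan difference
ΔMaxEnt = MaxEnt_variant − MaxEnt_reference, a site loss is called when

    max Δ ≥ 0.2 on a loss channel,  or  ΔMaxEnt < 0 within a functional site,

and a gain symmetrically for gain channels.

**Allele deleteriousness and genotype groups.** Alleles in the ACMG
null-variant class (nonsense, frameshift, canonical ±1/2 splice,
initiation-codon loss, exonic deletion), intronic alleles with a
predicted splice effect, and intronic alleles with prior severe-phenotype
evidence are *deleterious*; missense and in-frame indels are *mild*.
With homozygotes counting twice, a patient is group **A** (≥ 2 mild,
0 deleterious), **B** (exactly 1 deleterious + ≥ 1 mild) or **C**
(≥ 2 deleterious).

**Phenotype severity.** Acuity notations are converted to logMAR
(counting fingers → 1.98, hand motion → 2.28).  Five criteria — onset,
better-eye BCVA, fundus, AF and ERG types — are scored mild
(onset > 15 y, BCVA < 0.78, type 1) or severe (onset < 10 y, BCVA > 1.0,
type 3); ≥ 2 hits on one side (and < 2 on the other) gives the class,
otherwise moderate.  All inequalities are strict.

**Cohort analytics.** Onset strata (adult ≥ 18 y; late-onset subtype
≥ 45 y), per-eye mean logMAR, AF-type distribution, zygosity breakdown,
group counts and per-group central values (mean over all member eyes,
with true medians alongside), genotype × severity cross-tab, the
distinct-variant consequence spectrum with novelty counts, and per
exon/intron/protein-domain tallies against a transcript model.

A synthetic cohort generator plants genotype groups and group-dependent
phenotypes so the whole pipeline can be verified end to end: group
recovery is exact by construction, and severity recovery is exact on
complete records.

## Worked example

The package ships an 18-patient cohort (patient, variant and
splice-score TSVs).  Running

```sh
python examples/cohort_summary.py
```

prints

```
patients: 18  (adult onset 6, childhood/adolescent 12, late-onset subtype 4)
mean onset: adult 44.3 y, child 9.6 y
mean BCVA (logMAR): OD 0.96, OS 0.92
genotype groups: {'A': 5, 'B': 6, 'C': 7}  zygosity: {'biallelic_het': 14, 'homozygous': 3, 'triallelic': 1}
  group A: n=5, onset mean 39.4 (range 11-52), BCVA mean 0.767 over 10 eyes
  group B: n=6, onset mean 18.5 (range 6-55), BCVA mean 0.878 over 12 eyes
  group C: n=7, onset mean 10.4 (range 7-25), BCVA mean 1.113 over 14 eyes
severity: {1: 4, 2: 5, 3: 6} over 15 evaluable (3 unclassifiable); severe 40.0%
AF types: {1: 4, 2: 6, 3: 4} over 14 imaged patients
spectrum (30 distinct, 8 novel): {'frameshift': 5, 'near_splice_intronic': 2, ...}
```

Six of eighteen patients had adult onset (mean 44.3 years) versus a mean
of 9.6 years for childhood onset; the seven group-C patients (two
deleterious alleles) have the worst acuity (mean 1.113 logMAR over their
14 eyes) and the earliest onset — the expected dose–response between
residual ABCA4 function and disease severity.  The validation notes at
the end list the places where recomputation from the row-level table
disagrees with the table's own printed headline values (e.g. a left-eye
mean of 0.918 → 0.92 rather than 0.91); these are surfaced, never
silently adopted.

The other scripts in `examples/` each demonstrate one capability:
variant parsing, splice calls, genotype grouping, severity
classification, region tallies, and synthetic-cohort recovery.  A thin
CLI wraps the same library calls:

```sh
abca4tools summarize patients.tsv variants.tsv --splice-table splice.tsv
abca4tools simulate -n 200 --seed 1 --out-dir sim/
abca4tools validate patients.tsv variants.tsv --splice-table splice.tsv
```

## Layout

- `src/abca4tools/` — the library (`hgvs`, `splice`, `grouping`,
  `phenotype`, `cohort`, `simulate`, `io`, `cli`), with the packaged
  cohort tables under `data/`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, rules, parameters and limitations
- `tests/` — unit, property and end-to-end acceptance tests
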