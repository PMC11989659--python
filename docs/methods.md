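# Methods

## Scope and model

`abca4tools` implements the variant-interpretation and
genotype–phenotype classification workflow used in clinical cohort
studies of ABCA4-associated Stargardt disease.  The unit of analysis is
a cohort of unrelated patients, each with demographic and ophthalmic
measurements and a list of *ABCA4* alleles in HGVS notation.  Sequencing,
alignment and variant calling are upstream of this package, as is the
computation of in-silico splice scores (SpliceAI, MaxEntScan): variants
and scores arrive as TSV tables.  No VCF ingestion, no
genome-to-transcript projection and no reference-sequence validation are
performed — HGVS strings are taken at face value, which is the contract
under which clinical variant tables are published.

## Variant consequence typing

The parser covers the HGVS subset that occurs in such tables: cDNA
substitutions, deletions, duplications, insertions and delins with
optional intron offsets; protein missense/nonsense/frameshift
descriptions; and genomic deletion intervals for CNVs.  Anything else
fails loudly (`HgvsParseError`) rather than being guessed, because a
misread allele can silently change a patient's genotype group.

Consequence inference is hierarchical.  Protein notation, when present,
is the most direct evidence and dominates: `fs` ⇒ frameshift, `Ter`
without `fs` ⇒ nonsense, a substitution at Met1 ⇒ start loss, two
distinct residues ⇒ missense.  Without protein notation the intron
offset decides: |offset| ∈ {1, 2} is canonical splice; |offset| up to
the *near-splice window* (default 20 nt, configurable) is near-splice
intronic, i.e. close enough to a functional splice site for score-based
prediction to be meaningful; beyond the window is deep intronic.  The
20-nt default places offsets like −3 and +5 on the prediction-dependent
side and offsets of several hundred nucleotides on the deep-intronic
side, which matches how such variants are discussed clinically.  Exonic
substitutions without protein annotation classify as `other` — with no
reference sequence modelled, the protein annotation is the only evidence
distinguishing missense from nonsense from synonymous.  Exonic indels
without protein annotation are classified by span length modulo 3.

A deletion whose protein annotation is a direct stop
(`c.1378del (p.Val460Ter)`) follows the protein annotation (nonsense);
either reading is deleterious downstream, so grouping is unaffected.

## Splice decision rules

For each scored variant the maximum of the four SpliceAI delta scores
(acceptor gain/loss, donor gain/loss; fractions in [0, 1]) is taken,
with ties broken in fixed channel order for determinism.  A gain or loss
is called when that maximum is **at or above** the threshold (default
0.2; the comparison is ≥, so a score exactly at the threshold is a
call).  Independently, for variants lying *within a functional splice
site* — operationalized as |intron offset| ≤ near-splice window — a
MaxEntScan difference (variant − reference) that is **strictly
negative** is called a site loss; ΔMaxEnt = 0 is not a loss, and a
positive ΔMaxEnt is not treated as a gain (site strengthening is not
site creation).  Deep intronic variants never trigger the MaxEnt branch.
Score tables may carry the MaxEnt pair or only the difference; an absent
score disables the branch and is never read as zero.

## Allele deleteriousness and genotype groups

Deleteriousness is binary, anchored on the ACMG null-variant
(PVS1-class) concept: nonsense, frameshift, canonical ±1/2 splice,
initiation-codon loss and exonic (CNV) deletions are deleterious
outright.  Non-canonical intronic alleles are deleterious when the
splice call is a gain/loss **or** when prior literature links the
variant to a severe phenotype (the `prior_severe` flag in the score
table); otherwise they are non-deleterious with basis
`deep_intronic_unsupported` ("non-canonical intronic, no supporting
evidence").  Missense and in-frame indels are non-deleterious for
grouping purposes.  A near-splice allele with no score row raises an
error rather than defaulting, since the default would change the group;
a deep intronic allele without a row defaults to unsupported with a
warning, there being no functional-site score to miss.

Genotype groups follow the Fujinami scheme on allele counts, with
homozygotes counting twice and no phasing (compound heterozygosity is
assumed, as in the source classification): ≥ 2 deleterious ⇒ C, exactly
one deleterious with ≥ 1 mild ⇒ B, ≥ 2 alleles none deleterious ⇒ A,
fewer than two alleles ⇒ unassigned (excluded from group statistics with
a logged warning).

## Acuity and severity

Acuity strings are decimal logMAR or off-chart codes: counting fingers
("CF", "FC/⟨distance⟩") → 1.98, hand motion ("HM") → 2.28, both
configurable.  Unrecognized notation is an error, never a silent
default.  The better eye is the minimum logMAR.

Severity scores five criteria — onset, better-eye BCVA, fundus type, AF
type, ERG type — as mild hits (onset > 15 y, BCVA < 0.78, type 1) and
severe hits (onset < 10 y, BCVA > 1.0, type 3).  ≥ 2 mild hits with < 2
severe ⇒ mild; ≥ 2 severe with < 2 mild ⇒ severe; otherwise moderate.
All inequalities are strict: onset of exactly 10 or 15 years and BCVA of
exactly 0.78 or 1.0 hit neither side.  Missing labels contribute no hit;
missing onset or acuity makes the patient unclassifiable.  The
degenerate ≥ 2-hits-on-both-sides case resolves to moderate with a
logged warning and a `conflict` flag — it does not occur in the packaged
cohort.

Because fundus and ERG types are not printed per patient in the packaged
cohort table, severity-stratified cohort statistics default to the
table's printed severity labels (`severity_source="table_labels"`),
while the classifier itself is exercised on the patients whose class is
derivable from onset + BCVA + AF alone and on synthetic complete
records.  Setting `severity_source="computed"` switches the statistics
to the classifier's output.

## Cohort statistics

Onset strata split at 18 years (adult) with a separate late-onset
subtype count at ≥ 45 years; both thresholds are configuration fields.
The adult-onset threshold of 18 reproduces the cohort's printed 6/12
stratum split and both stratum means.  Group-level central values are
arithmetic means — onset over members, BCVA over *all eyes* of all
members — because the packaged cohort's printed central values are
reproducible as means; true medians are reported alongside, and the JSON
labels the field `central_value_mean`.  Empty strata are reported as
absent, never as zero.  The variant spectrum deduplicates by normalized
cDNA string (genomic string for CNVs); occurrence counts are per patient
by default (a homozygote counts once) with an allele-count mode, and the
denominator of any prevalence percentage is left to the caller.
Rounding for report output is half-up at the printed precision; raw
full-precision values are retained in the JSON.

The region tally locates exonic variants by anchor cDNA position,
intronic variants by the flanking exon and offset sign, and domains by
protein residue.  The packaged transcript model is **synthetic** (50
exons tiling a 6822-nt coding sequence with a six-domain residue map);
it exercises the machinery but its coordinates are not the reference
transcript, so tallies on it are structural checks, not biological
claims.

### Validation report

Recomputation from the row-level table disagrees with four of the
packaged cohort's own printed headline values: left-eye mean logMAR
(0.918 vs printed 0.91), group-A BCVA (0.767 vs 0.748), the distinct
variant total (30 vs 31) and the missense count (10 vs 11).  The
pipeline computes the row-level values and surfaces the disagreements in
the validation report (`validate` subcommand / `validation_report()`);
it never adopts a printed aggregate it cannot recompute.  Three patients
are flagged non-evaluable for severity statistics, per the cohort's own
accounting, even though a class is printed for one of them; the printed
genotype × severity cross-tab is reproduced under that flag.

## Synthetic cohort generator

The generator plants a genotype group per patient (default proportions
0.28/0.33/0.39 for A/B/C, matching the observed mix) and realizes it
with parseable alleles: group C receives two deleterious alleles (a
configurable 0.2 probability of a single homozygous one), B one
deleterious plus one mild, A two mild; 5% of patients receive a third
mild allele, which never changes the group.  Deleterious alleles are
drawn across nonsense, frameshift, canonical-splice, near-splice-loss
(one in five of these via the prior-evidence flag with a low delta
score) and CNV; mild alleles are missense (80%) or deep intronic with
low scores.  Positions are drawn without collision from a toy 6822-nt
coding model so region tallies are exercised.

Phenotypes are group-dependent: onset C ~ uniform(5, 15) years,
B ~ uniform(6, 55), A ~ normal(40, 12) truncated to [5, 60]; per-eye
logMAR is a group baseline (A 0.75, B 0.88, C 1.11 — the group-level
means observed in real cohorts) plus a patient effect (SD 0.30) and
per-eye noise (SD 0.15), truncated to [−0.1, 2.28], with values above
1.9 emitted as the clinical off-chart notations so the acuity parser is
exercised.  Imaging labels are a noisy read (fidelity 0.8) of one latent
per-patient stage drawn from group-conditional probabilities — the three
modalities are correlated, as in clinic, rather than independent — with
20% missingness per modality.  The ground-truth severity is an inline
tally of the five criteria, kept separate from the pipeline's classifier
so recovery tests compare two independently written routes.

All draws flow through a single seeded NumPy generator; identical
configuration and seed give byte-identical tables.

**What passing tests show, and what they do not.**  Group recovery is
exact (100%) for any seed because grouping is a deterministic function
of the planted allele categories — this validates the plumbing
(parse → score → classify → group), not the clinical validity of the
grouping.  Severity recovery is exact on complete records for the same
reason.  The generator does not simulate real ABCA4 haplotype structure,
allele frequencies, measurement error in onset recall, or correlations
between acuity and imaging stage beyond the shared group; distributional
results on synthetic cohorts therefore say nothing about real-cohort
effect sizes.

## Numerical and testing choices

Problem sizes: end-to-end synthetic checks run at n = 200 (fractions of
a second); distributional sanity checks (group proportions within 4
percentage points; mean-acuity ordering C > B > A) run at n = 1000,
where the binomial and mean standard errors make the assertions hold for
essentially any seed.  At a few hundred patients the planted 0.13-logMAR
A–B gap is only about two standard errors against the 0.30
patient-effect scatter, so strict ordering of group means is not yet
guaranteed there — a power consideration, not a property of the
pipeline.  Pipeline output is deterministic (sorted JSON keys, no
randomness outside the generator), and the test suite asserts
byte-identical repeated runs.

Known limitations: binary deleterious/mild allele grading (no
three-way mild/moderate/severe variant grading); no phasing; no
statistical hypothesis testing (inappropriate at n = 18); no image
analysis (AF/fundus/ERG types are input labels); splice scores are
inputs, never computed.
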