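# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `gwas2drug`, and what the synthetic-data tests do and do
not demonstrate.

## Strata and coordinates

SNP significance strata are *cumulative*: each stratum contains every SNP at
or below its threshold, so HS ⊆ MHS ⊆ MWS ⊆ WS, and all thresholds are
inclusive (a SNP at exactly p = 5×10⁻⁷ belongs to HS). SNP positions are
read as 1-based (association-file convention) and gene intervals as 0-based
half-open (BED convention); the single conversion happens when a locus is
built. Strand is parsed but ignored: distances are measured to the gene
interval, not to the transcription start site, because no TSS rule is part
of the method. Loci are never merged — a gene falling inside two SNP
windows belongs to both loci, which matters because the prediction rules
are defined by *cross-locus* sharing; in any gene universe it still counts
once.

## Search-space parameters

The six construction methods use fixed half-widths of 100 kb, 500 kb and
1 Mb and proximity counts k = 1, 3, 5. These span the locus sizes typical
of GWAS follow-up work (regulatory variants can sit hundreds of kb from
their gene) and are overridable per run. Proximity ties (two genes at equal
base-pair distance) are broken by lexicographic symbol order, which makes
construction deterministic. Fixed-window membership is interval
intersection with [pos − w, pos + w); a SNP inside a gene has distance 0.

## Prediction rules

The five rules are deliberately binary set-membership rules — no scores or
ranks — because everything downstream consumes only the membership of the
candidate set. CPS/PPI/CRT/MIR fire only across loci: a gene at locus L
needs a distinct partner gene whose locus set is not {L}. CMP is the one
anchor-based rule: it compares a gene's domain set against *seed* genes
(known disease genes for the phenotype, a required input) by Jaccard index
with default τ = 0.5; genes or seeds without domain annotation never match.
The MIR hub criterion requires at least `hub_k` = 5 distinct targeting
miRNAs in addition to one cross-locus shared miRNA. Genes missing from an
annotation source are silently non-candidates for that rule; no imputation
is attempted.

## Drug-database harmonization

Drug identity across databases is the case-folded, whitespace-normalized
drug name; no structure matching is attempted (a synonym table can be
supplied upstream of parsing). Status normalization maps "Launched"/
"Approved" to `approved`, any phase/trial/investigational string to
`clinical`, "Experimental"/"Preclinical" to `experimental`, and anything
else to `unknown` (counted and logged). Target harmonization translates
UniProt-shaped accessions through the id map and drops untranslatable
accessions — this doubles as the human-target filter, since non-human
targets have no HUGO mapping. Status is stored per record; an entity's
development class (`approved_only` / `clinical_only` / `both`) is derived
from the union of its records' statuses, with experimental/unknown binned
into the clinical class so that every experimental drug still appears in
exactly one repositioning class.

Indication matching is a normalized substring test against a configurable
phenotype-term list. Multi-word terms ("coronary artery disease") are
recommended; very short terms would over-match as substrings.

## Reporting conventions

The targetability index is reported as a percentage rounded half-up to the
nearest integer; the novelty ratio is reported *truncated* to two decimals.
These are the only conventions under which the four canonical worked
examples (192/647 → 30%, 102/264 → 39%, 184/192 → 0.95, 98/102 → 0.96) all
reproduce, and the test suite pins them.

## Benchmarks and the AUC

Benchmark 1 uses as universe the union of the six weakest-stratum search
spaces; known positives are pooled targets with a phenotype-matching drug
indication (positives outside the universe are excluded and logged). The
six spaces give six nested predicted sets, hence up to six distinct ROC
points. Benchmark 2 thresholds per-gene phenotype-citation counts at 1, 5,
10 and 15; genes without a citation record count as zero and are reported.

AUC is the trapezoidal area under the threshold points anchored at (0,0)
and (1,1); duplicate points are collapsed and points with an undefined rate
are skipped with a warning. Curve fitting of the ROC points was considered
and rejected: a fitted AUC depends on the chosen functional form, whereas
the trapezoid is assumption-free and exactly equals the rank-sum
(Mann–Whitney) AUC on score-threshold curves — an identity the test suite
verifies on instances up to 200 scores. Significance against AUC = 0.5 is
a one-sided label-permutation test (default 1,000 permutations, +1
corrected, seeded); per-gene scores for benchmark 1 are the number of
spaces in which the gene is a predicted target (0–6).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* the analysis assumes at roughly
1/30 scale so a full run takes seconds: 3 chromosomes, 600 genes
(exponential lengths, mean 10 kb; gaps, mean 40 kb), 20 planted disease
loci with stratum mix 4/4/6/6 across HS/MHS/MWS/WS, 300 null SNPs
(p > 10⁻³), ~8% of genes druggable, three partially overlapping databases
(seven-region profile, DrugBank-heavy), and 5 of the 20 planted targets
carrying a phenotype-indicated drug. Planted SNPs are placed *inside* their
gene, so every construction method recovers the gene; each planted gene is
wired so its designated rule fires (shared pathway/edge/TF/miRNA across
loci, or a domain profile identical to a seed gene). Decoy annotations
attach background genes only to private structures (unique pathway/TF/
domain ids, external interaction partners), so they cannot create
cross-locus false positives at any density — which is why default runs
recover the planted truth exactly.

By default, phenotype-indicated drugs attach only to planted (hence
predicted) targets, so benchmark 1 has no false negatives; the
`n_unpredicted_known` parameter plants known targets the predictor will
miss, for runs that should exercise the FN row of the contingency table.

Consequences for interpretation: passing the planted-recovery tests shows
the pipeline's plumbing and rule logic are correct, *not* that the rules
are sensitive on real data — real annotation databases contain abundant
cross-locus sharing among non-disease genes (false-positive pressure) and
incomplete coverage of true disease genes (false-negative pressure), real
LD makes the SNP-to-gene assignment far noisier than a SNP placed inside
its gene, and real drug nomenclature (salts, brands) defeats name-based
pooling more often than the generator's canonical names. None of these are
modelled; the generator has no LD, allele frequencies or chemistry.

## Numerical and degenerate-input conventions

Ratios with zero denominators raise a dedicated error and are rendered
"undefined" in reports rather than silently emitted as 0. Empty annotation
tables, empty candidate sets and empty drug files produce empty results,
not errors. All randomness flows through one `numpy.random.Generator`
passed explicitly; the pipeline itself is deterministic, and reports are
written with sorted keys and fixed float precision so identical config +
seed gives byte-identical artifacts. Every summary is checked against its
partition identities (targets = known + novel, drugs = known + novel,
status classes sum to their class totals, Venn regions reproduce per-set
totals) at construction time; a violation raises an integrity error naming
the identity.

## Known limitations

- The prediction rules are principle-level binary recreations; published
  candidate-gene platforms add scoring and prioritization layers that are
  out of scope here.
- Name-based drug pooling merges records only when names match after
  normalization; synonym resolution must happen upstream.
- The benchmark-1 universe choice (weakest-stratum six-space union) is a
  default, not a theorem; other universes are configurable and change the
  TN count materially.
- The permutation p-value is lower-bounded by 1/(n_perm + 1); increase
  `n_permutations` for smaller resolvable p-values.
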