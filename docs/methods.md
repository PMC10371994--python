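# Methods

`amplitype` implements a targeted amplicon-sequencing genotyping workflow
for human variants that modulate malaria disease outcomes, together with a
synthetic data generator that makes the whole pipeline testable offline.
This note documents the models, the defaults and the design decisions.

## The panel

The built-in `malaria_host_v1` panel targets four loci with 7 amplicons and
25 biallelic SNP sites on GRCh38:

| Locus | Amplicons | Key sites |
|---|---|---|
| *HBB* (chr 11) | 1 | rs334 (HbS), rs33930165 (HbC), rs33950507 (HbE), rs713040, 6 others |
| *G6PD* (chr X) | 4 | rs1050828 (202 C>T), rs1050829 (376 T>C), rs5030872 (542), rs137852328 (680), rs76723693 (968), 6 others |
| *ACKR1* (chr 1) | 1 | rs2814778 (Duffy) |
| Dantu (chr 4, intergenic) | 1 | rs186873296 |

Positions are 1-based genomic coordinates; amplicon-local offsets are
0-based (`offset = pos − start`). Ref/alt alleles are plus-strand genomic
bases even for the minus-strand genes (*HBB*, *G6PD*); cDNA-style labels
("202 C>T") are metadata. Amplicon boundaries are not part of the
published design, so the built-in panel places each amplicon as a 500–600 bp
window covering its sites (four non-overlapping windows for *G6PD*), within
the 400–600 bp band such assays use. Two adjacent G6PD rows carry rsIDs
(rs137852327/rs137852328) whose dbSNP identities are in tension with their
printed positions; the panel records them as published without asserting
dbSNP agreement.

The panel ships without reference sequences (keeping the package
download-free); real sequences can be attached from FASTA, and
`simulate_references` fabricates consistent ones for simulation.

## Synthetic data generator

The generator emulates a MiSeq amplicon pool:

* **References** — uniform random bases per amplicon, with each variant
  site's offset forced to its ref allele. Purely synthetic: no homology,
  GC structure or repeats.
* **Cohort truth** — per site, alleles are independent Bernoulli(alt
  frequency) draws (Hardy–Weinberg); male X sites get a single allele.
  Default alternate-allele frequencies are those observed in the Tanzanian
  severe-malaria cohort the panel was designed for (e.g. 376 ≈ 0.356,
  202 ≈ 0.138, HbS ≈ 0.066, Duffy fixed at 1.0). Because sites are drawn
  independently, a simulated female can carry a 202-variant on a
  376-reference background — a combination outside the canonical G6PD
  haplotype structure; the phenotype module classifies it `non_canonical`
  on truth and called data alike, so truth-vs-call comparisons remain
  well defined.
* **Reads** — per sample × amplicon, `Poisson(mean_depth × multiplier)`
  full-length single-end amplicon copies, each from a uniformly chosen
  haplotype (a heterozygote's expected alt fraction is 0.5), with iid
  per-base substitution errors uniform over the three alternative bases,
  flanked by the sample's 8-bp forward index and the reverse complement of
  its reverse index. Qualities are constant Q30. Errors hit the insert
  only, not the indices; index errors are exercised separately in the
  demultiplexer tests.

Defaults are the study's conditions: 100 samples, sex ratio 0.5, mean
depth 1200× with the Dantu amplicon down-weighted to 0.15× (≈180×,
matching its published coverage deficit from weaker primer binding), and
per-base error 0.005. The error rate is a free parameter — the run it
emulates reports no per-base error estimate; 0.005 is a conventional
post-filter Illumina figure. No indel errors, chimeras, index hopping or
quality-profile structure are modelled, so passing tests demonstrate the
*logic* of the pipeline, not robustness to every artefact of real data.

## Demultiplexing

Index lists are generated randomised-greedily under a minimum pairwise
Hamming distance (default 3, chosen so 1-mismatch assignment is provably
unambiguous; the published design states no distance). A 10×10 scheme with
same-rank pairs (i = j) excluded — a common anti-hopping safeguard, and the
reading under which 10 forward × 10 reverse indices yield the published 90
usable combinations — is the default shape. Reads are assigned when both
observed indices are within `max_mismatch` (default 0, the conservative
choice) of exactly one sample's pair; ambiguous, unmatched and short reads
go to an unassigned bin, so the output always partitions the input. A
pooling-plan check warns above 200 amplicon products per pool.

## Alignment and pileup

The pool is a closed universe of 7 amplicons, so whole-genome mapping is
replaced by amplicon-local alignment. The reference implementation is an
affine-gap Smith–Waterman (match +1, mismatch −1, gap open −2 counting the
first gap base, extend −1 — conventional defaults, all configurable;
identity < 0.8 over the aligned span or span < 50 columns rejects the
read). The default `auto` path screens amplicons by edlib edit distance and
rescores the edlib alignment path under the same scoring, trimmed to its
maximum-scoring contiguous segment (a Kadane pass over column scores —
exact because a maximal segment never starts or ends inside a gap run).
For substitution-dominated reads the two routes return the same optimum;
the test suite asserts this, and checks the Smith–Waterman itself for
score equality against Biopython's independent local aligner.

Pileups tally read bases at variant-site offsets only. `N` bases count
toward neither allele (they land in the N bin of total depth). Base
qualities are not filtered by default (simulated qualities are constant);
a threshold is available for ingested data. Externally mapped SAM/BAM can
be ingested, with genomic coordinates translated through the panel
intervals, for parity runs against standard mappers.

## Genotype calling

Per site: depth < 30 → `no_call` (exactly 30 is kept); otherwise with
f = alt/(ref+alt):

* f < 0.20 → homozygous reference,
* f > 0.80 → homozygous alternate,
* 0.20 ≤ f ≤ 0.80 → heterozygous.

The boundary points are not assigned by the published rule (< 20%, > 80%);
this implementation closes the heterozygote interval, consistent with
"> 20% non-reference for a heterozygous classification" being the het
entry condition at its open edge. Both thresholds and the depth floor are
config. The denominator excludes third bases so sequencing error cannot
depress the fraction; a `third_allele` flag fires when other bases exceed
10% of total depth (plumbing, not a published rule), and a covered column
with *no* ref/alt bases at all is withheld as `no_call` — the one case
where adequate depth still yields no call.

Male X sites are hemizygous: hom classes map to `hemi_ref`/`hemi_alt`, and
an apparent male heterozygote — which no published rule addresses — is
collapsed to its majority allele (ties to ref) with a `male_het_anomaly`
flag. A het is never emitted for a male X site. The 30× filter is applied
per site ("positions of interest"); a per-amplicon reading can be emulated
by calling with per-amplicon pileups.

## Phenotype inference

G6PD classes come from 202 (rs1050828) and 376 (rs1050829) only; the
remaining panel G6PD sites are reported as raw calls but do not move the
class. Allele rule: B = neither variant, A+ = 376 only, A− = 376 + 202.
Male X calls give one allele (B/A+/A−); female diplotypes resolve under
the assumption that every 202-variant allele sits on a 376-variant
background — the canonical A− haplotype the class system presupposes — so
a double-het female is B/A−. A 202-variant with 376-reference is reported
`non_canonical`/undetermined rather than forced into a class. Severe
deficiency ⇔ A− (male) or A−A− (female).

Haemoglobin types compose the two beta-globin alleles from HbS/HbC/HbE
doses (HbAA … HbSC); more than two variant alleles across the three sites
is flagged inconsistent, and S+E / C+E compounds fall outside the
supported label set (undetermined, flagged). Duffy status reads rs2814778
(alt/alt = Fy negative), Dantu status rs186873296. Any required site at
`no_call` makes the corresponding label undetermined.

## Cohort reporting

Summaries exclude `no_call` from every denominator (no imputation), fold
hemizygous classes into homozygous ones for tabulation, and round half-up
to printed precisions: frequencies 1 dp, overall discordance 2 dp,
discordance per 1000 genotypes 1 dp. "Carrier frequency" counts
participants with ≥ 1 variant allele — the convention of the cohort tables
this reproduces — while a true allele-count frequency is provided under a
distinct name. Concordance compares (sample, site) pairs where both tables
are determinate, on folded classes; it is symmetric in its arguments.
Completeness buckets samples by the number of amplicons with any failed
site.

## Problem sizes and numerical choices

The end-to-end round-trip used in tests and in the reproduction script is
50 samples × 7 amplicons at 100× uniform depth and error 0.005 (~35,000
reads), a size at which recovery of ≥ 99% of truth genotypes is expected
and observed at 100%; larger cohorts add nothing to the logic being
exercised. The Poisson goodness-of-fit check runs at mean 3 with ≥ 1,000
draws and pooled sparse tails. All randomness flows from explicit seeds
through `numpy.random.default_rng`; outputs are bit-reproducible given
(config, seed).

## Known limitations

* No indel calling or indel error model — the panel sites are SNPs.
* Single-end full-length reads only; no paired-end writer.
* No likelihood-based genotyping; thresholds are hard cut-offs, so
  allele-biased amplification below 20% alt reads is *designed* to
  misclassify a true het as hom-ref (the documented Dantu failure mode) —
  the package reproduces, not repairs, this behaviour.
* The index-scheme generator optimises nothing beyond Hamming distance
  (no GC balance, homopolymer or colour-space constraints).
* Synthetic references carry no homology between amplicons, so cross-mapping
  ambiguity is untested against real paralogy (e.g. GYPA/GYPB context of
  Dantu).
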