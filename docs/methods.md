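# Methods

## Scope and model

`apadel` implements a desk-scale version of a three-part workflow for
studying neuron-enriched long 3′ UTR mRNA isoforms: quantification of
distal poly(A) site usage (dPAU) from isoform-level abundance, design of
CRISPR/Cas9 dual-sgRNA deletions of the distal poly(A) site with an HDR
donor and genotyping assay, and verification of isoform knockout from
targeted oligo(dT)-primed long reads. Upstream read mapping and transcript
quantification (STAR/Salmon/minimap2-class tools) are treated as producers
of the package's inputs and are out of scope, as are machine-learned guide
scoring, genome-wide off-target search and GO enrichment.

## Coordinates and conventions

All internal coordinates are 0-based half-open; BED is native and GTF is
converted on read/write. A 3′ UTR isoform's cleavage site (`pas_pos`) is
`utr_end` on the plus strand and `utr_start` on the minus strand; every
"upstream/downstream" statement in the design and verification modules is
transcript-relative, which keeps the arithmetic strand-symmetric (and this
symmetry is property-tested). Ties for the distal isoform (equal 3′ UTR
length) go to the more distal genomic 3′ end, then lexicographic isoform
id, making outputs deterministic.

## dPAU quantification and differential testing

PAU is expressed in percent; per (gene, sample) the isoform PAUs sum to
100 wherever the gene's total TPM is positive and are NA otherwise. dPAU
is the PAU row of the distal isoform; single-isoform genes are removed.
The expression filter requires total gene TPM ≥ `min_tpm` (default 1) in
**every** sample — the strictest reading of an "across all samples"
threshold; a mean-based mode is available. Genes NA in any used sample are
skipped from testing with a logged count.

Differential dPAU uses a two-sided two-sample *t*-test on replicate dPAU
values, Benjamini–Hochberg adjustment (via `statsmodels`, cross-checked in
the tests against a brute-force step-up oracle), and classification at
q ≤ α (default 0.05) by the sign of ΔdPAU. The **pooled (Student) test is
the default**: the design is balanced with n = 3 replicates per condition,
where the Welch–Satterthwaite degrees of freedom frequently collapse
toward 2 and destroy power, while the equal-variance assumption holds for
replicate noise of this kind; Welch remains available (`test="welch"`) for
unbalanced or heteroskedastic designs. Genes with zero variance in both
groups and unequal means are reported at the forced limit p = 0 with a
`degenerate_variance` flag rather than dropped. A fold change
(dPAU_B + ε)/(dPAU_A + ε) with ε = 0.1 percent points is reported for
volcano-style plotting but is **not** used as a significance gate — no
defensible fold cutoff exists for percentages near zero.

Cross-system agreement (e.g. in-vitro neurons vs cortex) is summarized by
the Pearson correlation of per-gene mean dPAU over the gene-name
intersection (≥ 3 shared genes required). Cassette-exon tables in rMATS
4.x format are filtered by the strict rule FDR < 0.05 and
|IncLevelDifference| > 0.2 before gene-set intersection with the
lengthening calls.

## Deletion design

Guide enumeration finds every 20-mer + NGG on both strands of a window;
cut coordinates are insertion points 3 nt 5′ of the PAM (plus-strand
protospacer at [p, p+20) cuts at p+17; minus-strand PAM at [s, s+3) cuts
at s+6). Candidate quality uses a transparent surrogate score — hard
rejects for a TTTT stretch (U6/Pol III terminator), GC outside
[0.25, 0.75], or a homopolymer ≥ 5; otherwise
0.5·(1 − |GC − 0.5|/0.5) + 0.5·(1 − |offset|/150). This deliberately
replaces proprietary machine-learned rankings: the feasibility statistics
of the strategy depend on placement geometry, which the surrogate
preserves exactly, not on fine-grained activity prediction; reports label
the score as a surrogate.

Pair feasibility: the upstream guide must cut transcript-5′ of the PAS
hexamer start — the hexamer is auto-detected as AATAAA, then ATTAAA,
within 10–40 nt upstream of the cleavage site, with a ≥ 20 nt fallback
when absent — and the downstream guide must cut ≥ `due_span` (default
30) nt transcript-3′ of the cleavage site, approximating the span of the
downstream U/GU-rich element, which published descriptions never quantify
precisely. The selected pair maximizes the summed score, breaking ties by
smaller deletion then lower cut coordinate; selection is verified against
brute-force pair enumeration in the tests. Both cuts lying inside 150-nt
windows bounds the deletion at 303 nt.

The donor concatenates guide-1 site+PAM, a 750-nt left arm ending exactly
at the upstream cut, the user-supplied selection cassette, a 750-nt right
arm starting exactly at the downstream cut, and guide-2 site+PAM, all in
transcript orientation. The guide sites at the ends exist for donor
linearization in the cell and necessarily span their cuts (a protospacer
extends 17 nt past the cut on its PAM side), so the "no deleted sequence"
guarantee is defined on the donor **body** (arms + cassette), which is
what persists after cleavage; the tests enforce it at 15-mer resolution
on both strands. FRT sites are the cassette supplier's responsibility;
the module validates a motif only when one is configured.

Genotyping uses three primers under screening constraints (length 18–25,
Wallace-rule Tm 57–63 °C — Tm(2·(A+T)+4·(G+C)) is a screening
approximation, not a nearest-neighbour model — GC 0.40–0.60, homopolymer
< 5, unique exact match in the locus). The common forward primer is
placed 5′ of the left homology arm so that a knock-in band can only
amplify from on-locus integration, not from residual donor plasmid; the
placement relative to the arms is this package's choice. Band sizes come
from exact-match in-silico PCR (no mismatch model), and the pipeline's
closure property — simulated HDR followed by PCR reproduces the predicted
knock-in band exactly and extinguishes the wild-type band — is asserted
in the acceptance tests.

## Long-read 3′-end verification

The 3′ soft clip of each primary alignment is read 5′→3′ of the
transcript. Its longest prefix matching the genomic continuation past the
alignment end is treated as templated and extends the 3′ end before tail
evaluation — this operationalizes the untemplated-poly(A) check and
guarantees genomically encoded A-stretches are never counted as tails. A
tail is called at ≥ 10 untemplated nt with ≥ 0.8 A-fraction. A tail-less
end whose 20-nt transcript-downstream genomic window has A-fraction ≥ 0.6
or a run of ≥ 6 A is flagged as an internal-priming artifact (flagged
reads are excluded from isoform assignment and cryptic clustering). These
thresholds follow common oligo(dT)-artifact heuristics; none are given in
published protocols, and all are configurable and logged.

Non-artifact ends are assigned to the nearest annotated poly(A) site
within ± 30 nt (exact ties go to the proximal site — the conservative
choice for knockout verification); other ends are single-linkage
clustered with a 30-nt gap, and clusters of ≥ 5 reads are reported as
cryptic poly(A) candidates at their modal position. The verdict requires
the wild-type control to show both annotated 3′ ends; long-isoform loss
is confirmed iff the edited sample's distal fraction among assigned reads
is ≤ ε (default 0.01) and no cryptic cluster is present. Only primary
alignments are used.

## ΔΔCt analysis

Technical replicate Cts are averaged per (sample, target) first;
biological samples are the units of inference (n = 3 by default).
ΔCt = Ct_target − Ct_reference per sample; ΔΔCt is the difference of
condition means from the calibrator condition; fold = 2^−ΔΔCt. For
long-isoform measurements the reference is the total-gene amplicon of the
same sample. The per-condition p-value is a two-sided t-test on
per-sample ΔCt versus the calibrator. No amplification-efficiency
correction is applied (no standard-curve model). Shift invariance (adding
a constant to every Ct) and calibrator-swap reciprocity are
property-tested.

## Synthetic data generator

Each simulated gene occupies its own contig (alternating strands) with two
3′ UTR isoforms sharing their 5′ boundary: a proximal segment of 400–800
nt and a distal extension of 1500–4000 nt (echoing the short-vs-long UTR
geometry typical of neural APA genes). Every cleavage site gets an AATAAA
hexamer planted 16–35 nt upstream and a GU/U-rich 18-mer 5 nt downstream;
the five bases immediately past each cleavage site are A-free so genuine
tails are unambiguous. Half the genes (configurable) carry an 18-nt
genomic A-stretch mid-way through the long UTR as an internal-priming
site. Favorable guide contexts are planted in both design windows for all
but a held-out undesignable fraction (default 2.5%) whose windows are
generated PAM-free.

Abundance: gene depth is log-normal (mean 50 TPM, σ = 1; a
negative-binomial count layer is available via `depth_model="negbinom"`).
Condition-A dPAU baselines are Beta(2,2)-distributed, scaled into the
range that leaves headroom for the full planted shift (default ± 30
percent points for 40 lengthening and 10 shortening genes of 200), so a
planted effect is literally the stated number of points; replicate noise
N(0, 5 pts) is applied on the percent scale before conversion to isoform
TPMs, keeping the effect interpretable in dPAU units, and values are
clipped to [0, 100].

Reads: per gene and sample, reads are drawn from the configured
proximal/distal mix, 5′-truncated with probability 0.5, substituted at
2% (substitution-only by default — verification logic depends on end
positions, not internal identity), and given an untemplated poly(A) tail
of N(60, 20) nt (min 10) with ± 3 nt end jitter. With probability 0.1 a
distal-isoform read of an A-stretch gene instead ends at the A-stretch
start with an entirely genome-templated A clip and no untemplated tail —
the canonical oligo(dT) artifact signature. Ct tables are generated as
Ct = 30 − log2(expression) + N(0, 0.15), with the long-3′UTR target
driven by the distal-isoform TPM.

Fixed seeds give byte-identical outputs. The generator emulates the
*structure* of real data, not nanopore error profiles, splicing, gene
bodies beyond the 3′ UTR, or coverage biases — passing recovery tests
demonstrates the pipeline's logic is correct under its stated model, not
its performance on real libraries.

## Problem sizes and test design

The recovery analyses run at 200 genes × 3 replicates × 2 conditions over
20 seeds, and knockout verification at 500 reads per sample over 20
seeds — sizes chosen so the full suite and the acceptance script each
complete in well under a minute while keeping binomial noise on the
reported rates small. Oracle-equivalence tests compare against
independent brute-force implementations (exhaustive BH step-up, exhaustive
PAM scans, full pair enumeration, textbook t-test formulas); stochastic
recovery tests pool counts across seeds and assert pre-stated bounds
(sensitivity ≥ 0.90, empirical FDR ≤ 0.10, dPAU correlation r ≥ 0.95,
knockout confirmed in ≥ 19/20 runs, artifact recall ≥ 0.9 at FPR ≤ 0.05,
ΔΔCt fold in [3, 5]).

## Known limitations

- Exact-match in-silico PCR and primer uniqueness checked only within the
  provided locus, not genome-wide.
- The surrogate guide score ranks by geometry and composition only; it
  does not predict cutting efficiency.
- Internal-priming detection assumes oligo(dT) chemistry; template-switch
  artifacts at the 5′ end are not modeled.
- dPAU inference consumes isoform-level abundance as given; quantification
  uncertainty from the upstream estimator is not propagated.
- The qPCR model assumes 100% amplification efficiency.
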