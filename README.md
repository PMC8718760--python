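# apadel

Tools for studying **neural long 3′ UTR mRNA isoforms** produced by
alternative cleavage and polyadenylation (APA), built around a CRISPR/Cas9
strategy that deletes a gene's **distal poly(A) site** to knock out its long
3′ UTR isoform. The package is aimed at molecular biologists and
bioinformaticians who (i) quantify distal poly(A) site usage from short-read
RNA-seq, (ii) design dual-sgRNA deletions with a homology-directed-repair
(HDR) donor and genotyping primers, and (iii) confirm isoform loss from
targeted oligo(dT)-primed long reads.

## What it computes

**Poly(A) site usage.** For isoform *i* of gene *g* in sample *s*,

    PAU_{i,s} = 100 · TPM_{i,s} / Σ_{j∈g} TPM_{j,s}      (percent)

The **dPAU** of a gene is the PAU of its longest-3′UTR (most distal)
isoform; single-poly(A)-site genes carry no APA signal and are dropped.
Genes are kept when total TPM ≥ 1 in every sample. Differential dPAU between
two conditions uses a two-sided two-sample *t*-test per gene with
Benjamini–Hochberg FDR control; a gene is called *lengthening* when
q ≤ 0.05 and ΔdPAU > 0, *shortening* when q ≤ 0.05 and ΔdPAU < 0.

**Deletion design.** SpCas9 guides (20-nt protospacer + NGG PAM, blunt cut
3 nt 5′ of the PAM) are enumerated in 150-nt windows on both sides of the
distal cleavage site. A feasible pair cuts transcript-upstream of the PAS
hexamer (AATAAA/ATTAAA, auto-detected 10–40 nt upstream) and ≥ 30 nt
transcript-downstream of the cleavage site, so both the poly(A) signal and
the downstream U/GU-rich element fall inside the deletion. Guides are ranked
by a transparent rule-based surrogate score (GC balance and proximity;
hard rejects for TTTT, extreme GC, homopolymers ≥ 5). The HDR donor is
assembled as

    [guide1 site+PAM][750-nt left arm][cassette][750-nt right arm][guide2 site+PAM]

with homology arms abutting the two cuts exactly. Genotyping uses a
three-primer scheme — common forward primer, reverse primer inside the
deletion (wild-type band), reverse primer in the cassette (knock-in band) —
with band sizes predicted by exact-match in-silico PCR.

**Knockout verification.** Aligned long-read 3′ soft clips are split into a
genome-templated prefix and an untemplated remainder; a read has a genuine
poly(A) tail only if ≥ 10 untemplated nt are ≥ 80% A. Tail-less ends whose
downstream genomic window is A-rich are flagged as oligo(dT)
internal-priming artifacts. Remaining ends are assigned to the nearest
annotated poly(A) site (±30 nt) or clustered to detect cryptic site
activation. Loss of the long isoform is confirmed when the edited sample
has (essentially) no distal calls and no cryptic cluster, with the
wild-type sample as a positive control. qPCR tables are analysed by the
ΔΔCt method (fold = 2^−ΔΔCt).

A seeded synthetic-data generator (`apadel simulate`) emits a toy genome,
3′ UTR annotation, replicate abundance tables with planted dPAU shifts,
oligo(dT) long reads with tails and internal-priming artifacts, and Ct
tables — so the whole pipeline runs and is tested without any download.

## Worked example

```
$ cat example.yaml
sim:
  n_genes: 60
  n_lengthening: 12
  n_shortening: 3
  n_reads: 400

$ apadel --seed 7 --config example.yaml simulate --out-dir fixtures
$ apadel pau --abundance fixtures/abundance.tsv --annotation fixtures/utrs.bed --out-prefix q
60 expressed multi-isoform genes
$ apadel diffapa --dpau q.dpau.tsv --groups fixtures/groups.tsv --out diff.tsv
{
 "unchanged": 44,
 "lengthening": 12,
 "shortening": 4
}
```

All 12 planted lengthening genes are recovered (one null gene is a false
shortening call at q ≤ 0.05 — consistent with the nominal FDR). Designing
the deletion for one gene and checking feasibility across all 60:

```
$ apadel design --genome fixtures/genome.fa --annotation fixtures/utrs.bed \
      --gene gene0000 --out design.json
gene0000: 94 nt deletion at (2624, 2718)
$ apadel design --genome fixtures/genome.fa --annotation fixtures/utrs.bed \
      --all --out feasibility.tsv
{
 "n_genes": 60, "n_designable": 58, "designable_fraction": 0.967,
 "up_offset_mean": 46.1, "down_offset_mean": 44.7,
 "deletion_size_mean": 90.8, "deletion_size_sd": 18.7, ...
}
```

58/60 genes are designable (the two failures are loci without usable PAM
context); deletions average ~91 nt spanning the distal poly(A) site. Donor
assembly and genotyping primers:

```
$ apadel donor --design design.json --genome fixtures/genome.fa \
      --cassette cassette.fa --out donor.fa
{"length": 2746, "junctions": [...]}          # 23+750+1200+750+23
$ apadel primers --design design.json --genome fixtures/genome.fa \
      --cassette cassette.fa --out primers.tsv
{"wt_band": 1078, "ki_band": 1069}
```

The wild-type band (1078 nt) disappears and the knock-in band (1069 nt)
appears exactly when the same primers are run by in-silico PCR on the
HDR-edited genome. Verifying a simulated knockout from long reads:

```
$ apadel verify --alignments fixtures/truth_WT.sam --ko-alignments fixtures/truth_KO.sam \
      --genome fixtures/genome.fa --annotation fixtures/utrs.bed \
      --gene gene0000 --out verdict.json
{"long_loss_confirmed": true}
```

The wild-type sample shows both 3′ ends plus internal-priming artifacts at
the planted genomic A-stretch; the knockout sample has proximal ends only
and no cryptic poly(A) cluster, so the long-isoform loss is confirmed.

## Layout

- `src/apadel/io_core.py` — formats (FASTA, BED12/GTF, TSV, SAM/BAM),
  coordinate conventions, config/logging
- `src/apadel/apa_quant.py` — PAU/dPAU and expression filtering
- `src/apadel/apa_diff.py` — differential dPAU, BH FDR, correlation,
  splice-table filtering
- `src/apadel/del_design.py` — guide scan, pair selection, donor, primers,
  in-silico PCR, bulk feasibility
- `src/apadel/read_verify.py` — tail classification, internal-priming
  flags, cryptic clusters, knockout verdict
- `src/apadel/qpcr_quant.py` — ΔΔCt relative expression
- `src/apadel/synth_data.py` — synthetic genomes, abundance, reads, Ct
  tables with planted truth
- `docs/methods.md` — model, assumptions, parameter defaults, limitations
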