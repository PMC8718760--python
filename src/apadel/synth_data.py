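"""Synthetic APA study data with planted ground truth.

Emulates the structure of a two-condition neuronal-differentiation APA
study: per gene a toy locus with two 3' UTR isoforms sharing their 5'
boundary, a proximal and a distal cleavage site each preceded by an
AATAAA poly(A) signal 10-40 nt transcript-upstream and followed by a
GU/U-rich downstream element; replicate abundance tables with planted
dPAU shifts between conditions; oligo(dT)-primed long reads with
untemplated poly(A) tails, 5' truncation, substitution errors and
internal-priming artifacts at planted genomic A-stretches; and qPCR Ct
tables driven by the same expression truth. Every emitted fixture passes
the package's own parsers and invariants, and a fixed seed gives
byte-identical outputs.

The generator does not attempt realistic nanopore error profiles (no
indels by default), splicing, or non-UTR gene structure; recovery results
on this data demonstrate correctness of the pipeline's logic, not its
performance on real libraries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .apa_quant import counts_to_tpm
from .io_core import Genome, GenomeSequence, UtrIsoform, revcomp
from .qpcr_quant import CtRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DUE_SEQ = "TGTGTTTGTGTGTTTGTT"  # GU/U-rich, no NGG/CCN PAM context, A-free
POST_CLEAVAGE_SEQ = "GCTGC"  # keeps the first bases past a cleavage site A-free
A_STRETCH_LEN = 18


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the scaled-down recovery setting used throughout the
    test suite: 200 two-isoform genes, 40 lengthening at +30 dPAU percent
    points and 10 shortening at -30, replicate noise of 5 points, three
    replicates per condition, and oligo(dT) reads with mean 60-nt tails
    and a 10% internal-priming rate at planted A-stretches.
    """

    seed: int = 0
    n_genes: int = 200
    n_lengthening: int = 40
    n_shortening: int = 10
    effect_pts: float = 30.0
    noise_sd_pts: float = 5.0
    replicates: int = 3
    conditions: tuple = ("mESC", "neuron")
    # gene depth model
    depth_model: str = "lognormal"  # or "negbinom"
    depth_mean_tpm: float = 50.0
    depth_sigma: float = 1.0
    nb_dispersion: float = 0.1
    nb_count_scale: float = 0.5  # mean counts per TPM-nt unit for the NB model
    # locus geometry (nt)
    pad5: int = 400
    pad3: int = 1000
    proximal_len_range: tuple = (400, 800)
    distal_extension_range: tuple = (1500, 4000)
    a_stretch_fraction: float = 0.5
    undesignable_fraction: float = 0.025
    # long-read simulation
    n_reads: int = 500
    tail_mean: float = 60.0
    tail_sd: float = 20.0
    tail_min: int = 10
    p_truncation: float = 0.5
    substitution_rate: float = 0.02
    internal_priming_rate: float = 0.1
    end_jitter: int = 3
    # qPCR simulation
    ct_intercept: float = 30.0
    ct_sd: float = 0.15
    ct_tech_reps: int = 3


@dataclass
class SimTruth:
    """Planted ground truth consistent with the emitted fixtures."""

    genes: dict = field(default_factory=dict)
    reads: list = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _pam_free_seq(rng: np.random.Generator, n: int) -> str:
    """Random sequence with no GG or CC dinucleotide on either strand."""
    out = []
    prev = "A"
    for _ in range(n):
        pool = "AT" if prev in "GC" else "ACGT"
        base = pool[rng.integers(0, len(pool))]
        out.append(base)
        prev = base
    return "".join(out)


def _random_protospacer(rng: np.random.Generator) -> str:
    """A 20-mer with GC 0.5, no TTTT and no homopolymer of length >= 4."""
    while True:
        seq = _random_seq(rng, 20)
        gc = seq.count("G") + seq.count("C")
        if gc != 10 or "TTTT" in seq:
            continue
        if any(b * 4 in seq for b in "ACGT"):
            continue
        return seq


def _plant(seq: list, pos: int, insert: str) -> None:
    seq[pos : pos + len(insert)] = list(insert)


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Build the toy genome, its 3' UTR isoform annotation and the truth.

    Each gene lives on its own contig, alternating strands. Guides with a
    favorable NGG context are planted in both 150-nt design windows around
    the distal cleavage site for all genes except a held-out undesignable
    fraction whose windows are generated PAM-free.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    if cfg.n_lengthening + cfg.n_shortening > n:
        raise ValueError("planted effect genes exceed n_genes")
    lo_p, hi_p = cfg.proximal_len_range
    lo_d, hi_d = cfg.distal_extension_range
    if lo_d < 600:
        raise ValueError("distal extension too short for the design windows")

    classes = np.array(
        ["lengthening"] * cfg.n_lengthening
        + ["shortening"] * cfg.n_shortening
        + ["null"] * (n - cfg.n_lengthening - cfg.n_shortening)
    )
    rng.shuffle(classes)
    n_undesignable = int(round(cfg.undesignable_fraction * n))
    undesignable = set(rng.choice(n, size=n_undesignable, replace=False).tolist())
    with_stretch = rng.random(n) < cfg.a_stretch_fraction

    contigs, isoforms = [], []
    truth = SimTruth()
    for i in range(n):
        gene = f"gene{i:04d}"
        chrom = f"chr_{gene}"
        strand = "+" if i % 2 == 0 else "-"
        prox_len = int(rng.integers(lo_p, hi_p + 1))
        dist_ext = int(rng.integers(lo_d, hi_d + 1))
        utr_start = cfg.pad5
        cp = utr_start + prox_len  # proximal cleavage (transcript coords)
        cd = cp + dist_ext  # distal cleavage
        length = cd + cfg.pad3
        seq = list(_random_seq(rng, length))

        if i in undesignable:
            _plant(seq, cd - 173, _pam_free_seq(rng, 346))

        for c in (cp, cd):
            hex_start = c - int(rng.integers(16, 36))
            _plant(seq, hex_start, "AATAAA")
            _plant(seq, c, POST_CLEAVAGE_SEQ + DUE_SEQ)

        a_stretch_t = None
        if with_stretch[i]:
            mid = (cp + 100 + cd - 300) // 2
            a_stretch_t = (mid, mid + A_STRETCH_LEN)
            _plant(seq, mid, "A" * A_STRETCH_LEN)

        if i not in undesignable:
            up_off = int(np.clip(round(rng.normal(90, 25)), 45, 130))
            down_off = int(np.clip(round(rng.normal(62, 25)), 40, 130))
            _plant(seq, cd - up_off - 17, _random_protospacer(rng) + "AGG")
            _plant(seq, cd + down_off - 17, _random_protospacer(rng) + "AGG")

        t_seq = "".join(seq)
        g_seq = t_seq if strand == "+" else revcomp(t_seq)
        contigs.append(GenomeSequence(chrom, g_seq))

        def to_genomic(t0, t1):
            return (t0, t1) if strand == "+" else (length - t1, length - t0)

        prox_iv = to_genomic(utr_start, cp)
        dist_iv = to_genomic(utr_start, cd)
        isoforms.append(UtrIsoform(gene, f"{gene}.P", chrom, strand, *prox_iv))
        isoforms.append(UtrIsoform(gene, f"{gene}.D", chrom, strand, *dist_iv))

        truth.genes[gene] = {
            "chrom": chrom,
            "strand": strand,
            "apa_class": str(classes[i]),
            "contig_len": length,
            "utr_start_t": utr_start,
            "proximal_cleavage_t": cp,
            "distal_cleavage_t": cd,
            "proximal_pas": prox_iv[1] if strand == "+" else prox_iv[0],
            "distal_pas": dist_iv[1] if strand == "+" else dist_iv[0],
            "a_stretch_t": a_stretch_t,
            "designable_planted": i not in undesignable,
            "true_dpau": None,
        }
    return Genome(contigs), isoforms, truth


def simulate_abundance(truth: SimTruth, cfg: SimConfig, rng: np.random.Generator | None = None):
    """Replicate isoform TPM tables with planted dPAU shifts.

    Condition-A dPAU baselines are Beta(2,2)-distributed on the percent
    scale; lengthening/shortening genes shift by +/- ``effect_pts`` in
    condition B, clipped to [0, 100]. Replicate noise is Normal(0,
    ``noise_sd_pts``) on the dPAU percent scale before conversion to
    isoform TPMs, so the planted effect stays interpretable in percent
    points. Returns (abundance table, sample->condition mapping).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    cond_a, cond_b = cfg.conditions
    genes = sorted(truth.genes)
    base = rng.beta(2.0, 2.0, size=len(genes))
    for g, b in zip(genes, base):
        cls = truth.genes[g]["apa_class"]
        shift = {"lengthening": cfg.effect_pts, "shortening": -cfg.effect_pts, "null": 0.0}[cls]
        # Effect-gene baselines are drawn with headroom for the full shift,
        # so a planted effect really is effect_pts points; the [0, 100] clip
        # still guards replicate noise and user-configured larger effects.
        lo, hi = max(0.0, -shift), min(100.0, 100.0 - shift)
        hi = max(lo, hi)  # effects beyond 100 pts pin the baseline at a bound
        baseline = lo + b * (hi - lo)
        truth.genes[g]["true_dpau"] = {
            cond_a: float(np.clip(baseline, 0.0, 100.0)),
            cond_b: float(np.clip(baseline + shift, 0.0, 100.0)),
        }

    samples, groups = [], {}
    data = {}
    for cond in (cond_a, cond_b):
        for rep in range(1, cfg.replicates + 1):
            sample = f"{cond}_{rep}"
            samples.append(sample)
            groups[sample] = cond
            col = {}
            for g in genes:
                info = truth.genes[g]
                gene_tpm = float(rng.lognormal(np.log(cfg.depth_mean_tpm), cfg.depth_sigma))
                dpau = float(np.clip(info["true_dpau"][cond] + rng.normal(0, cfg.noise_sd_pts), 0, 100))
                tpm_d = gene_tpm * dpau / 100.0
                tpm_p = gene_tpm - tpm_d
                col[f"{g}.P"] = tpm_p
                col[f"{g}.D"] = tpm_d
            data[sample] = col
    abund = pd.DataFrame(data)
    if cfg.depth_model == "negbinom":
        # resample through a count layer with gene-length effective lengths
        lengths = np.array([600.0 if i.endswith(".P") else 3000.0 for i in abund.index])
        for s in abund.columns:
            mean_counts = abund[s].to_numpy() * lengths * cfg.nb_count_scale / 1000.0
            r = 1.0 / cfg.nb_dispersion
            p = r / (r + np.maximum(mean_counts, 1e-9))
            counts = rng.negative_binomial(r, p)
            abund[s] = counts_to_tpm(counts, lengths)
    elif cfg.depth_model != "lognormal":
        raise ValueError(f"unknown depth model {cfg.depth_model!r}")
    abund.index.name = "isoform_id"
    return abund, groups


# ---------------------------------------------------------------------------
# Long-read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    read_id: str
    gene: str
    chrom: str
    strand: str
    seq: str  # 5'->3' of the molecule (transcript orientation)
    aln_start: int  # genomic, 0-based half-open aligned span
    aln_end: int
    clip: str  # 3' soft clip, transcript orientation
    source_isoform: str | None  # 'proximal' | 'distal' | None for artifacts
    artifact: bool
    true_end_t: int  # transcript-coordinate aligned end


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def simulate_long_reads(
    genome: Genome,
    truth: SimTruth,
    cfg: SimConfig,
    isoform_mix: dict,
    rng: np.random.Generator | None = None,
    read_prefix: str = "read",
) -> list[SimRead]:
    """Oligo(dT)-primed reads for the genes in ``isoform_mix``.

    ``isoform_mix`` maps gene -> {'proximal': p, 'distal': q} with p+q = 1.
    Distal-isoform reads become internal-priming artifacts with probability
    ``internal_priming_rate`` when the gene carries a planted A-stretch: the
    aligned end falls at the A-stretch start and the 3' clip is an entirely
    genome-templated A-run (no untemplated tail). All other reads carry an
    untemplated poly(A) tail of at least ``tail_min`` nt.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    reads: list[SimRead] = []
    for gene in sorted(isoform_mix):
        mix = isoform_mix[gene]
        if not np.isclose(mix.get("proximal", 0) + mix.get("distal", 0), 1.0):
            raise ValueError(f"isoform mix for {gene} does not sum to 1")
        info = truth.genes[gene]
        chrom, strand, length = info["chrom"], info["strand"], info["contig_len"]
        g_seq = genome.seq(chrom)
        t_seq = g_seq if strand == "+" else revcomp(g_seq)
        u0 = info["utr_start_t"]
        for k in range(cfg.n_reads):
            rid = f"{read_prefix}_{gene}_{k:05d}"
            iso = "distal" if rng.random() < mix.get("distal", 0) else "proximal"
            artifact = (
                iso == "distal"
                and info["a_stretch_t"] is not None
                and rng.random() < cfg.internal_priming_rate
            )
            if artifact:
                end_t = info["a_stretch_t"][0]
                clip = "A" * int(rng.integers(8, A_STRETCH_LEN + 1))
                source = None
            else:
                pas_t = info["distal_cleavage_t"] if iso == "distal" else info["proximal_cleavage_t"]
                end_t = pas_t + int(rng.integers(-cfg.end_jitter, cfg.end_jitter + 1))
                tail_len = max(cfg.tail_min, int(round(rng.normal(cfg.tail_mean, cfg.tail_sd))))
                clip = "A" * tail_len
                source = iso
            start_t = u0
            if rng.random() < cfg.p_truncation:
                start_t = u0 + int(rng.integers(0, max(1, int(0.7 * (end_t - u0)))))
            aligned = _substitute(t_seq[start_t:end_t], cfg.substitution_rate, rng)
            if strand == "+":
                aln_start, aln_end = start_t, end_t
            else:
                aln_start, aln_end = length - end_t, length - start_t
            reads.append(
                SimRead(
                    read_id=rid,
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    seq=aligned + clip,
                    aln_start=aln_start,
                    aln_end=aln_end,
                    clip=clip,
                    source_isoform=source,
                    artifact=artifact,
                    true_end_t=end_t,
                )
            )
    truth.reads.extend(reads)
    return reads


def to_aligned_records(reads: list[SimRead]):
    """In-memory AlignedReadRecord view of simulated reads."""
    from .io_core import AlignedReadRecord

    out = []
    for r in reads:
        sam_seq = r.seq if r.strand == "+" else revcomp(r.seq)
        out.append(
            AlignedReadRecord(
                read_id=r.read_id,
                chrom=r.chrom,
                strand=r.strand,
                aln_start=r.aln_start,
                aln_end=r.aln_end,
                soft_clip_3p=r.clip,
                read_seq=sam_seq,
            )
        )
    return out


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth_sam(reads: list[SimRead], genome: Genome, path: str | Path) -> None:
    """Truth alignments as plain-text SAM (aligned span M, 3' tail soft-clipped)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": s.name, "LN": len(s)} for s in genome],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.aln_start
            a.mapping_quality = 60
            alen = r.aln_end - r.aln_start
            clip_n = len(r.clip)
            if r.strand == "+":
                a.flag = 0
                a.query_sequence = r.seq
                a.cigarstring = f"{alen}M{clip_n}S" if clip_n else f"{alen}M"
            else:
                a.flag = 16
                a.query_sequence = revcomp(r.seq)
                a.cigarstring = f"{clip_n}S{alen}M" if clip_n else f"{alen}M"
            out.write(a)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_ct(
    truth: SimTruth,
    cfg: SimConfig,
    gene_id: str,
    rng: np.random.Generator | None = None,
) -> list[CtRecord]:
    """Ct table for one gene: long-3'UTR and total-gene targets per sample.

    Ct = intercept - log2(expression) + Normal(0, ct_sd), so doubling the
    expression lowers the mean Ct by one cycle. The long-3'UTR target is
    driven by the distal-isoform TPM implied by the gene's true dPAU, the
    total target by the (condition-constant) gene TPM.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    info = truth.genes[gene_id]
    if info["true_dpau"] is None:
        raise ValueError("true dPAU unset; run simulate_abundance first")
    records = []
    for cond in cfg.conditions:
        expr = {
            "long_utr": cfg.depth_mean_tpm * info["true_dpau"][cond] / 100.0,
            "total_gene": cfg.depth_mean_tpm,
        }
        for s in range(1, cfg.replicates + 1):
            sample = f"{cond}_{s}"
            for target, e in expr.items():
                if e <= 0:
                    raise ValueError(f"non-positive expression for {target} in {cond}")
                for rep in range(1, cfg.ct_tech_reps + 1):
                    ct = cfg.ct_intercept - np.log2(e) + rng.normal(0, cfg.ct_sd)
                    records.append(CtRecord(sample, cond, target, rep, float(ct)))
    return records


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------


def simulate_all(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Run every simulator stage and write the fixture set to ``out_dir``."""
    from .io_core import write_abundance, write_utr_annotation
    from .qpcr_quant import write_ct_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, isoforms, truth = simulate_genome(cfg)
    genome.to_fasta(out / "genome.fa")
    write_utr_annotation(isoforms, out / "utrs.bed", dialect="BED12")
    abund, groups = simulate_abundance(truth, cfg)
    write_abundance(abund, out / "abundance.tsv")
    pd.Series(groups, name="condition").rename_axis("sample_id").to_csv(out / "groups.tsv", sep="\t")

    files = {
        "genome": "genome.fa",
        "annotation": "utrs.bed",
        "abundance": "abundance.tsv",
        "groups": "groups.tsv",
    }
    if truth.genes:
        verify_gene = sorted(truth.genes)[0]
        rng_reads = np.random.default_rng(cfg.seed + 2)
        wt = simulate_long_reads(
            genome, truth, cfg, {verify_gene: {"proximal": 0.5, "distal": 0.5}},
            rng=rng_reads, read_prefix="wt",
        )
        ko = simulate_long_reads(
            genome, truth, cfg, {verify_gene: {"proximal": 1.0, "distal": 0.0}},
            rng=rng_reads, read_prefix="ko",
        )
        write_fastq(wt, out / "reads_WT.fastq")
        write_fastq(ko, out / "reads_KO.fastq")
        write_truth_sam(wt, genome, out / "truth_WT.sam")
        write_truth_sam(ko, genome, out / "truth_KO.sam")
        ct = simulate_ct(truth, cfg, verify_gene)
        write_ct_table(ct, out / "ct.tsv")
        files.update(
            reads_wt="reads_WT.fastq", reads_ko="reads_KO.fastq",
            truth_wt="truth_WT.sam", truth_ko="truth_KO.sam", ct="ct.tsv",
            verify_gene=verify_gene,
        )

    truth_json = {
        "config": dataclasses.asdict(cfg),
        "genes": truth.genes,
        "n_reads": len(truth.reads),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, default=str)
    files["truth"] = "truth.json"
    return files
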