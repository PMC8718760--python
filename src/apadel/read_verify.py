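"""Targeted long-read 3'-end classification for isoform-knockout verification.

Oligo(dT)-primed cDNA reads end, after alignment, in a 3' soft clip that is
genuinely polyadenylated only if it is *untemplated*: clip bases that match
the genomic sequence continuing past the alignment end are treated as
templated and extend the 3' end before the tail is evaluated, so
genomically encoded A-stretches are never mistaken for tails. Reads without
an untemplated tail whose downstream genomic window is A-rich are flagged
as internal-priming artifacts. Remaining ends are assigned to the nearest
annotated poly(A) site within a tolerance; unassigned ends are clustered
to detect cryptic poly(A) site activation. A knockout is confirmed when
the edited sample retains (essentially) no distal calls and no cryptic
cluster, with the wild-type sample as positive control.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_core import AlignedReadRecord, Genome, UtrIsoform, distal_isoform, revcomp

MIN_UNTEMPLATED_TAIL = 10
MIN_TAIL_PURITY = 0.8
IP_WINDOW = 20
IP_A_FRAC = 0.6
IP_RUN = 6
ASSIGN_TOL = 30
CLUSTER_WINDOW = 30
CLUSTER_MIN_READS = 5
DISTAL_EPSILON = 0.01


@dataclass(frozen=True)
class PolyATail:
    """Evidence for an untemplated poly(A) tail in a 3' soft clip."""

    clip_len: int
    untemplated_len: int
    a_fraction: float  # A-fraction of the whole clip (0 for empty clip)
    is_polya: bool
    templated_ext: int  # clip prefix matching the genome, extends the 3' end


def extract_tail(read: AlignedReadRecord, genome: Genome) -> tuple[PolyATail, int]:
    """Classify the 3' soft clip and return (tail, extended 3'-end position).

    The longest clip prefix matching the genomic continuation past the
    alignment end is templated; the remainder is the candidate tail. A
    contig edge truncates the continuation, leaving the rest untemplated.
    """
    clip = read.soft_clip_3p.upper()
    if read.strand == "+":
        cont = genome.fetch(read.chrom, read.aln_end, read.aln_end + len(clip))
    else:
        cont = revcomp(genome.fetch(read.chrom, read.aln_start - len(clip), read.aln_start))
    m = 0
    while m < len(clip) and m < len(cont) and clip[m] == cont[m]:
        m += 1
    untemplated = clip[m:]
    a_frac = clip.count("A") / len(clip) if clip else 0.0
    tail_a_frac = untemplated.count("A") / len(untemplated) if untemplated else 0.0
    is_polya = len(untemplated) >= MIN_UNTEMPLATED_TAIL and tail_a_frac >= MIN_TAIL_PURITY
    tail = PolyATail(
        clip_len=len(clip),
        untemplated_len=len(untemplated),
        a_fraction=a_frac,
        is_polya=is_polya,
        templated_ext=m,
    )
    end_pos = read.aln_end + m if read.strand == "+" else read.aln_start - m
    return tail, end_pos


def flag_internal_priming(
    end_pos: int,
    chrom: str,
    strand: str,
    genome: Genome,
    tail: PolyATail,
    window: int = IP_WINDOW,
    a_frac_min: float = IP_A_FRAC,
    run_min: int = IP_RUN,
) -> bool:
    """True iff the read has no untemplated tail and the transcript-downstream
    genomic window is A-rich (fraction >= ``a_frac_min`` or a run of
    >= ``run_min`` consecutive A)."""
    if tail.is_polya:
        return False
    if strand == "+":
        win = genome.fetch(chrom, end_pos, end_pos + window)
    else:
        win = revcomp(genome.fetch(chrom, end_pos - window, end_pos))
    if not win:
        return False
    if win.count("A") / len(win) >= a_frac_min:
        return True
    return "A" * run_min in win


def assign_three_prime_end(
    end_pos: int, isoforms: list[UtrIsoform], tol: int = ASSIGN_TOL
) -> tuple[str, str | None]:
    """Assign a 3' end to the nearest annotated poly(A) site within ``tol``.

    Returns (call, isoform_id); call is 'proximal'/'distal' by 3' UTR
    length rank, 'unassigned' beyond tolerance. Exact distance ties go to
    the proximal site (conservative for knockout verification).
    """
    distal = distal_isoform(isoforms)
    ranked = sorted(
        isoforms,
        key=lambda iso: (abs(end_pos - iso.pas_pos), iso is distal, iso.isoform_id),
    )
    best = ranked[0]
    if abs(end_pos - best.pas_pos) > tol:
        return "unassigned", None
    label = "distal" if best is distal else "proximal"
    return label, best.isoform_id


@dataclass(frozen=True)
class ReadEndCall:
    read_id: str
    end_pos: int
    tail: PolyATail
    call: str  # proximal | distal | cryptic_candidate | internal_priming | unassigned
    matched_isoform_id: str | None


def classify_reads(
    reads: list[AlignedReadRecord],
    genome: Genome,
    isoforms: list[UtrIsoform],
    tol: int = ASSIGN_TOL,
    ip_window: int = IP_WINDOW,
    ip_a_frac: float = IP_A_FRAC,
    ip_run: int = IP_RUN,
) -> list[ReadEndCall]:
    """Per-read 3'-end classification; deterministic and read-order independent."""
    calls = []
    for read in reads:
        tail, end = extract_tail(read, genome)
        aligned_end = read.aln_end if read.strand == "+" else read.aln_start
        if flag_internal_priming(
            aligned_end, read.chrom, read.strand, genome, tail, ip_window, ip_a_frac, ip_run
        ):
            calls.append(ReadEndCall(read.read_id, aligned_end, tail, "internal_priming", None))
            continue
        label, iso = assign_three_prime_end(end, isoforms, tol)
        calls.append(ReadEndCall(read.read_id, end, tail, label, iso))
    return calls


def cluster_cryptic_ends(
    ends: list[int], window: int = CLUSTER_WINDOW, min_reads: int = CLUSTER_MIN_READS
) -> list[dict]:
    """Single-linkage clusters of unassigned 3' ends (gap <= ``window``).

    Clusters with >= ``min_reads`` members are reported at their modal
    position (smallest position on a count tie).
    """
    if not ends:
        return []
    ends = sorted(ends)
    clusters, current = [], [ends[0]]
    for e in ends[1:]:
        if e - current[-1] <= window:
            current.append(e)
        else:
            clusters.append(current)
            current = [e]
    clusters.append(current)
    out = []
    for members in clusters:
        if len(members) >= min_reads:
            counts = Counter(members)
            modal = min(counts, key=lambda pos: (-counts[pos], pos))
            out.append({"position": modal, "n_reads": len(members)})
    return out


@dataclass
class SampleSummary:
    counts: dict
    distal_fraction: float
    cryptic_clusters: list


@dataclass
class VerificationVerdict:
    samples: dict  # sample name -> SampleSummary
    long_loss_confirmed: bool | None
    cryptic_detected: bool
    control_failed: bool


def summarize_calls(
    calls: list[ReadEndCall],
    cluster_window: int = CLUSTER_WINDOW,
    cluster_min_reads: int = CLUSTER_MIN_READS,
) -> SampleSummary:
    counts = Counter(c.call for c in calls)
    assigned = counts.get("proximal", 0) + counts.get("distal", 0)
    if assigned == 0:
        raise ValueError("zero assigned reads in sample")
    clusters = cluster_cryptic_ends(
        [c.end_pos for c in calls if c.call == "unassigned"],
        window=cluster_window,
        min_reads=cluster_min_reads,
    )
    return SampleSummary(
        counts=dict(counts),
        distal_fraction=counts.get("distal", 0) / assigned,
        cryptic_clusters=clusters,
    )


def verify_deletion(
    wt_calls: list[ReadEndCall],
    ko_calls: list[ReadEndCall],
    epsilon: float = DISTAL_EPSILON,
    cluster_window: int = CLUSTER_WINDOW,
    cluster_min_reads: int = CLUSTER_MIN_READS,
) -> VerificationVerdict:
    """Knockout verdict from classified wild-type and edited-sample reads.

    The wild type must show both annotated 3' ends (positive control);
    otherwise the verdict is withheld with ``control_failed``. Long-isoform
    loss is confirmed iff the edited sample's distal fraction is
    <= ``epsilon`` and no cryptic cluster is detected in it.
    """
    wt = summarize_calls(wt_calls, cluster_window, cluster_min_reads)
    ko = summarize_calls(ko_calls, cluster_window, cluster_min_reads)
    control_ok = wt.counts.get("proximal", 0) > 0 and wt.counts.get("distal", 0) > 0
    cryptic = len(ko.cryptic_clusters) > 0
    confirmed: bool | None
    if not control_ok:
        confirmed = None
    else:
        confirmed = ko.distal_fraction <= epsilon and not cryptic
    return VerificationVerdict(
        samples={"WT": wt, "KO": ko},
        long_loss_confirmed=confirmed,
        cryptic_detected=cryptic,
        control_failed=not control_ok,
    )
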