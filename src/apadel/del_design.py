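"""Dual-sgRNA deletion design for distal poly(A) sites.

The strategy pairs one SpCas9 guide cutting transcript-upstream of the
distal poly(A) signal (PAS hexamer) with one cutting transcript-downstream
of the cleavage site and its downstream U/GU-rich element (DUE), so the
deletion removes both cis elements required for 3' end formation. Cas9
cuts bluntly 3 nt 5' of the NGG PAM; all deletion arithmetic follows from
the resulting insertion-point cut coordinates. The homology-directed
repair (HDR) donor carries both guide target sites (protospacer + PAM) at
its ends for in-cell linearization, 750-nt homology arms abutting the two
cuts, and a user-supplied selection cassette between them. Genotyping uses
a three-primer design: a common forward primer outside the left homology
arm, a reverse primer inside the deleted region (wild-type band) and a
reverse primer in the cassette (knock-in band), validated by exact-match
in-silico PCR.

Guide on-target quality uses a transparent rule-based surrogate score
(GC content and proximity to the cleavage site, with hard rejects for
poly-T stretches, extreme GC and long homopolymers), not a machine-learned
model; placement geometry is what the bulk feasibility analysis depends
on, and that is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import Genome, UtrIsoform, VALID_BASES, distal_isoform, group_by_gene, logger, revcomp

GUIDE_LEN = 20
PAM_LEN = 3
CUT_OFFSET_FROM_PAM = 3  # blunt cut 3 nt 5' of the PAM
DEFAULT_WINDOW = 150
DEFAULT_DUE_SPAN = 30
DEFAULT_ARM_LEN = 750
PAS_HEXAMERS = ("AATAAA", "ATTAAA")


class DesignError(ValueError):
    """Raised when no feasible design exists; message names the failing side."""


# ---------------------------------------------------------------------------
# Guide finding and scoring
# ---------------------------------------------------------------------------


@dataclass
class GuideCandidate:
    """A 20-nt protospacer with NGG PAM and its blunt-cut coordinate.

    ``cut_pos`` is an insertion-point (0-based, between-bases) genomic
    coordinate: a plus-strand protospacer at [p, p+20) with PAM [p+20, p+23)
    cuts at p+17; a minus-strand PAM at [s, s+3) with protospacer
    [s+3, s+23) cuts at s+6. ``offset`` is signed nt from the distal
    cleavage site, negative meaning transcript-upstream.
    """

    protospacer: str
    pam: str
    strand: str
    cut_pos: int
    offset: int | None = None
    score: float = 0.0
    reject_reasons: list = field(default_factory=list)


def find_guides(window: str, genomic_offset: int = 0) -> list[GuideCandidate]:
    """All 20-mer + NGG matches on both strands of ``window``.

    ``genomic_offset`` is the genomic coordinate of the window's first base;
    cut positions are reported genomically. Candidates containing N are
    skipped. Output ordered by (cut_pos, strand).
    """
    window = window.upper()
    bad = set(window) - VALID_BASES
    if bad:
        raise ValueError(f"window contains non-ACGTN bases: {sorted(bad)}")
    out: list[GuideCandidate] = []
    n = len(window)
    for p in range(0, n - 22):
        # plus strand: protospacer [p, p+20), PAM [p+20, p+23)
        if window[p + 21 : p + 23] == "GG":
            proto = window[p : p + 20]
            pam = window[p + 20 : p + 23]
            if "N" not in proto and "N" not in pam:
                out.append(
                    GuideCandidate(proto, pam, "+", genomic_offset + p + 17)
                )
        # minus strand: PAM [p, p+3) on minus => CC at [p, p+2) on plus
        if window[p : p + 2] == "CC":
            proto = revcomp(window[p + 3 : p + 23])
            pam = revcomp(window[p : p + 3])
            if "N" not in proto and "N" not in pam:
                out.append(
                    GuideCandidate(proto, pam, "-", genomic_offset + p + 6)
                )
    out.sort(key=lambda g: (g.cut_pos, g.strand))
    return out


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def score_guide(g: GuideCandidate, window_half_width: int = DEFAULT_WINDOW) -> float:
    """Rule-based surrogate on-target score in [0, 1].

    Hard rejects (score 0): a TTTT stretch (Pol III / U6 terminator),
    GC outside [0.25, 0.75], or any homopolymer of length >= 5. Otherwise
    the score rewards balanced GC and proximity to the cleavage site:
    0.5*(1 - |GC-0.5|/0.5) + 0.5*(1 - |offset|/window_half_width).
    """
    if g.offset is None:
        raise ValueError("guide offset from the cleavage site must be set before scoring")
    if abs(g.offset) > window_half_width:
        raise ValueError("guide outside the design window")
    reasons = []
    gc = (g.protospacer.count("G") + g.protospacer.count("C")) / len(g.protospacer)
    if "TTTT" in g.protospacer:
        reasons.append("polyT")
    if not 0.25 <= gc <= 0.75:
        reasons.append("gc_out_of_range")
    if _max_homopolymer(g.protospacer) >= 5:
        reasons.append("homopolymer")
    g.reject_reasons = reasons
    if reasons:
        g.score = 0.0
    else:
        g.score = 0.5 * (1 - abs(gc - 0.5) / 0.5) + 0.5 * (1 - abs(g.offset) / window_half_width)
    return g.score


# ---------------------------------------------------------------------------
# PAS hexamer and pair selection
# ---------------------------------------------------------------------------


def find_pas_hexamer(genome: Genome, chrom: str, strand: str, pas_pos: int) -> tuple[int, int] | None:
    """Genomic interval of the PAS hexamer 10-40 nt transcript-upstream of
    the cleavage site, searching AATAAA first and then ATTAAA; None if absent.
    """
    if strand == "+":
        region = genome.fetch(chrom, pas_pos - 40, pas_pos - 10)
        origin = max(0, pas_pos - 40)
        for hexamer in PAS_HEXAMERS:
            i = region.find(hexamer)
            if i >= 0:
                return (origin + i, origin + i + 6)
    else:
        region = revcomp(genome.fetch(chrom, pas_pos + 10, pas_pos + 40))
        end = min(len(genome.seq(chrom)), pas_pos + 40)
        for hexamer in PAS_HEXAMERS:
            i = region.find(hexamer)
            if i >= 0:
                # i nt in from the transcript-upstream (genomic right) edge
                return (end - i - 6, end - i)
    return None


def transcript_offset(cut_pos: int, pas_pos: int, strand: str) -> int:
    """Signed transcript-relative offset of a cut from the cleavage site."""
    return cut_pos - pas_pos if strand == "+" else pas_pos - cut_pos


@dataclass
class GuidePair:
    """An upstream/downstream guide pair and the deletion between the cuts."""

    up: GuideCandidate
    down: GuideCandidate
    deletion: tuple[int, int]
    deletion_size: int


def deletion_interval(pair_or_cuts) -> tuple[tuple[int, int], int]:
    """Half-open genomic interval between the two cut positions and its size."""
    if isinstance(pair_or_cuts, GuidePair):
        cuts = (pair_or_cuts.up.cut_pos, pair_or_cuts.down.cut_pos)
    else:
        cuts = tuple(pair_or_cuts)
    lo, hi = min(cuts), max(cuts)
    if lo == hi:
        raise ValueError("equal cut positions give an empty deletion")
    return (lo, hi), hi - lo


def select_guide_pair(
    candidates: Iterable[GuideCandidate],
    pas_pos: int,
    strand: str,
    pas_hexamer: tuple[int, int] | None = None,
    window_half_width: int = DEFAULT_WINDOW,
    due_span: int = DEFAULT_DUE_SPAN,
) -> GuidePair:
    """Pick the best-scoring feasible (upstream, downstream) guide pair.

    Upstream guides must cut transcript-5' of the PAS hexamer start (or,
    with no annotated hexamer, >= 20 nt upstream of the cleavage site);
    downstream guides must cut >= ``due_span`` nt transcript-3' of the
    cleavage site so the DUE is removed. The pair maximizes the summed
    surrogate score; ties prefer the smallest deletion, then the lowest
    cut coordinates.
    """
    if pas_hexamer is not None:
        hex_lo, hex_hi = pas_hexamer
        # transcript-upstream edge of the hexamer, as an offset from the pas
        hex_start_off = transcript_offset(hex_lo if strand == "+" else hex_hi, pas_pos, strand)
        up_limit = hex_start_off
    else:
        up_limit = -20

    ups, downs = [], []
    for g in candidates:
        g.offset = transcript_offset(g.cut_pos, pas_pos, strand)
        if abs(g.offset) > window_half_width:
            continue
        score_guide(g, window_half_width)
        if g.score <= 0:
            continue
        if g.offset <= up_limit:
            ups.append(g)
        elif g.offset >= due_span:
            downs.append(g)
    if not ups:
        raise DesignError("no upstream guide")
    if not downs:
        raise DesignError("no downstream guide")

    def key(pair):
        up, down = pair
        (_, size) = deletion_interval((up.cut_pos, down.cut_pos))
        return (-(up.score + down.score), size, min(up.cut_pos, down.cut_pos), max(up.cut_pos, down.cut_pos))

    up, down = min(((u, d) for u in ups for d in downs), key=key)
    interval, size = deletion_interval((up.cut_pos, down.cut_pos))
    return GuidePair(up=up, down=down, deletion=interval, deletion_size=size)


def design_deletion(
    genome: Genome,
    isoforms: list[UtrIsoform],
    window_half_width: int = DEFAULT_WINDOW,
    due_span: int = DEFAULT_DUE_SPAN,
) -> GuidePair:
    """Full per-gene design: distal isoform -> guide scan -> pair selection."""
    distal = distal_isoform(isoforms)
    pas = distal.pas_pos
    chrom = distal.chrom
    margin = window_half_width + GUIDE_LEN + PAM_LEN
    contig_len = len(genome.seq(chrom))
    if pas - margin < 0 or pas + margin > contig_len:
        raise DesignError("design window exceeds contig bounds")
    window = genome.fetch(chrom, pas - margin, pas + margin)
    cands = find_guides(window, genomic_offset=pas - margin)
    hexamer = find_pas_hexamer(genome, chrom, distal.strand, pas)
    return select_guide_pair(
        cands, pas, distal.strand, pas_hexamer=hexamer,
        window_half_width=window_half_width, due_span=due_span,
    )


# ---------------------------------------------------------------------------
# Bulk feasibility
# ---------------------------------------------------------------------------


@dataclass
class FeasibilityReport:
    """Per-gene designability rows plus recomputable summary statistics.

    Offsets are reported as positive magnitudes: nt upstream (up) and
    downstream (down) of the distal 3' end.
    """

    rows: pd.DataFrame
    summary: dict


def bulk_feasibility(
    annot: list[UtrIsoform],
    genome: Genome,
    window_half_width: int = DEFAULT_WINDOW,
    due_span: int = DEFAULT_DUE_SPAN,
) -> FeasibilityReport:
    """Run the design over every gene and summarize placement geometry."""
    rows = []
    for gene, isos in sorted(group_by_gene(annot).items()):
        row = {"gene_id": gene, "designable": False, "failure_reason": "",
               "up_offset_nt": np.nan, "down_offset_nt": np.nan, "deletion_size_nt": np.nan}
        try:
            pair = design_deletion(genome, isos, window_half_width, due_span)
            row.update(
                designable=True,
                up_offset_nt=-pair.up.offset,
                down_offset_nt=pair.down.offset,
                deletion_size_nt=pair.deletion_size,
            )
        except (DesignError, KeyError) as exc:
            row["failure_reason"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["designable", "failure_reason", "up_offset_nt", "down_offset_nt", "deletion_size_nt"]
    )
    ok = df[df["designable"]] if len(df) else df
    summary = {
        "n_genes": int(len(df)),
        "n_designable": int(len(ok)),
        "designable_fraction": float(len(ok) / len(df)) if len(df) else float("nan"),
        "up_offset_mean": float(ok["up_offset_nt"].mean()) if len(ok) else float("nan"),
        "up_offset_sd": float(ok["up_offset_nt"].std(ddof=1)) if len(ok) > 1 else 0.0 if len(ok) == 1 else float("nan"),
        "down_offset_mean": float(ok["down_offset_nt"].mean()) if len(ok) else float("nan"),
        "down_offset_sd": float(ok["down_offset_nt"].std(ddof=1)) if len(ok) > 1 else 0.0 if len(ok) == 1 else float("nan"),
        "deletion_size_mean": float(ok["deletion_size_nt"].mean()) if len(ok) else float("nan"),
        "deletion_size_sd": float(ok["deletion_size_nt"].std(ddof=1)) if len(ok) > 1 else 0.0 if len(ok) == 1 else float("nan"),
    }
    return FeasibilityReport(rows=df, summary=summary)


# ---------------------------------------------------------------------------
# HDR donor assembly
# ---------------------------------------------------------------------------


@dataclass
class DonorConstruct:
    """HDR donor: guide1 site+PAM, 750-nt left arm, cassette, 750-nt right
    arm, guide2 site+PAM, written 5'->3' in transcript orientation."""

    left_flank: str
    left_arm: str
    cassette: str
    right_arm: str
    right_flank: str
    junctions: list

    @property
    def full_seq(self) -> str:
        return self.left_flank + self.left_arm + self.cassette + self.right_arm + self.right_flank


def build_donor(
    genome: Genome,
    chrom: str,
    strand: str,
    pair: GuidePair,
    cassette: str,
    arm_len: int = DEFAULT_ARM_LEN,
) -> DonorConstruct:
    """Assemble the donor with homology arms abutting the two cuts exactly.

    Arms are taken in transcript orientation: the left arm is the ``arm_len``
    nt immediately transcript-5' of the upstream cut, the right arm the
    ``arm_len`` nt immediately transcript-3' of the downstream cut. No base
    of the deletion interval enters the arms or the cassette.
    """
    if not cassette:
        raise ValueError("cassette must be non-empty")
    cut_up, cut_down = pair.up.cut_pos, pair.down.cut_pos
    lo, hi = min(cut_up, cut_down), max(cut_up, cut_down)
    contig = genome.seq(chrom)
    if strand == "+":
        if lo - arm_len < 0 or hi + arm_len > len(contig):
            raise ValueError("insufficient flanking sequence for homology arms")
        left_arm = contig[lo - arm_len : lo]
        right_arm = contig[hi : hi + arm_len]
    else:
        if hi + arm_len > len(contig) or lo - arm_len < 0:
            raise ValueError("insufficient flanking sequence for homology arms")
        left_arm = revcomp(contig[hi : hi + arm_len])
        right_arm = revcomp(contig[lo - arm_len : lo])
    left_flank = pair.up.protospacer + pair.up.pam
    right_flank = pair.down.protospacer + pair.down.pam
    off = 0
    junctions = []
    for name, seg in [
        ("left_flank/left_arm", left_flank),
        ("left_arm/cassette", left_arm),
        ("cassette/right_arm", cassette),
        ("right_arm/right_flank", right_arm),
    ]:
        off += len(seg)
        junctions.append({"join": name, "position": off})
    return DonorConstruct(left_flank, left_arm, cassette, right_arm, right_flank, junctions)


def hdr_edit(genome: Genome, chrom: str, strand: str, deletion: tuple[int, int], cassette: str) -> Genome:
    """Simulated HDR outcome: the deletion interval replaced by the cassette.

    The cassette is supplied in transcript orientation and is inserted
    reverse-complemented for minus-strand loci.
    """
    lo, hi = deletion
    contig = genome.seq(chrom)
    ins = cassette if strand == "+" else revcomp(cassette)
    edited = contig[:lo] + ins + contig[hi:]
    from .io_core import GenomeSequence

    seqs = [GenomeSequence(chrom, edited) if s.name == chrom else s for s in genome]
    return Genome(seqs)


# ---------------------------------------------------------------------------
# Genotyping primers and in-silico PCR
# ---------------------------------------------------------------------------


def primer_tm(seq: str) -> float:
    """Wallace-rule melting temperature 2*(A+T) + 4*(G+C), for screening."""
    if not 8 <= len(seq) <= 40:
        raise ValueError("primer length must be in [8, 40]")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous base in primer {seq!r}")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def insilico_pcr(template: str, fwd: str, rev: str, max_len: int = 5000) -> list[dict]:
    """Exact-match PCR products on the plus strand of ``template``.

    The forward primer anneals as-is; the reverse primer anneals as its
    reverse complement downstream of the forward site. Product sizes are
    inclusive of both primers.
    """
    rev_site = revcomp(rev)
    products = []
    for f in _find_all(template, fwd):
        for r in _find_all(template, rev_site):
            if r >= f:
                size = r + len(rev_site) - f
                if size <= max_len:
                    products.append({"start": f, "end": r + len(rev_site), "size": size})
    return sorted(products, key=lambda p: (p["start"], p["end"]))


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i >= 0:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 25
    tm_range: tuple[float, float] = (57.0, 63.0)
    gc_range: tuple[float, float] = (0.40, 0.60)
    max_homopolymer: int = 4
    search_span: int = 300  # nt scanned for each primer's binding region
    min_amplicon: int = 100


@dataclass
class Primer:
    name: str
    seq: str
    position: int  # 0-based start of the binding site (locus or cassette coords)
    tm: float
    gc: float


@dataclass
class PrimerSet:
    fwd_common: Primer
    rev_wt: Primer
    rev_cassette: Primer
    wt_amplicon_size: int
    ki_amplicon_size: int


def _primer_ok(seq: str, c: PrimerConstraints) -> bool:
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    return (
        set(seq) <= set("ACGT")
        and c.gc_range[0] <= gc <= c.gc_range[1]
        and c.tm_range[0] <= primer_tm(seq) <= c.tm_range[1]
        and _max_homopolymer(seq) < c.max_homopolymer + 1
    )


def _scan_primer(region: str, region_origin: int, locus: str, c: PrimerConstraints, name: str) -> Primer:
    """First constraint-satisfying, locus-unique k-mer of the region."""
    for i in range(len(region)):
        for k in range(c.min_len, c.max_len + 1):
            if i + k > len(region):
                break
            cand = region[i : i + k]
            if not _primer_ok(cand, c):
                continue
            if len(_find_all(locus, cand)) + len(_find_all(locus, revcomp(cand))) != 1:
                continue
            gc = (cand.count("G") + cand.count("C")) / k
            return Primer(name, cand, region_origin + i, primer_tm(cand), gc)
    raise DesignError(f"no primer satisfying constraints in the {name} search region")


def design_genotyping_primers(
    locus: str,
    deletion: tuple[int, int],
    cassette: str,
    arm_len: int = DEFAULT_ARM_LEN,
    constraints: PrimerConstraints | None = None,
) -> PrimerSet:
    """Three-primer genotyping design on a transcript-oriented locus.

    ``locus`` is the wild-type genomic sequence in transcript orientation
    with ``deletion`` given in its coordinates. The common forward primer
    is placed 5' of the left homology arm so the knock-in band requires
    on-locus integration; the wild-type reverse primer binds inside the
    deleted region; the cassette reverse primer binds the cassette in
    reverse orientation. Band sizes come from exact-match in-silico PCR on
    the wild-type and HDR-edited locus.
    """
    c = constraints or PrimerConstraints()
    lo, hi = deletion
    if hi - lo < c.min_len:
        raise DesignError("deletion region too short for a wild-type reverse primer")
    arm_start = lo - arm_len
    if arm_start - c.search_span < 0:
        raise DesignError("insufficient sequence 5' of the left homology arm")
    edited = locus[:lo] + cassette + locus[hi:]

    fwd_region = locus[arm_start - c.search_span : arm_start]
    fwd = _scan_primer(fwd_region, arm_start - c.search_span, locus, c, "fwd_common")

    # rev_wt binds inside the deletion; its sequence is the reverse
    # complement of a plus-strand k-mer of the deleted interval.
    del_region = locus[lo:hi]
    rev_wt_site = _scan_primer(del_region, lo, locus, c, "rev_wt")
    rev_wt = Primer("rev_wt", revcomp(rev_wt_site.seq), rev_wt_site.position, rev_wt_site.tm, rev_wt_site.gc)

    cas_region = cassette[: min(len(cassette), c.search_span)]
    rev_cas_site = _scan_primer(cas_region, 0, edited, c, "rev_cassette")
    rev_cas = Primer(
        "rev_cassette", revcomp(rev_cas_site.seq), rev_cas_site.position, rev_cas_site.tm, rev_cas_site.gc
    )

    wt_products = insilico_pcr(locus, fwd.seq, rev_wt.seq)
    ki_products = insilico_pcr(edited, fwd.seq, rev_cas.seq)
    if len(wt_products) != 1 or len(ki_products) != 1:
        raise DesignError("genotyping primers do not give unique bands")
    wt_size, ki_size = wt_products[0]["size"], ki_products[0]["size"]
    if wt_size < c.min_amplicon or ki_size < c.min_amplicon:
        raise DesignError("predicted amplicon below the minimum size")
    return PrimerSet(fwd, rev_wt, rev_cas, wt_size, ki_size)
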