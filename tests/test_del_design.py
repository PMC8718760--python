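import numpy as np
import pytest

from apadel.del_design import (
    DesignError,
    GuideCandidate,
    PrimerConstraints,
    build_donor,
    bulk_feasibility,
    deletion_interval,
    design_deletion,
    design_genotyping_primers,
    find_guides,
    find_pas_hexamer,
    hdr_edit,
    insilico_pcr,
    primer_tm,
    score_guide,
    select_guide_pair,
)
from apadel.io_core import Genome, GenomeSequence, UtrIsoform, distal_isoform, group_by_gene, revcomp
from oracles import best_pair_oracle, guide_scan_oracle, surrogate_score_oracle


def _random_window(rng, n=300):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestFindGuides:
    def test_single_site_window(self):
        window = "ACGTACGTACGTACGTACGTAGG"
        (g,) = find_guides(window, genomic_offset=500)
        assert (g.protospacer, g.pam, g.strand, g.cut_pos) == (window[:20], "AGG", "+", 517)

    def test_pam_free_window_is_empty(self):
        assert find_guides("ATATATATATATATATATATATATAT") == []

    def test_non_dna_window_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            find_guides("ACGTACGTACGTACGTACGTAGX")

    def test_matches_exhaustive_scan_on_random_windows(self, rng):
        for _ in range(50):
            w = _random_window(rng)
            got = {(g.protospacer, g.pam, g.strand, g.cut_pos) for g in find_guides(w, 1000)}
            assert got == guide_scan_oracle(w, 1000)

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(20):
            w = _random_window(rng)
            fwd = find_guides(w)
            rev = find_guides(revcomp(w))
            assert len(fwd) == len(rev)
            assert sorted(g.protospacer for g in fwd) == sorted(g.protospacer for g in rev)
            assert {g.strand for g in fwd} == {
                {"+": "-", "-": "+"}[g.strand] for g in rev
            } or len(fwd) == 0


class TestScoreGuide:
    def _guide(self, proto, offset):
        g = GuideCandidate(proto, "AGG", "+", 0, offset=offset)
        return g

    def test_polyT_rejected(self):
        g = self._guide("ACGTTTTACGTACGTACGTA", 0)
        assert score_guide(g) == 0.0
        assert "polyT" in g.reject_reasons

    def test_formula_maximum(self):
        g = self._guide("ACGT" * 5, 0)  # GC = 10/20, no rejects
        assert score_guide(g) == pytest.approx(1.0)

    def test_hand_evaluated_score(self):
        proto = "GC" * 6 + "AT" * 4  # GC = 12/20 = 0.6
        g = self._guide(proto, 75)
        assert score_guide(g, window_half_width=150) == pytest.approx(0.65)
        assert score_guide(g, 150) == pytest.approx(
            surrogate_score_oracle(proto, 75, 150)
        )

    def test_homopolymer_and_gc_rejections(self):
        g = self._guide("ACGGGGGTAGCTAGCTAGCT", 0)
        assert score_guide(g) == 0.0 and "homopolymer" in g.reject_reasons
        g = self._guide("ATATATATATATATATATAT", 0)
        assert score_guide(g) == 0.0 and "gc_out_of_range" in g.reject_reasons


class TestDeletionInterval:
    def test_precise_107_bp_deletion(self):
        interval, size = deletion_interval((1000, 1107))
        assert interval == (1000, 1107) and size == 107

    def test_minimal_and_symmetric(self):
        assert deletion_interval((5, 6))[1] == 1
        assert deletion_interval((1107, 1000)) == deletion_interval((1000, 1107))

    def test_equal_cuts_rejected(self):
        with pytest.raises(ValueError):
            deletion_interval((7, 7))


class TestSelectGuidePair:
    def test_failure_names_missing_side(self, sim):
        truth, genome = sim["truth"], sim["genome"]
        gene = next(g for g in sorted(truth.genes) if truth.genes[g]["designable_planted"])
        info = truth.genes[gene]
        pas = info["distal_pas"]
        margin = 173
        window = genome.fetch(info["chrom"], pas - margin, pas + margin)
        cands = find_guides(window, pas - margin)
        upstream_only = [c for c in cands if (c.cut_pos - pas if info["strand"] == "+" else pas - c.cut_pos) < 0]
        with pytest.raises(DesignError, match="no downstream guide"):
            select_guide_pair(upstream_only, pas, info["strand"])

    def test_matches_brute_force_enumeration(self, sim):
        """The selected pair equals exhaustive enumeration over all feasible
        pairs under the same objective, for every designable gene."""
        truth, genome = sim["truth"], sim["genome"]
        checked = 0
        for gene in sorted(truth.genes):
            info = truth.genes[gene]
            isos = [i for i in sim["isoforms"] if i.gene_id == gene]
            pas = info["distal_pas"]
            margin = 173
            window = genome.fetch(info["chrom"], pas - margin, pas + margin)
            hexamer = find_pas_hexamer(genome, info["chrom"], info["strand"], pas)
            expected = best_pair_oracle(window, pas - margin, pas, info["strand"], hexamer)
            try:
                pair = design_deletion(genome, isos)
            except DesignError:
                assert expected is None
                continue
            assert expected is not None
            u, d = expected
            assert (pair.up.protospacer, pair.up.cut_pos) == (u[0], u[3])
            assert (pair.down.protospacer, pair.down.cut_pos) == (d[0], d[3])
            checked += 1
        assert checked >= 10

    def test_deletion_bounded_by_design_windows(self, sim):
        for gene, isos in group_by_gene(sim["isoforms"]).items():
            try:
                pair = design_deletion(sim["genome"], isos)
            except DesignError:
                continue
            assert 1 <= pair.deletion_size <= 303

    def test_strand_invariance(self, sim):
        """Designing on the reverse-complemented locus yields the same
        deletion size and transcript-relative offsets."""
        truth, genome = sim["truth"], sim["genome"]
        done = 0
        for gene in sorted(truth.genes)[:6]:
            info = truth.genes[gene]
            isos = [i for i in sim["isoforms"] if i.gene_id == gene]
            contig = genome.seq(info["chrom"])
            L = len(contig)
            flipped = Genome([GenomeSequence(info["chrom"], revcomp(contig))])
            flip_strand = "-" if info["strand"] == "+" else "+"
            flipped_isos = [
                UtrIsoform(i.gene_id, i.isoform_id, i.chrom, flip_strand, L - i.utr_end, L - i.utr_start)
                for i in isos
            ]
            try:
                fwd = design_deletion(genome, isos)
            except DesignError:
                with pytest.raises(DesignError):
                    design_deletion(flipped, flipped_isos)
                continue
            rev = design_deletion(flipped, flipped_isos)
            assert rev.deletion_size == fwd.deletion_size
            assert (rev.up.offset, rev.down.offset) == (fwd.up.offset, fwd.down.offset)
            done += 1
        assert done >= 4


class TestBulkFeasibility:
    def test_empty_annotation(self):
        rep = bulk_feasibility([], Genome([GenomeSequence("c", "ACGT" * 10)]))
        assert rep.summary["n_genes"] == 0 and len(rep.rows) == 0

    def test_designable_matches_planted_guides(self, sim):
        rep = bulk_feasibility(sim["isoforms"], sim["genome"])
        planted = {g for g, v in sim["truth"].genes.items() if v["designable_planted"]}
        designed = set(rep.rows.index[rep.rows["designable"]])
        # every gene with planted guides must be designable
        assert planted <= designed
        assert rep.summary["n_designable"] == len(designed)

    def test_single_gene_summary_sd_is_zero(self, sim):
        truth = sim["truth"]
        gene = next(g for g in sorted(truth.genes) if truth.genes[g]["designable_planted"])
        isos = [i for i in sim["isoforms"] if i.gene_id == gene]
        rep = bulk_feasibility(isos, sim["genome"])
        assert rep.summary["n_designable"] == 1
        assert rep.summary["deletion_size_sd"] == 0.0


@pytest.fixture(scope="module")
def designed_locus(sim, ):
    """One designable gene with its pair, cassette and donor, per strand."""
    rng = np.random.default_rng(7)
    cassette = "".join("ACGT"[i] for i in rng.integers(0, 4, 1200))
    out = {}
    for want in ("+", "-"):
        truth = sim["truth"]
        gene = next(
            g for g in sorted(truth.genes)
            if truth.genes[g]["designable_planted"] and truth.genes[g]["strand"] == want
        )
        isos = [i for i in sim["isoforms"] if i.gene_id == gene]
        pair = design_deletion(sim["genome"], isos)
        info = truth.genes[gene]
        out[want] = dict(gene=gene, info=info, pair=pair, cassette=cassette)
    return out


class TestDonor:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_structure_and_exact_arms(self, sim, designed_locus, strand):
        d = designed_locus[strand]
        donor = build_donor(sim["genome"], d["info"]["chrom"], strand, d["pair"], d["cassette"])
        assert len(donor.full_seq) == 23 + 750 + len(d["cassette"]) + 750 + 23
        contig = sim["genome"].seq(d["info"]["chrom"])
        lo, hi = d["pair"].deletion
        if strand == "+":
            assert donor.left_arm == contig[lo - 750 : lo]
            assert donor.right_arm == contig[hi : hi + 750]
        else:
            assert donor.left_arm == revcomp(contig[hi : hi + 750])
            assert donor.right_arm == revcomp(contig[lo - 750 : lo])

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_no_deletion_15mer_in_donor_body(self, sim, designed_locus, strand):
        """The donor's homology body (arms + cassette) contains no 15-mer of
        the deleted interval on either strand; the guide-site adapters at
        the donor ends deliberately span the cuts and are exempt."""
        d = designed_locus[strand]
        donor = build_donor(sim["genome"], d["info"]["chrom"], strand, d["pair"], d["cassette"])
        body = donor.left_arm + donor.cassette + donor.right_arm
        contig = sim["genome"].seq(d["info"]["chrom"])
        lo, hi = d["pair"].deletion
        deleted = contig[lo:hi]
        for i in range(len(deleted) - 14):
            kmer = deleted[i : i + 15]
            assert kmer not in body
            assert revcomp(kmer) not in body

    def test_empty_cassette_rejected(self, sim, designed_locus):
        d = designed_locus["+"]
        with pytest.raises(ValueError, match="cassette"):
            build_donor(sim["genome"], d["info"]["chrom"], "+", d["pair"], "")


class TestPrimerTm:
    def test_direct_formula(self):
        # 8-mer repeats of ATGC: Tm = 2*4 + 4*4 = 24 per 8 bases
        assert primer_tm("ATGCATGC") == 24.0
        assert primer_tm("ATGC" * 5) == 60.0  # 20-mer, 10 G/C, 10 A/T

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
            assert primer_tm(seq) == primer_tm(revcomp(seq))

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            primer_tm("ACGTNACGTN")


class TestInsilicoPcr:
    def test_absent_primer(self):
        assert insilico_pcr("A" * 200, "ACGTACGTACGTACGT", "GGCCGGCC") == []

    def test_hand_coordinate_arithmetic(self, rng):
        template = list("".join("ACGT"[i] for i in rng.integers(0, 4, 700)))
        fwd = "ACCGTTACGGATCCTAGCAT"
        rev = "TGGCATTGCCAATGGTCGAT"
        template[100:120] = fwd
        template[580:600] = revcomp(rev)
        (product,) = insilico_pcr("".join(template), fwd, rev)
        assert product == {"start": 100, "end": 600, "size": 500}

    def test_multiple_forward_sites(self, rng):
        template = list("".join("ACGT"[i] for i in rng.integers(0, 4, 900)))
        fwd = "ACCGTTACGGATCCTAGCAT"
        rev = "TGGCATTGCCAATGGTCGAT"
        template[50:70] = fwd
        template[300:320] = fwd
        template[700:720] = revcomp(rev)
        products = insilico_pcr("".join(template), fwd, rev)
        assert [p["size"] for p in products] == [670, 420]


class TestGenotypingPrimers:
    def _locus(self, sim, strand):
        truth = sim["truth"]
        gene = next(
            g for g in sorted(truth.genes)
            if truth.genes[g]["designable_planted"] and truth.genes[g]["strand"] == strand
        )
        isos = [i for i in sim["isoforms"] if i.gene_id == gene]
        pair = design_deletion(sim["genome"], isos)
        info = truth.genes[gene]
        contig = sim["genome"].seq(info["chrom"])
        lo, hi = pair.deletion
        if strand == "+":
            return contig, (lo, hi), info, pair
        return revcomp(contig), (len(contig) - hi, len(contig) - lo), info, pair

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_constraints_verified_independently(self, sim, designed_locus, strand):
        locus, deletion, info, pair = self._locus(sim, strand)
        cassette = designed_locus[strand]["cassette"]
        pset = design_genotyping_primers(locus, deletion, cassette)
        c = PrimerConstraints()
        for primer in (pset.fwd_common, pset.rev_wt, pset.rev_cassette):
            seq = primer.seq
            assert c.min_len <= len(seq) <= c.max_len
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert c.gc_range[0] <= gc <= c.gc_range[1]
            tm = 2 * (seq.count("A") + seq.count("T")) + 4 * (seq.count("G") + seq.count("C"))
            assert c.tm_range[0] <= tm <= c.tm_range[1]
            assert not any(b * (c.max_homopolymer + 1) in seq for b in "ACGT")
        # rev_wt binds strictly inside the deletion interval
        site = revcomp(pset.rev_wt.seq)
        start = locus.find(site)
        assert deletion[0] <= start and start + len(site) <= deletion[1]
        # fwd_common is 5' of the left homology arm
        assert pset.fwd_common.position + len(pset.fwd_common.seq) <= deletion[0] - 750
        assert pset.wt_amplicon_size >= 100 and pset.ki_amplicon_size >= 100

    def test_deletion_too_short(self, sim, designed_locus):
        locus, deletion, info, pair = self._locus(sim, "+")
        with pytest.raises(DesignError, match="too short"):
            design_genotyping_primers(locus, (deletion[0], deletion[0] + 10), designed_locus["+"]["cassette"])

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_hdr_closure_reproduces_predicted_bands(self, sim, designed_locus, strand):
        """Simulated HDR followed by in-silico PCR gives exactly the
        predicted knock-in band; the wild-type locus gives the WT band and
        the edited locus gives no WT band."""
        locus, deletion, info, pair = self._locus(sim, strand)
        cassette = designed_locus[strand]["cassette"]
        pset = design_genotyping_primers(locus, deletion, cassette)
        edited_genome = hdr_edit(sim["genome"], info["chrom"], strand, pair.deletion, cassette)
        edited = edited_genome.seq(info["chrom"])
        edited_t = edited if strand == "+" else revcomp(edited)
        ki = insilico_pcr(edited_t, pset.fwd_common.seq, pset.rev_cassette.seq)
        wt = insilico_pcr(locus, pset.fwd_common.seq, pset.rev_wt.seq)
        assert [p["size"] for p in ki] == [pset.ki_amplicon_size]
        assert [p["size"] for p in wt] == [pset.wt_amplicon_size]
        assert insilico_pcr(edited_t, pset.fwd_common.seq, pset.rev_wt.seq) == []
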