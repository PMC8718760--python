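"""Readers/writers, coordinate conventions, config and logging.

All genomic intervals are 0-based half-open throughout the package. BED is
read natively; GTF (1-based inclusive) is converted on read and write.
On the minus strand the isoform 3' end (cleavage site) maps to ``utr_start``;
"upstream"/"downstream" elsewhere in the package is transcript-relative.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
import yaml

logger = logging.getLogger("apadel")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def setup_logging(level: str = "INFO") -> None:
    """Route package logging to stderr at the requested level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


def load_config(path: str | Path) -> dict:
    """Load a structured (YAML) config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a config mapping, for reproducibility headers."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_run_header(version: str, cfg: Mapping | None, seed: int | None) -> None:
    """Emit the reproducibility header every CLI run writes."""
    logger.info(
        "apadel %s | config=%s | seed=%s",
        version,
        config_hash(cfg) if cfg else "none",
        seed,
    )


# ---------------------------------------------------------------------------
# Genome sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """A named reference sequence over the {A,C,G,T,N} alphabet."""

    name: str
    seq: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.name!r} is empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"sequence {self.name!r} has invalid bases: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


class Genome:
    """A set of uniquely named reference sequences with slice access."""

    def __init__(self, sequences: Iterable[GenomeSequence]):
        self._seqs: dict[str, GenomeSequence] = {}
        for s in sequences:
            if s.name in self._seqs:
                raise ValueError(f"duplicate sequence name {s.name!r}")
            self._seqs[s.name] = s

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self):
        return iter(self._seqs.values())

    def names(self) -> list[str]:
        return list(self._seqs)

    def seq(self, name: str) -> str:
        if name not in self._seqs:
            raise KeyError(f"reference {name!r} not in genome")
        return self._seqs[name].seq

    def fetch(self, name: str, start: int, end: int) -> str:
        """Slice [start, end) clipped to the contig; may be shorter at edges."""
        s = self.seq(name)
        return s[max(0, start) : max(0, min(len(s), end))]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from Bio import SeqIO

        return cls(
            GenomeSequence(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        )

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for s in self:
                fh.write(f">{s.name}\n")
                for i in range(0, len(s.seq), width):
                    fh.write(s.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 3' UTR isoform annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UtrIsoform:
    """One 3' UTR isoform of a gene with its genomic cleavage site.

    ``pas_pos`` is the 0-based coordinate of the isoform 3' end: ``utr_end``
    on the plus strand and ``utr_start`` on the minus strand.
    """

    gene_id: str
    isoform_id: str
    chrom: str
    strand: str
    utr_start: int
    utr_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.utr_start < self.utr_end:
            raise ValueError(
                f"{self.isoform_id}: utr_start {self.utr_start} must be < utr_end {self.utr_end}"
            )

    @property
    def pas_pos(self) -> int:
        return self.utr_end if self.strand == "+" else self.utr_start

    @property
    def utr_length(self) -> int:
        return self.utr_end - self.utr_start


def _check_unique(isoforms: list[UtrIsoform]) -> list[UtrIsoform]:
    seen = set()
    for iso in isoforms:
        key = (iso.gene_id, iso.isoform_id)
        if key in seen:
            raise ValueError(f"duplicate isoform id {iso.isoform_id!r} in gene {iso.gene_id!r}")
        seen.add(key)
    return isoforms


def parse_utr_annotation(path: str | Path, dialect: str = "BED12") -> list[UtrIsoform]:
    """Parse a 3' UTR isoform annotation (BED12 or GTF) into UtrIsoform records.

    BED names use ``gene|isoform``; GTF records carry ``gene_id`` and
    ``transcript_id`` attributes on ``three_prime_utr`` features.
    """
    dialect = dialect.upper()
    if dialect not in ("BED12", "GTF"):
        raise ValueError(f"unknown dialect {dialect!r}")
    isoforms: list[UtrIsoform] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "BED12":
                    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    strand = fields[5]
                    gene_id, isoform_id = name.split("|", 1)
                    isoforms.append(
                        UtrIsoform(gene_id, isoform_id, chrom, strand, start, end)
                    )
                else:
                    if len(fields) < 9 or fields[2] != "three_prime_utr":
                        continue
                    chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                    attrs = _parse_gtf_attrs(fields[8])
                    isoforms.append(
                        UtrIsoform(attrs["gene_id"], attrs["transcript_id"], chrom, strand, start, end)
                    )
            except (ValueError, IndexError, KeyError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    return _check_unique(isoforms)


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def write_utr_annotation(isoforms: Iterable[UtrIsoform], path: str | Path, dialect: str = "BED12") -> None:
    dialect = dialect.upper()
    with open(path, "w") as fh:
        for iso in isoforms:
            if dialect == "BED12":
                size = iso.utr_length
                fh.write(
                    "\t".join(
                        [
                            iso.chrom,
                            str(iso.utr_start),
                            str(iso.utr_end),
                            f"{iso.gene_id}|{iso.isoform_id}",
                            "0",
                            iso.strand,
                            str(iso.utr_start),
                            str(iso.utr_end),
                            "0,0,0",
                            "1",
                            f"{size},",
                            "0,",
                        ]
                    )
                    + "\n"
                )
            elif dialect == "GTF":
                attrs = f'gene_id "{iso.gene_id}"; transcript_id "{iso.isoform_id}";'
                fh.write(
                    "\t".join(
                        [
                            iso.chrom,
                            "apadel",
                            "three_prime_utr",
                            str(iso.utr_start + 1),
                            str(iso.utr_end),
                            ".",
                            iso.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def group_by_gene(isoforms: Iterable[UtrIsoform]) -> dict[str, list[UtrIsoform]]:
    genes: dict[str, list[UtrIsoform]] = {}
    for iso in isoforms:
        genes.setdefault(iso.gene_id, []).append(iso)
    return genes


def distal_isoform(isoforms: list[UtrIsoform]) -> UtrIsoform:
    """The longest-3'UTR isoform of a gene.

    Ties broken by the most distal genomic 3' end (strand-aware), then by
    lexicographic isoform id, so output ordering is deterministic.
    """

    def key(iso: UtrIsoform):
        distal_rank = iso.pas_pos if iso.strand == "+" else -iso.pas_pos
        return (-iso.utr_length, -distal_rank, iso.isoform_id)

    return min(isoforms, key=key)


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read an isoform x sample TPM table (TSV, first column isoform ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate isoform ids in {path}: {dups}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in abundance table {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing cells in abundance table {path}")
    if (df.values < 0).any():
        raise ValueError(f"negative abundance in {path}")
    df.index = df.index.astype(str)
    return df


def write_abundance(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="isoform_id")


# ---------------------------------------------------------------------------
# Long-read alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedReadRecord:
    """A primary long-read alignment with its 3' soft clip.

    ``soft_clip_3p`` always reads 5'->3' of the originating transcript: for
    minus-strand alignments it is the reverse complement of the clipped bases
    at the start of the stored (reference-orientation) sequence.
    """

    read_id: str
    chrom: str
    strand: str
    aln_start: int
    aln_end: int
    soft_clip_3p: str
    read_seq: str


def read_alignments(path: str | Path, genome: Genome | None = None) -> list[AlignedReadRecord]:
    """Read primary alignments from SAM/BAM, extracting strand-aware 3' clips."""
    records: list[AlignedReadRecord] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for aln in af:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                chrom = aln.reference_name
                if genome is not None and chrom not in genome:
                    raise ValueError(f"reference {chrom!r} absent from genome set")
                seq = aln.query_sequence or ""
                cig = aln.cigartuples or []
                strand = "-" if aln.is_reverse else "+"
                clip = ""
                if strand == "+" and cig and cig[-1][0] == 4:
                    n = cig[-1][1]
                    clip = seq[len(seq) - n :]
                elif strand == "-" and cig and cig[0][0] == 4:
                    n = cig[0][1]
                    clip = revcomp(seq[:n])
                else:
                    n = 0
                if n and len(clip) < n:
                    raise ValueError(
                        f"read {aln.query_name}: soft clip shorter than CIGAR-declared length"
                    )
                records.append(
                    AlignedReadRecord(
                        read_id=aln.query_name,
                        chrom=chrom,
                        strand=strand,
                        aln_start=aln.reference_start,
                        aln_end=aln.reference_end,
                        soft_clip_3p=clip,
                        read_seq=seq,
                    )
                )
    finally:
        pysam.set_verbosity(save)
    return records
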