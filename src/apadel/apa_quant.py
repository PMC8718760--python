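"""Poly(A) site usage (PAU) and distal PAU (dPAU) from isoform abundance.

PAU is the percent of a gene's TPM assigned to one 3' UTR isoform; dPAU is
the PAU of the longest-3'UTR (most distal) isoform. Genes with a single
annotated poly(A) site carry no APA signal and are dropped from the dPAU
matrix. PAU is NA for (gene, sample) cells with zero total TPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import UtrIsoform, distal_isoform, group_by_gene, logger


def counts_to_tpm(counts, eff_lengths) -> np.ndarray:
    """Convert read counts to TPM: 1e6 * (c_i/L_i) / sum_j (c_j/L_j)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(eff_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and eff_lengths must have equal length")
    if (counts < 0).any():
        raise ValueError("negative count")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return 1e6 * rate / total


@dataclass
class PauTable:
    """Per-isoform PAU (percent) and per-gene total TPM across samples."""

    pau: pd.DataFrame  # isoform x sample, percent, NaN where gene total is 0
    gene_totals: pd.DataFrame  # gene x sample, TPM
    gene_of: pd.Series  # isoform -> gene


@dataclass
class DpauMatrix:
    """Per-gene distal poly(A) site usage (percent) across samples."""

    dpau: pd.DataFrame  # gene x sample, percent
    distal_isoform_id: dict  # gene -> isoform id of the longest 3' UTR


def compute_pau(abund: pd.DataFrame, annot: list[UtrIsoform]) -> PauTable:
    """PAU_{i,s} = 100 * TPM_{i,s} / sum over the gene's isoforms."""
    gene_of = {iso.isoform_id: iso.gene_id for iso in annot}
    missing = [i for i in abund.index if i not in gene_of]
    if missing:
        raise ValueError(f"isoforms without gene assignment: {missing[:5]}")
    genes = pd.Series({i: gene_of[i] for i in abund.index}, name="gene_id")
    totals = abund.groupby(genes).sum()
    denom = totals.loc[genes.values].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pau = 100.0 * abund.to_numpy() / denom
    pau = pd.DataFrame(pau, index=abund.index, columns=abund.columns)
    pau[denom == 0] = np.nan
    return PauTable(pau=pau, gene_totals=totals, gene_of=genes)


def compute_dpau(pau: PauTable, annot: list[UtrIsoform]) -> DpauMatrix:
    """dPAU per multi-isoform gene: the PAU row of its distal isoform."""
    rows, distal_ids = {}, {}
    for gene, isos in sorted(group_by_gene(annot).items()):
        if len(isos) < 2:  # non-APA gene, single poly(A) site
            continue
        distal = distal_isoform(isos)
        if distal.isoform_id in pau.pau.index:
            rows[gene] = pau.pau.loc[distal.isoform_id]
            distal_ids[gene] = distal.isoform_id
    dpau = pd.DataFrame(rows).T
    dpau.index.name = "gene_id"
    return DpauMatrix(dpau=dpau, distal_isoform_id=distal_ids)


def filter_expressed(
    abund: pd.DataFrame,
    annot: list[UtrIsoform],
    min_tpm: float = 1.0,
    mode: str = "every_sample",
) -> set[str]:
    """Genes whose total TPM passes ``min_tpm`` in every sample (default).

    ``mode='mean'`` relaxes this to the across-sample mean.
    """
    if min_tpm < 0:
        raise ValueError("min_tpm must be >= 0")
    gene_of = {iso.isoform_id: iso.gene_id for iso in annot}
    genes = pd.Series({i: gene_of.get(i) for i in abund.index})
    if genes.isna().any():
        raise ValueError("isoform without gene assignment")
    totals = abund.groupby(genes).sum()
    if mode == "every_sample":
        keep = (totals >= min_tpm).all(axis=1)
    elif mode == "mean":
        keep = totals.mean(axis=1) >= min_tpm
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kept = set(totals.index[keep])
    logger.debug("expression filter kept %d/%d genes", len(kept), totals.shape[0])
    return kept
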