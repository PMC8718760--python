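"""Differential distal poly(A) site usage between two conditions.

Per gene, dPAU values of replicate samples are compared with a two-sided
two-sample t-test, p-values are Benjamini-Hochberg
adjusted, and genes are classified as 3' UTR lengthening (q <= alpha,
delta > 0), shortening (q <= alpha, delta < 0) or unchanged. The pooled
(Student) test is the default: the replicate design is balanced and small
(n = 3), where the Welch-Satterthwaite degrees of freedom collapse and
cost most of the power; Welch remains available via ``test="welch"`` for
unbalanced or heteroskedastic designs. A
pseudo-counted fold change (dPAU_B + eps)/(dPAU_A + eps) is reported but
not used as a gate. Also hosts the cross-system dPAU correlation and the
cassette-exon (rMATS-format) event filter / gene-set intersection used to
relate lengthening genes to alternative splicing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .apa_quant import DpauMatrix
from .io_core import logger

FOLD_CHANGE_EPS = 0.1  # percent points added to both means before the ratio


def two_sample_ttest(a, b, test: str = "student") -> tuple[float, float, bool]:
    """Two-sided two-sample t-test returning (t, p, degenerate).

    Zero within-group variance in both groups is handled explicitly:
    equal means give (0, 1), unequal means the forced limit (inf, 0) with
    the degenerate flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        # sign convention matches scipy's ttest_ind(a, b): positive when a > b
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0, True
    if test == "welch":
        t, p = stats.ttest_ind(a, b, equal_var=False)
    elif test == "student":
        t, p = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(t), float(p), False


def test_dpau(
    dpau: DpauMatrix | pd.DataFrame,
    groups: Mapping[str, str],
    condition_a: str | None = None,
    condition_b: str | None = None,
    test: str = "student",
) -> pd.DataFrame:
    """Per-gene two-sample test of dPAU between conditions A and B.

    Genes with NA dPAU in any used sample, or fewer than two usable
    replicates in a condition, are skipped with a logged count. ``delta``
    is mean(B) - mean(A) in percent points.
    """
    mat = dpau.dpau if isinstance(dpau, DpauMatrix) else dpau
    conds = sorted(set(groups.values()))
    if condition_a is None or condition_b is None:
        if len(conds) != 2:
            raise ValueError(f"need exactly 2 conditions, got {conds}")
        condition_a, condition_b = conds
    samples_a = [s for s in mat.columns if groups.get(s) == condition_a]
    samples_b = [s for s in mat.columns if groups.get(s) == condition_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per condition")

    rows = []
    n_skipped = 0
    for gene, row in mat.iterrows():
        a = row[samples_a].to_numpy(dtype=float)
        b = row[samples_b].to_numpy(dtype=float)
        if np.isnan(a).any() or np.isnan(b).any():
            n_skipped += 1
            continue
        t, p, degen = two_sample_ttest(a, b, test=test)
        mean_a, mean_b = a.mean(), b.mean()
        rows.append(
            {
                "gene_id": gene,
                "mean_dpau_A": mean_a,
                "mean_dpau_B": mean_b,
                "delta": mean_b - mean_a,
                "fold_change": (mean_b + FOLD_CHANGE_EPS) / (mean_a + FOLD_CHANGE_EPS),
                "t": t,
                "p_value": p,
                "degenerate_variance": degen,
            }
        )
    if n_skipped:
        logger.info("test_dpau: skipped %d genes with NA dPAU", n_skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "mean_dpau_A",
            "mean_dpau_B",
            "delta",
            "fold_change",
            "t",
            "p_value",
            "degenerate_variance",
        ],
    ).set_index("gene_id")


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to adjust_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_apa(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach BH q-values and lengthening/shortening/unchanged calls."""
    out = results.copy()
    out["q_value"] = adjust_fdr(out["p_value"].to_numpy())
    sig = out["q_value"] <= alpha
    out["apa_class"] = "unchanged"
    out.loc[sig & (out["delta"] > 0), "apa_class"] = "lengthening"
    out.loc[sig & (out["delta"] < 0), "apa_class"] = "shortening"
    return out


@dataclass(frozen=True)
class CorrelationResult:
    n_genes: int
    pearson_r: float
    p_value: float


def correlate_dpau(mean_dpau_x: Mapping[str, float], mean_dpau_y: Mapping[str, float]) -> CorrelationResult:
    """Pearson correlation of mean dPAU over the gene-name intersection."""
    shared = sorted(set(mean_dpau_x) & set(mean_dpau_y))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x = np.array([mean_dpau_x[g] for g in shared], dtype=float)
    y = np.array([mean_dpau_y[g] for g in shared], dtype=float)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(n_genes=len(shared), pearson_r=float(r), p_value=float(p))


@dataclass(frozen=True)
class SpliceEvent:
    """One cassette-exon event with its FDR and inclusion-level difference."""

    gene_id: str
    event_id: str
    fdr: float
    inc_level_diff: float

    def __post_init__(self):
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"fdr {self.fdr} outside [0,1]")


def read_splice_events(path: str | Path) -> list[SpliceEvent]:
    """Read an rMATS 4.x-style tab-separated event table.

    Uses the ``geneSymbol`` (fallback ``GeneID``), ``ID``, ``FDR`` and
    ``IncLevelDifference`` columns.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = "geneSymbol" if "geneSymbol" in df.columns else "GeneID"
    events = []
    for _, row in df.iterrows():
        events.append(
            SpliceEvent(
                gene_id=str(row[gene_col]).strip('"'),
                event_id=str(row.get("ID", len(events))),
                fdr=float(row["FDR"]),
                inc_level_diff=float(row["IncLevelDifference"]),
            )
        )
    return events


def filter_splice_events(
    events: Sequence[SpliceEvent], fdr_max: float = 0.05, min_abs_inc: float = 0.2
) -> list[SpliceEvent]:
    """High-confidence events: FDR < fdr_max and |IncLevelDiff| > min_abs_inc.

    Both inequalities are strict.
    """
    return [e for e in events if e.fdr < fdr_max and abs(e.inc_level_diff) > min_abs_inc]


def intersect_genesets(a, b) -> tuple[list[str], dict[str, int]]:
    """Sorted intersection of two gene-id sets with membership counts."""
    sa, sb = set(a), set(b)
    shared = sorted(sa & sb)
    return shared, {"n_a": len(sa), "n_b": len(sb), "n_shared": len(shared)}
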