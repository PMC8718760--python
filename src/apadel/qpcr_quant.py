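"""Relative expression from qPCR Ct tables by the ddCt method.

Technical replicate Cts are averaged per (sample, target) first; biological
samples are the units of the two-tailed t-test on dCt. Long-isoform
measurements normalize the long-3'UTR amplicon to the total-gene amplicon
of the same sample; marker-gene measurements normalize to a reference
gene. Fold change is 2^-ddCt versus the calibrator condition, whose own
fold is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .apa_diff import two_sample_ttest

CT_MIN, CT_MAX = 0.0, 45.0


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    condition: str
    target: str  # e.g. long_utr | total_gene | reference_gene | a gene name
    replicate: int
    ct: float

    def __post_init__(self):
        if not CT_MIN < self.ct < CT_MAX:
            raise ValueError(f"Ct {self.ct} outside ({CT_MIN}, {CT_MAX})")


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a TSV with columns sample_id, condition, target, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    return [
        CtRecord(str(r.sample_id), str(r.condition), str(r.target), int(r.replicate), float(r.ct))
        for r in df.itertuples()
    ]


def write_ct_table(records: list[CtRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


@dataclass
class RelativeExpression:
    per_sample: pd.DataFrame  # sample_id, condition, delta_ct
    per_condition: pd.DataFrame  # condition, mean/sd delta_ct, fold_change, p_value
    calibrator: str


def _mean_ct(records: list[CtRecord], target: str) -> pd.Series:
    rows = [(r.sample_id, r.condition, r.ct) for r in records if r.target == target]
    if not rows:
        raise ValueError(f"no Ct records for target {target!r}")
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "ct"])
    return df.groupby(["sample_id", "condition"])["ct"].mean()


def delta_delta_ct(
    records: list[CtRecord],
    target: str,
    reference: str,
    calibrator: str,
    test: str = "student",
) -> RelativeExpression:
    """ddCt analysis of ``target`` normalized to ``reference``.

    dCt_sample = mean Ct(target) - mean Ct(reference); ddCt per condition
    is the mean dCt minus the calibrator's mean dCt; fold = 2^-ddCt. The
    p-value per non-calibrator condition is a two-sided t-test of the
    per-sample dCt against the calibrator samples.
    """
    ct_t = _mean_ct(records, target)
    ct_r = _mean_ct(records, reference)
    missing = set(ct_r.index.get_level_values(0)) ^ set(ct_t.index.get_level_values(0))
    if missing:
        raise ValueError(f"samples missing a target measurement: {sorted(missing)}")
    dct = (ct_t - ct_r).reset_index().rename(columns={"ct": "delta_ct"})
    conditions = sorted(dct["condition"].unique())
    if calibrator not in conditions:
        raise ValueError(f"calibrator {calibrator!r} not among conditions {conditions}")
    sizes = dct.groupby("condition").size()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"conditions with < 2 samples (t-test impossible): {small}")

    cal_dct = dct.loc[dct["condition"] == calibrator, "delta_ct"].to_numpy()
    rows = []
    for cond in conditions:
        vals = dct.loc[dct["condition"] == cond, "delta_ct"].to_numpy()
        ddct = vals.mean() - cal_dct.mean()
        if cond == calibrator:
            fold, p = 1.0, np.nan
        else:
            fold = float(2.0 ** (-ddct))
            _, p, _ = two_sample_ttest(cal_dct, vals, test=test)
        rows.append(
            {
                "condition": cond,
                "n": len(vals),
                "mean_delta_ct": float(vals.mean()),
                "sd_delta_ct": float(vals.std(ddof=1)),
                "delta_delta_ct": float(ddct),
                "fold_change": fold,
                "p_value": p,
            }
        )
    return RelativeExpression(
        per_sample=dct, per_condition=pd.DataFrame(rows).set_index("condition"), calibrator=calibrator
    )


def relative_long_expression(
    records: list[CtRecord], calibrator: str, test: str = "student"
) -> RelativeExpression:
    """Long-3'UTR isoform expression normalized to total gene expression."""
    return delta_delta_ct(records, target="long_utr", reference="total_gene", calibrator=calibrator, test=test)
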