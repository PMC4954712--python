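"""Comparative-Ct (2^-ddCt) relative expression analysis.

Replicate structure follows the study design: three RNA extractions per
sample, each assayed in technical triplicate.  Technical replicates are
averaged first; each extraction then yields dCt = Ct(target) -
Ct(housekeeping); ddCt subtracts the calibrator sample's mean dCt, and
the fold change is 2^-ddCt (amplification efficiency fixed at 2, the
comparative-Ct assumption).  The calibrator's own fold is exactly 1.
Undetermined wells are handled explicitly so an undetectable transcript
is reported as "not detected" rather than a numeric fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = {"sample", "gene", "extraction", "tech_rep", "ct"}


@dataclass
class ExpressionResult:
    sample: str
    gene: str
    fold_change: Optional[float]  # None when not detected
    sd: Optional[float]
    p_value: Optional[float]
    detected: bool

    def __post_init__(self) -> None:
        if self.detected and (self.fold_change is None or self.fold_change <= 0):
            raise ValueError("detected genes must report a positive fold change")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    numeric = pd.to_numeric(table["ct"], errors="coerce")
    bad = table[~numeric.isna() & ((numeric <= 0) | (numeric > 45))]
    if len(bad):
        raise ValueError("Ct values must lie in (0, 45] or be the undetermined sentinel")
    return table.assign(ct_num=numeric)


def _extraction_means(table: pd.DataFrame, sample: str, gene: str) -> pd.Series:
    """Mean Ct per extraction after averaging technical replicates.
    Extractions mixing undetermined and numeric wells are dropped with a
    warning; fully undetermined extractions are dropped silently (they
    carry no signal)."""
    sub = table[(table["sample"] == sample) & (table["gene"] == gene)]
    means = {}
    for ext, grp in sub.groupby("extraction"):
        n_undet = grp["ct_num"].isna().sum()
        if n_undet == 0:
            means[ext] = grp["ct_num"].mean()
        elif n_undet < len(grp):
            warnings.warn(
                f"{sample}/{gene} extraction {ext}: mixed undetermined and "
                "numeric wells; extraction dropped",
                stacklevel=2,
            )
    return pd.Series(means, dtype=float)


def detect_undetermined(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Per-sample detection report for ``gene``: a sample is flagged
    not-detected when every well carries the undetermined sentinel."""
    table = _validate(table)
    rows = []
    for sample, grp in table[table["gene"] == gene].groupby("sample"):
        all_undet = grp["ct_num"].isna().all()
        rows.append((sample, gene, not all_undet))
    return pd.DataFrame(rows, columns=["sample", "gene", "detected"])


def ddct(
    table: pd.DataFrame,
    target: str,
    housekeeping: str,
    calibrator: str,
    equal_var: bool = True,
) -> list[ExpressionResult]:
    """Comparative-Ct fold changes of ``target`` relative to the
    ``calibrator`` sample, normalized to ``housekeeping``.

    Per extraction: dCt = mean tech-rep Ct(target) - mean tech-rep
    Ct(housekeeping); fold = 2^-(mean dCt - mean dCt of the calibrator);
    the SD is over extraction-level folds and the p value is a two-sample
    t test of extraction-level folds against the calibrator (Welch with
    ``equal_var=False``).
    """
    table = _validate(table)
    samples = list(dict.fromkeys(table["sample"]))
    if housekeeping not in set(table["gene"]):
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from the table")
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} absent from the table")

    dcts: dict[str, pd.Series] = {}
    detected: dict[str, bool] = {}
    for sample in samples:
        hk = _extraction_means(table, sample, housekeeping)
        if hk.empty:
            raise ValueError(f"housekeeping gene undetected in sample {sample!r}")
        tg = _extraction_means(table, sample, target)
        detected[sample] = not tg.empty
        if detected[sample]:
            common = tg.index.intersection(hk.index)
            dcts[sample] = tg[common] - hk[common]

    if not detected.get(calibrator, False):
        raise ValueError(f"target undetected in calibrator sample {calibrator!r}")
    cal_dct = dcts[calibrator]
    cal_mean = float(cal_dct.mean())
    cal_folds = np.power(2.0, -(cal_dct.to_numpy() - cal_mean))

    results = []
    for sample in samples:
        if not detected[sample]:
            results.append(ExpressionResult(sample, target, None, None, None, False))
            continue
        ddct_ext = dcts[sample].to_numpy() - cal_mean
        folds = np.power(2.0, -ddct_ext)
        fold = float(2.0 ** -(float(dcts[sample].mean()) - cal_mean))
        sd = float(np.std(folds, ddof=1)) if folds.size > 1 else None
        p = None
        if sample != calibrator and folds.size > 1 and cal_folds.size > 1:
            if folds.std() == 0 and cal_folds.std() == 0:
                p = 1.0 if np.isclose(folds.mean(), cal_folds.mean()) else 0.0
            else:
                p = float(stats.ttest_ind(folds, cal_folds, equal_var=equal_var).pvalue)
        results.append(ExpressionResult(sample, target, fold, sd, p, True))
    return results


def results_table(results: list[ExpressionResult]) -> pd.DataFrame:
    rows = [
        (r.sample, r.gene,
         r.fold_change if r.detected else "not detected",
         r.sd, r.p_value, r.detected)
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["sample", "gene", "fold_change", "sd", "p_value", "detected"]
    )
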