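"""Two-group differential expression of miRNAs (responders vs non-responders).

Implements the classical screening step: per-miRNA two-sample t-test
(Student pooled-variance by default, Welch optional) with a fold-change
filter.  Selection uses the raw p-value, as is conventional for this kind
of screen; Benjamini–Hochberg FDR is reported alongside for reuse but does
not enter the selection rule.

Input is a miRNA × sample expression matrix, assumed log2-normalized by
default (microarray series matrices from GEO are distributed this way), so
the fold-change threshold ``|FC| > f`` is applied as ``|log2FC| > log2(f)``.
A ``scale="linear"`` switch handles linear-intensity matrices.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import normalize_mirna_id

__all__ = [
    "GROUP_NON_RESPONDER",
    "GROUP_RESPONDER",
    "ExpressionMatrix",
    "fold_change",
    "read_expression",
    "select_de",
    "two_sample_t",
    "write_de_table",
]

logger = logging.getLogger(__name__)

GROUP_RESPONDER = "responder"
GROUP_NON_RESPONDER = "non_responder"
_VALID_GROUPS = {GROUP_RESPONDER, GROUP_NON_RESPONDER}
_VALID_SCALES = {"log2", "linear"}


@dataclass
class ExpressionMatrix:
    """miRNA × sample expression values with a two-level sample labelling.

    ``values`` rows are normalized miRNA IDs (unique), columns sample IDs;
    every sample carries a group label and both groups are non-empty.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ValueError(f"scale must be one of {sorted(_VALID_SCALES)}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated miRNA IDs after collapsing: {dupes}")
        unlabelled = [s for s in self.values.columns if s not in self.groups]
        if unlabelled:
            raise ValueError(f"samples without group label: {unlabelled}")
        bad = {s: g for s, g in self.groups.items() if g not in _VALID_GROUPS}
        if bad:
            raise ValueError(f"invalid group labels (expected "
                             f"{sorted(_VALID_GROUPS)}): {bad}")
        for group in _VALID_GROUPS:
            if not self.samples_in_group(group):
                raise ValueError(f"group '{group}' has no samples")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)


def read_expression(
    path: str | Path,
    group_file: str | Path,
    scale: str = "log2",
    alias_table: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (first column = miRNA IDs, header = samples)
    plus a two-column sample→group TSV.

    Rows with any missing value are dropped with a counted warning
    (complete-case analysis; no imputation).  miRNA IDs are normalized and
    duplicate rows collapsed by per-sample mean.  Each group must contain
    at least two samples for the t-test to be defined.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    frame = frame.apply(pd.to_numeric, errors="coerce")

    n_before = len(frame)
    frame = frame.dropna(axis=0, how="any")
    if len(frame) < n_before:
        logger.warning("dropped %d rows with missing values from %s",
                       n_before - len(frame), path)

    frame.index = [normalize_mirna_id(str(i), alias_table) for i in frame.index]
    if frame.index.duplicated().any():
        n_dup = int(frame.index.duplicated().sum())
        logger.warning("collapsed %d duplicate miRNA rows by mean in %s",
                       n_dup, path)
        frame = frame.groupby(level=0, sort=False).mean()

    raw_groups = pd.read_csv(group_file, sep="\t", header=None,
                             names=["sample", "group"], dtype=str, comment="#")
    if len(raw_groups) and raw_groups.iloc[0, 0].strip().lower() == "sample":
        raw_groups = raw_groups.iloc[1:]
    groups = {
        str(row["sample"]).strip(): str(row["group"]).strip()
        for _, row in raw_groups.iterrows()
    }

    missing = [s for s in frame.columns if s not in groups]
    if missing:
        raise ValueError(f"samples in matrix absent from group file: {missing}")
    extra = [s for s in groups if s not in frame.columns]
    if extra:
        logger.warning("group file lists %d samples not in the matrix: %s",
                       len(extra), extra)
        groups = {s: g for s, g in groups.items() if s in frame.columns}
    for group in _VALID_GROUPS:
        n = sum(1 for g in groups.values() if g == group)
        if n < 2:
            raise ValueError(
                f"group '{group}' has {n} samples; at least 2 required "
                "for a two-sample t-test"
            )
    return ExpressionMatrix(frame, groups, scale)


def two_sample_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "student",
) -> float:
    """Two-sided two-sample t-test p-value.

    ``variant="student"`` uses the pooled-variance statistic with
    ``nA + nB − 2`` degrees of freedom; ``"welch"`` uses the
    Welch–Satterthwaite approximation.  Degenerate inputs follow the
    conventions: both groups constant and equal → p = 1; both constant but
    different → p = 0 (the limit of a vanishing-variance shift).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN in t-test input")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in {"student", "welch"}:
        raise ValueError(f"unknown t-test variant '{variant}'")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    result = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(result.pvalue)


def fold_change(mean_a: float, mean_b: float, scale: str = "log2") -> tuple[float, float]:
    """(linear fold-change, log2 fold-change) of group a over group b.

    On log2-scale input the log2 fold-change is the difference of means;
    on linear input it is the log of the ratio (both means must be
    strictly positive).  Group a is the responder group by convention.
    """
    if scale == "log2":
        log2_fc = float(mean_a) - float(mean_b)
        return 2.0 ** log2_fc, log2_fc
    if scale == "linear":
        if mean_a <= 0 or mean_b <= 0:
            raise ValueError(
                "linear-scale fold change requires strictly positive means; "
                "supply log2-scale input instead"
            )
        fc = float(mean_a) / float(mean_b)
        return fc, math.log2(fc)
    raise ValueError(f"scale must be one of {sorted(_VALID_SCALES)}")


def select_de(
    expr: ExpressionMatrix,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    variant: str = "student",
) -> pd.DataFrame:
    """Differential-expression table with the selection flag.

    One row per miRNA with group means, fold-change, two-sided p-value,
    BH FDR, and ``selected = (p < p_threshold) and (|log2FC| >
    log2(fc_threshold))``.  Rows where both groups are constant get a
    ``zero_variance`` QC flag.  Sorted by p ascending, miRNA ID tiebreak.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    resp = expr.samples_in_group(GROUP_RESPONDER)
    nonresp = expr.samples_in_group(GROUP_NON_RESPONDER)
    if len(resp) < 2 or len(nonresp) < 2:
        raise ValueError("each group needs at least 2 samples")

    a = expr.values[resp].to_numpy(dtype=float)
    b = expr.values[nonresp].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("expression matrix contains missing values; "
                         "drop incomplete rows first")

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance rows trigger a scipy precision warning; their
        # p-values are overwritten by the degenerate-case conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
        pvals = np.asarray(result.pvalue, dtype=float)

    degenerate = (var_a == 0.0) & (var_b == 0.0)
    pvals[degenerate & (mean_a == mean_b)] = 1.0
    pvals[degenerate & (mean_a != mean_b)] = 0.0
    qc = np.where(degenerate, "zero_variance", "")

    if expr.scale == "log2":
        log2_fc = mean_a - mean_b
        fc = 2.0 ** log2_fc
    else:
        if (mean_a <= 0).any() or (mean_b <= 0).any():
            raise ValueError(
                "linear-scale data with non-positive group means; "
                "supply log2-scale input instead"
            )
        fc = mean_a / mean_b
        log2_fc = np.log2(fc)

    bh_fdr = multipletests(pvals, method="fdr_bh")[1]
    selected = (pvals < p_threshold) & (np.abs(log2_fc) > math.log2(fc_threshold))

    table = pd.DataFrame(
        {
            "mirna_id": expr.mirna_ids,
            "mean_responder": mean_a,
            "mean_nonresponder": mean_b,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "bh_fdr": bh_fdr,
            "selected": selected,
            "qc": qc,
        }
    )
    table = table.sort_values(["p_value", "mirna_id"], kind="mergesort")
    return table.reset_index(drop=True)


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
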