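"""Threshold-cycle (Ct) quantification for qPCR confirmation experiments.

Relative expression follows the comparative Ct method with amplification
efficiency fixed at 2 (perfect doubling per cycle): replicate Ct values are
averaged on the Ct scale, normalized against a reference gene
(delta-Ct = mean Ct target - mean Ct reference), and expressed as
2**(-delta-Ct). Fold changes between conditions are ratios of relative
expressions, i.e. 2**(-delta-delta-Ct). Group comparisons use Welch's
two-sample t-test, by default on the log scale (delta-Ct), since
2**(-delta-Ct) is log-normal-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParseError, ValidationError

__all__ = [
    "CtTable",
    "read_ct_table",
    "delta_ct",
    "relative_expression",
    "fold_change",
    "GroupComparison",
    "compare_groups",
]

_CT_MAX = 45.0


@dataclass
class CtTable:
    """Long-format qPCR measurements: one row per (sample, gene, replicate)."""

    frame: pd.DataFrame  # columns: sample, gene, replicate, ct

    def __post_init__(self) -> None:
        required = ["sample", "gene", "replicate", "ct"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns {missing}")
        ct = pd.to_numeric(self.frame["ct"], errors="coerce")
        if ct.isna().any():
            raise ParseError("non-numeric Ct value in table")
        if ((ct <= 0) | (ct > _CT_MAX)).any():
            bad = self.frame.loc[(ct <= 0) | (ct > _CT_MAX)]
            raise ValidationError(
                f"Ct values must lie in (0, {_CT_MAX}]; offending rows:\n{bad}"
            )
        self.frame = self.frame.assign(ct=ct.astype(float))

    def genes(self) -> list[str]:
        return sorted(self.frame["gene"].unique())

    def samples(self) -> list[str]:
        return list(pd.unique(self.frame["sample"]))

    def mean_ct(self, gene: str) -> pd.Series:
        """Replicate-averaged Ct per sample for one gene."""
        sub = self.frame[self.frame["gene"] == gene]
        return sub.groupby("sample", sort=False)["ct"].mean()

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> CtTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})
    except Exception as exc:
        raise ParseError(f"{path}: could not read Ct TSV: {exc}") from exc
    return CtTable(df)


def delta_ct(ct: CtTable, target_gene: str, reference_gene: str) -> pd.Series:
    """Per-sample delta-Ct = mean Ct(target) - mean Ct(reference)."""
    t = ct.mean_ct(target_gene)
    r = ct.mean_ct(reference_gene)
    if t.empty:
        raise ValidationError(f"no Ct rows for target gene {target_gene!r}")
    missing = sorted(set(t.index) - set(r.index))
    if missing:
        raise ValidationError(
            f"reference gene {reference_gene!r} missing for samples {missing}"
        )
    out = t - r.reindex(t.index)
    out.name = "delta_ct"
    return out


def relative_expression(ct: CtTable, target_gene: str, reference_gene: str) -> pd.Series:
    """Per-sample relative expression 2**(-delta-Ct)."""
    out = np.power(2.0, -delta_ct(ct, target_gene, reference_gene))
    out.name = "relative_expression"
    return out


def fold_change(treated, control):
    """Paired fold change = treated relative expression / control relative
    expression = 2**(-delta-delta-Ct)."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape:
        raise ValidationError("treated/control values must be paired (same shape)")
    if np.any(c == 0):
        raise ValidationError("zero control relative expression; fold change undefined")
    return t / c


@dataclass(frozen=True)
class GroupComparison:
    p: float
    t_stat: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


def compare_groups(values_a, values_b, on_log_scale: bool = True) -> GroupComparison:
    """Welch two-sample t-test between groups of relative expressions.

    When ``on_log_scale`` the test runs on log2(values) — equivalently on
    -delta-Ct — which is the default since relative expressions are
    log-normal-like; otherwise on the raw values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    if on_log_scale:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValidationError("log-scale comparison requires positive values")
        a, b = np.log2(a), np.log2(b)
    t_stat, p = sps.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(p):  # identical constant groups -> t = 0/0
        t_stat, p = 0.0, 1.0
    return GroupComparison(
        p=float(p),
        t_stat=float(t_stat),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
    )
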