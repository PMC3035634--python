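"""Gene-level follow-up for a screened set: per-gene tests and direction calls.

The per-gene test is the single-gene reduction of the set-level mixed model
(group fixed; batch random when more than one batch), so gene tables and set
screens share one model family. With a single batch this is exactly the
pooled two-sample t-test. Direction is the sign of the raw case - control
mean difference on the log2 scale ("up" = higher in cases).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import SetLookupError, ValidationError
from .io import ExpressionMatrix, GeneSetCollection, SampleMetadata
from .model import ModelSpec, fit_gene_set_model

__all__ = ["GeneLevelResult", "test_gene", "table_for_set", "write_gene_table"]


@dataclass(frozen=True)
class GeneLevelResult:
    gene: str
    direction: str  # "up" | "down" | "none"
    p: float
    delta: float  # case mean - control mean, log2 scale


def test_gene(
    gene: str,
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    spec: ModelSpec = ModelSpec(),
) -> GeneLevelResult:
    """Test one gene for a group difference via the singleton-set reduction."""
    y = matrix.gene_row(gene)  # raises SetLookupError if absent
    if meta.samples != matrix.sample_ids:
        meta = meta.reorder(matrix.sample_ids)
    res = fit_gene_set_model([gene], matrix, meta, spec, min_size=1, set_name=gene)
    case = meta.case_mask
    delta = float(y[case].mean() - y[~case].mean())
    direction = "up" if delta > 0 else ("down" if delta < 0 else "none")
    return GeneLevelResult(gene=gene, direction=direction, p=res.raw_p, delta=delta)


def table_for_set(
    set_name: str,
    collection: GeneSetCollection,
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    spec: ModelSpec = ModelSpec(),
    alpha: float = 0.05,
) -> list[GeneLevelResult]:
    """Per-gene table for one set: member genes with p <= alpha, ascending p
    (ties broken by gene name). ``alpha`` is an unadjusted reporting
    threshold, not a family-wise inferential claim."""
    if set_name not in collection:
        raise SetLookupError(f"unknown gene set {set_name!r}")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    measured = set(matrix.gene_ids)
    rows = [
        test_gene(g, matrix, meta, spec)
        for g in collection[set_name].genes
        if g in measured
    ]
    rows = [r for r in rows if r.p <= alpha]
    rows.sort(key=lambda r: (r.p, r.gene))
    return rows


def write_gene_table(rows: list[GeneLevelResult], path) -> None:
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "direction": [r.direction for r in rows],
            "p": [f"{r.p:.4g}" for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)
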