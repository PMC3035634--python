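"""End-to-end orchestration: ingest -> screen -> outputs, plus the
row-standardized heat-map matrix export.

``run_screen`` writes three artifacts into the output directory:

* ``screen.tsv`` — the human table (p-values at 4 significant digits)
* ``screen_full.tsv`` — the same table at full precision
* ``manifest.json`` — config echo, package/library versions and every
  warning raised during the run; the manifest alone suffices to re-run and
  reproduce a screen byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SetLookupError, ValidationError
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    read_expression,
    read_gmt,
)
from .model import ModelSpec, ScreenTable, screen_gene_sets

logger = logging.getLogger("mmgsa")

__all__ = ["RunConfig", "run_screen", "export_heatmap_matrix"]


@dataclass
class RunConfig:
    expression: str
    metadata: str
    gmt: str
    out_dir: str
    model: ModelSpec = field(default_factory=ModelSpec)
    min_size: int = 5
    alpha: float = 0.05
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "mmgsa": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def run_screen(config: RunConfig) -> tuple[ScreenTable, dict]:
    """Execute restrict -> per-set fit -> FDR -> sorted table, write outputs
    and a run manifest. Returns (table, manifest)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("reading expression %s / metadata %s", config.expression, config.metadata)
    matrix, meta = read_expression(config.expression, config.metadata)
    logger.info("reading gene sets %s", config.gmt)
    collection = read_gmt(config.gmt)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = screen_gene_sets(
            collection, matrix, meta, spec=config.model, min_size=config.min_size
        )
    warn_messages = [str(w.message) for w in caught]
    for msg in warn_messages:
        logger.warning("%s", msg)

    screen_path = out_dir / "screen.tsv"
    full_path = out_dir / "screen_full.tsv"
    table.write(screen_path, full_precision=False)
    table.write(full_path, full_precision=True)

    manifest = {
        "config": config.to_dict(),
        "versions": _versions(),
        "n_sets_screened": len(table),
        "n_sets_converged": int(sum(r.converged for r in table.results)),
        "warnings": warn_messages,
        "outputs": {"screen": str(screen_path), "screen_full": str(full_path)},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return table, manifest


def export_heatmap_matrix(
    set_name: str,
    collection: GeneSetCollection,
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
) -> pd.DataFrame:
    """Row-standardized submatrix of a set for external heat-map plotting.

    Each gene row gets mean 0 / SD 1; zero-SD rows are emitted as zeros with
    a warning. Columns are ordered controls first, then cases (stable within
    group).
    """
    if set_name not in collection:
        raise SetLookupError(f"unknown gene set {set_name!r}")
    if meta.samples != matrix.sample_ids:
        meta = meta.reorder(matrix.sample_ids)
    sub = matrix.subset_genes(collection[set_name].genes)
    if sub.n_genes == 0:
        raise ValidationError(f"set {set_name!r} has no measured genes")

    values = sub.values.astype(float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, keepdims=True)
    flat = sds[:, 0] == 0.0
    sds[flat] = 1.0
    z = (values - means) / sds
    if np.any(flat):
        flat_genes = [g for g, f in zip(sub.gene_ids, flat) if f]
        warnings.warn(f"constant gene rows emitted as zeros: {flat_genes}")
        z[flat] = 0.0

    order = np.concatenate(
        [np.nonzero(~meta.case_mask)[0], np.nonzero(meta.case_mask)[0]]
    )
    cols = [sub.sample_ids[i] for i in order]
    return pd.DataFrame(z[:, order], index=sub.gene_ids, columns=cols)
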