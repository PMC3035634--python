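"""Readers, writers and container types for expression matrices, sample
metadata and gene set collections.

File dialects
-------------
* Expression: TSV, first column ``gene`` (unique symbols), remaining columns
  one per sample, log2-scale values.
* Metadata: TSV with header ``sample  group  batch  subject``; ``group`` is
  ``case`` or ``control`` (control is always the reference level, so a
  positive group effect means higher expression in cases).
* Gene sets: MSigDB-style GMT — one set per line, tab-separated
  ``name<TAB>description<TAB>gene1<TAB>gene2...``. Comment lines are not
  part of the dialect. Gene identifiers are matched case-sensitively after
  whitespace stripping; no alias resolution is attempted.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

GROUP_LEVELS = ("control", "case")

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "restrict_to_measured",
    "read_expression",
    "write_expression",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples.

    Invariants: finite values, unique gene and sample identifiers, matching
    shapes. Size floors for model fitting (>=4 samples, >=2 per group) are
    enforced at fit time, not here, so single-gene slices remain legal.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        g, s = self.values.shape
        if g != len(self.gene_ids) or s != len(self.sample_ids):
            raise ValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes / {len(self.sample_ids)} samples"
            )
        if g == 0 or s == 0:
            raise ValidationError("expression matrix must be non-empty")
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValidationError(f"duplicate gene identifiers: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample identifiers: {sorted(dup_s)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        from .errors import SetLookupError

        if gene not in self._gene_index:
            raise SetLookupError(f"gene {gene!r} not in expression matrix")
        return self.values[self._gene_index[gene]]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Submatrix for ``genes`` (matrix row order preserved; unknowns skipped)."""
        wanted = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample group/batch/subject labels, aligned to a sample order."""

    samples: list[str]
    group: np.ndarray  # str array of "case"/"control"
    batch: np.ndarray
    subject: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.group = np.asarray([str(g) for g in self.group], dtype=object)
        self.batch = np.asarray([str(b) for b in self.batch], dtype=object)
        self.subject = np.asarray([str(s) for s in self.subject], dtype=object)
        n = len(self.samples)
        for name, arr in (("group", self.group), ("batch", self.batch), ("subject", self.subject)):
            if len(arr) != n:
                raise ValidationError(f"metadata column {name!r} has length {len(arr)}, expected {n}")
        dup = _duplicates(self.samples)
        if dup:
            raise ValidationError(f"duplicate sample identifiers in metadata: {sorted(dup)}")
        bad = sorted(set(self.group) - set(GROUP_LEVELS))
        if bad:
            raise ValidationError(f"group labels must be 'case'/'control'; got {bad}")
        counts = {lvl: int(np.sum(self.group == lvl)) for lvl in GROUP_LEVELS}
        for lvl, c in counts.items():
            if c < 2:
                raise ValidationError(f"need >=2 samples in group {lvl!r}, found {c}")
        # each subject belongs to exactly one group
        subj_groups: dict[str, str] = {}
        for s, g in zip(self.subject, self.group):
            if subj_groups.setdefault(s, g) != g:
                raise ValidationError(f"subject {s!r} appears in more than one group")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def case_mask(self) -> np.ndarray:
        return self.group == "case"

    def reorder(self, sample_order: list[str]) -> "SampleMetadata":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_order if s not in pos]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        idx = [pos[s] for s in sample_order]
        return SampleMetadata(
            [self.samples[i] for i in idx], self.group[idx], self.batch[idx], self.subject[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "group": self.group, "batch": self.batch, "subject": self.subject}
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        dup = _duplicates(self.genes)
        if dup:
            raise ValidationError(f"gene set {self.name!r} has duplicate genes: {sorted(dup)}")

    @property
    def size(self) -> int:
        return len(self.genes)


class GeneSetCollection(Mapping):
    """Ordered mapping set_name -> :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._sets:
                raise ValidationError(f"duplicate gene set name {gs.name!r}")
            self._sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return list(self._sets.items()) == list(other._sets.items())

    def sets(self) -> list[GeneSet]:
        return list(self._sets.values())


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (MSigDB dialect).

    Each line: ``name<TAB>description<TAB>gene...``. Duplicate genes within a
    line are deduplicated keeping the first occurrence; empty trailing fields
    are ignored. A line with fewer than 3 fields is a :class:`ParseError`
    naming the line number; a duplicate set name is a :class:`ValidationError`.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line == "":
                continue
            fields = line.split("\t")
            name = fields[0].strip()
            genes: list[str] = []
            gseen: set[str] = set()
            for tok in fields[2:]:
                g = tok.strip()
                if g == "" or g in gseen:
                    continue
                gseen.add(g)
                genes.append(g)
            if len(fields) < 3 or not genes:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, fields[1].strip(), tuple(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in collection.sets():
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def restrict_to_measured(
    collection: GeneSetCollection, measured: Iterable[str], min_size: int = 5
) -> GeneSetCollection:
    """Intersect every set with the measured gene universe and drop sets with
    fewer than ``min_size`` surviving genes. Idempotent."""
    if min_size < 2:
        raise ValidationError(f"min_size must be >= 2, got {min_size}")
    universe = set(measured)
    if not universe:
        raise ValidationError("measured gene universe is empty")
    kept: list[GeneSet] = []
    for gs in collection.sets():
        genes = tuple(g for g in gs.genes if g in universe)
        if len(genes) >= min_size:
            kept.append(GeneSet(gs.name, gs.description, genes))
    return GeneSetCollection(kept)


# ---------------------------------------------------------------------------
# Expression TSV + metadata TSV
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, meta_path: str | Path
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read an expression TSV and its metadata TSV and cross-validate them.

    Metadata rows are re-ordered to the matrix column order. Samples present
    in only one of the two files raise a :class:`ValidationError` listing the
    offenders.
    """
    path, meta_path = Path(path), Path(meta_path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: could not read expression TSV: {exc}") from exc
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"{path}: duplicated gene rows: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric expression cell: {exc}") from exc

    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = ["sample", "group", "batch", "subject"]
    missing_cols = [c for c in required if c not in meta_df.columns]
    if missing_cols:
        raise ParseError(f"{meta_path}: missing metadata columns {missing_cols}")

    matrix_samples = [str(c) for c in df.columns]
    meta_samples = list(meta_df["sample"])
    only_matrix = sorted(set(matrix_samples) - set(meta_samples))
    only_meta = sorted(set(meta_samples) - set(matrix_samples))
    if only_matrix or only_meta:
        parts = []
        if only_matrix:
            parts.append(f"in matrix but not metadata: {only_matrix}")
        if only_meta:
            parts.append(f"in metadata but not matrix: {only_meta}")
        raise ValidationError("sample mismatch: " + "; ".join(parts))

    meta = SampleMetadata(
        meta_samples,
        meta_df["group"].to_numpy(),
        meta_df["batch"].to_numpy(),
        meta_df["subject"].to_numpy(),
    ).reorder(matrix_samples)
    matrix = ExpressionMatrix([str(g) for g in df.index], matrix_samples, values)
    return matrix, meta


def write_expression(
    matrix: ExpressionMatrix, meta: SampleMetadata, path: str | Path, meta_path: str | Path
) -> None:
    df = matrix.to_dataframe()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6f")
    meta.to_dataframe().to_csv(meta_path, sep="\t", index=False)
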