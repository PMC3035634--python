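"""Synthetic data with exactly the covariance and effect structure the mixed
model assumes, plus ground-truth labels, so every pipeline stage is testable
without any external download.

For each gene set an orthonormal G x K_true loading matrix E is drawn and

    y_gs = baseline + delta * I[case(s)] * I[set non-null] + b_batch(s)
           + u_s + sum_k a_sk E_gk + eps_gs

with b ~ N(0, batch_sd^2), u ~ N(0, subject_sd^2), a_sk ~ N(0, factor_sds_k^2)
and eps ~ N(0, residual_sd^2). Gene sets are disjoint by construction; sample
batches are assigned round-robin within each group so group and batch stay
balanced. A single seeded RNG stream makes outputs bit-identical per seed.

Defaults mirror a small two-batch case-control microarray cohort (8 cases vs
4 controls) with realistic log2-scale magnitudes; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleMetadata,
    write_expression,
    write_gmt,
)
from .qpcr import CtTable

__all__ = ["SimulationConfig", "TruthLabels", "simulate_dataset", "simulate_qpcr", "write_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    n_case: int = 8
    n_control: int = 4
    n_batches: int = 2
    batch_sd: float = 0.2
    subject_sd: float = 0.3
    residual_sd: float = 0.5
    K_true: int = 2
    factor_sds: tuple[float, ...] = (0.5, 0.3)
    n_sets: int = 20
    genes_per_set: int = 20
    frac_nonnull: float = 0.1
    delta: float = 1.0
    baseline_mean: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_case < 2:
            problems.append(f"n_case must be >= 2 (got {self.n_case})")
        if self.n_control < 2:
            problems.append(f"n_control must be >= 2 (got {self.n_control})")
        if self.n_batches < 1:
            problems.append(f"n_batches must be >= 1 (got {self.n_batches})")
        if self.genes_per_set < 2:
            problems.append(f"genes_per_set must be >= 2 (got {self.genes_per_set})")
        if self.n_sets < 1:
            problems.append(f"n_sets must be >= 1 (got {self.n_sets})")
        if not 0.0 <= self.frac_nonnull <= 1.0:
            problems.append(f"frac_nonnull must be in [0, 1] (got {self.frac_nonnull})")
        if self.K_true < 0:
            problems.append(f"K_true must be >= 0 (got {self.K_true})")
        if len(self.factor_sds) != self.K_true:
            problems.append(
                f"factor_sds must have length K_true={self.K_true} "
                f"(got {len(self.factor_sds)})"
            )
        for name in ("batch_sd", "subject_sd", "residual_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0 (got {getattr(self, name)})")
        if any(s < 0 for s in self.factor_sds):
            problems.append("factor_sds must all be >= 0")
        if self.K_true > self.genes_per_set:
            problems.append("K_true cannot exceed genes_per_set")
        if problems:
            raise ValidationError("invalid simulation config: " + "; ".join(problems))


@dataclass
class TruthLabels:
    """Ground truth for power/FDR checks: per-set null status and effect,
    the global variance components, and the drawn factor loadings."""

    is_nonnull: dict  # set_name -> bool
    delta: dict  # set_name -> float (0.0 for null sets)
    variance_components: dict  # batch/subject/residual/factor SDs
    loadings: dict  # set_name -> (G x K_true) orthonormal array


def _orthonormal_loadings(rng: np.random.Generator, G: int, K: int) -> np.ndarray:
    if K == 0:
        return np.empty((G, 0))
    M = rng.standard_normal((G, K))
    Q, _ = np.linalg.qr(M)
    return Q[:, :K]


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, GeneSetCollection, TruthLabels]:
    """Generate (matrix, metadata, collection, truth) under ``config``.

    Deterministic per seed: two calls with identical config give
    byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_ctrl, n_case = config.n_control, config.n_case
    n = n_ctrl + n_case
    samples = [f"ctrl{i + 1:02d}" for i in range(n_ctrl)] + [
        f"case{i + 1:02d}" for i in range(n_case)
    ]
    group = np.array(["control"] * n_ctrl + ["case"] * n_case, dtype=object)
    # round-robin within each group keeps group/batch balanced
    batch = np.array(
        [f"B{i % config.n_batches + 1}" for i in range(n_ctrl)]
        + [f"B{i % config.n_batches + 1}" for i in range(n_case)],
        dtype=object,
    )
    subject = np.array(samples, dtype=object)  # cross-sectional: 1 sample/subject
    case_ind = (group == "case").astype(float)

    n_nonnull = int(round(config.frac_nonnull * config.n_sets))
    nonnull_idx = set(
        rng.choice(config.n_sets, size=n_nonnull, replace=False).tolist()
    )

    batch_effects = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    batch_codes = np.array([int(b[1:]) - 1 for b in batch])
    subject_effects = rng.normal(0.0, config.subject_sd, size=n)
    sample_shift = batch_effects[batch_codes] + subject_effects  # shared by all sets

    G = config.genes_per_set
    factor_sds = np.asarray(config.factor_sds, dtype=float)

    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    sets: list[GeneSet] = []
    is_nonnull: dict = {}
    deltas: dict = {}
    loadings: dict = {}
    for j in range(config.n_sets):
        name = f"SET{j + 1:04d}"
        genes = tuple(f"{name}_G{k + 1:03d}" for k in range(G))
        E = _orthonormal_loadings(rng, G, config.K_true)
        a = rng.normal(0.0, 1.0, size=(n, config.K_true)) * factor_sds
        eps = rng.normal(0.0, config.residual_sd, size=(G, n))
        nonnull = j in nonnull_idx
        shift = config.delta * case_ind if nonnull else 0.0
        block = config.baseline_mean + sample_shift + shift + E @ a.T + eps
        gene_ids.extend(genes)
        blocks.append(block)
        sets.append(GeneSet(name, "synthetic gene set", genes))
        is_nonnull[name] = bool(nonnull)
        deltas[name] = float(config.delta) if nonnull else 0.0
        loadings[name] = E

    matrix = ExpressionMatrix(gene_ids, samples, np.vstack(blocks))
    meta = SampleMetadata(samples, group, batch, subject)
    truth = TruthLabels(
        is_nonnull=is_nonnull,
        delta=deltas,
        variance_components={
            "batch_sd": config.batch_sd,
            "subject_sd": config.subject_sd,
            "residual_sd": config.residual_sd,
            "factor_sds": list(config.factor_sds),
        },
        loadings=loadings,
    )
    return matrix, meta, GeneSetCollection(sets), truth


def simulate_qpcr(
    n_case: int,
    n_control: int,
    delta_dct: float,
    sd: float,
    seed: int,
    *,
    base_dct: float = 5.0,
    target_gene: str = "TARGET",
    reference_gene: str = "ACTB",
    n_replicates: int = 3,
) -> CtTable:
    """Simulate a triplicate Ct table for one target/reference gene pair.

    Reference Ct ~ N(20, 0.2); the target's per-sample delta-Ct ~
    N(base_dct, sd), shifted by ``delta_dct`` in cases; replicate Ct values
    jittered N(0, 0.1). Deterministic per seed.
    """
    if n_case < 2 or n_control < 2:
        raise ValidationError("need >= 2 samples per group")
    if sd <= 0:
        raise ValidationError(f"sd must be > 0, got {sd}")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [("control", f"ctrl{i + 1:02d}") for i in range(n_control)] + [
        ("case", f"case{i + 1:02d}") for i in range(n_case)
    ]
    for grp, sample in samples:
        ref_ct = rng.normal(20.0, 0.2)
        dct = rng.normal(base_dct, sd) + (delta_dct if grp == "case" else 0.0)
        tgt_ct = ref_ct + dct
        for gene, mean_ct in ((reference_gene, ref_ct), (target_gene, tgt_ct)):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "replicate": rep,
                        "ct": mean_ct + rng.normal(0.0, 0.1),
                    }
                )
    return CtTable(pd.DataFrame(rows))


def write_dataset(
    out_dir,
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    collection: GeneSetCollection,
    truth: TruthLabels | None = None,
) -> dict:
    """Write a complete ready-to-screen directory (expression.tsv,
    metadata.tsv, sets.gmt[, truth.json]); returns the path map."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "gmt": out / "sets.gmt",
    }
    write_expression(matrix, meta, paths["expression"], paths["metadata"])
    write_gmt(collection, paths["gmt"])
    if truth is not None:
        paths["truth"] = out / "truth.json"
        payload = {
            "is_nonnull": truth.is_nonnull,
            "delta": truth.delta,
            "variance_components": truth.variance_components,
        }
        paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
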