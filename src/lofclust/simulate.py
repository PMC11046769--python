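"""Resampling null for positional clustering.

Simulated gene variant sets are drawn from the empirical pool of relative
positions of all observed variants (all classes pooled), with per-gene
variant counts matched to the observed pLoF counts.  Each replicate redraws
every gene; projecting the replicate profiles through the fitted clustering
model yields (a) the false-positive rate at which genes of a given variant
count land in non-uniform clusters by chance, and (b) an empirical p-value
for the observed number of non-uniform genes,

    p = (1 + #{replicates with count >= observed}) / (n_reps + 1),

which is strictly positive and super-uniform under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .cluster import PositionClusterer

__all__ = [
    "PositionPool",
    "SimulationResult",
    "simulate_genes",
    "fpr_by_count",
    "empirical_enrichment_p",
    "run_null_simulation",
]


@dataclass(frozen=True)
class PositionPool:
    """Pool of relative positions in [0, 1) of all observed variants."""

    relative_positions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.relative_positions, dtype=float)
        if arr.size == 0:
            raise ValidationError("position pool is empty")
        if np.any((arr < 0) | (arr >= 1)):
            raise ValidationError("pool positions must lie in [0, 1)")
        object.__setattr__(self, "relative_positions", arr)

    @classmethod
    def from_variants(
        cls,
        variants: pd.DataFrame,
        models: Mapping,
    ) -> "PositionPool":
        """Pool the relative positions of every variant of every class."""
        known = variants["transcript_id"].isin(models.keys())
        df = variants[known]
        L = df["transcript_id"].map({t: m.cds_length for t, m in models.items()})
        rel = (df["cds_pos"].to_numpy(float) - 1) / L.to_numpy(float)
        return cls(rel)


@dataclass
class SimulationResult:
    """Outcome of a resampling-null run."""

    n_reps: int
    per_rep_nonuniform_fraction: np.ndarray
    per_rep_nonuniform_count: np.ndarray
    per_count_fpr: pd.DataFrame
    empirical_p: float | None
    seed: int | None
    observed_nonuniform: int | None = None
    per_gene_counts: dict = field(default_factory=dict)


def _quintile_counts(rel: np.ndarray) -> np.ndarray:
    """Per-row quintile count vectors for an (m, n) relative-position array."""
    q = np.floor(5 * rel).astype(np.int64)  # 0..4
    m = rel.shape[0]
    flat = q + 5 * np.arange(m)[:, None]
    return np.bincount(flat.ravel(), minlength=5 * m).reshape(m, 5)


def simulate_genes(
    pool: PositionPool,
    per_gene_counts: Mapping[str, int],
    n_reps: int = 10_000,
    seed: int | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Draw replicate profile sets under the positional null.

    For every replicate and gene, ``n`` positions are sampled with
    replacement from the pool (``n`` matched to that gene's observed pLoF
    count) and binned into quintiles by ``floor(5 r) + 1``.

    Returns ``(proportions, genes, counts)`` where ``proportions`` has shape
    ``(n_reps, n_genes, 5)`` and rows sum to 1.  Deterministic given ``seed``.
    """
    if any(n < 1 for n in per_gene_counts.values()):
        raise ValidationError("per-gene variant counts must all be >= 1")
    genes = sorted(per_gene_counts)
    counts = np.array([per_gene_counts[g] for g in genes], dtype=np.int64)
    if n_reps == 0:
        return np.zeros((0, len(genes), 5)), genes, counts
    rng = np.random.default_rng(seed)
    out = np.empty((n_reps, len(genes), 5), dtype=float)
    # group genes by count so each group samples as one rectangular block
    for n in np.unique(counts):
        idx = np.flatnonzero(counts == n)
        draws = rng.choice(
            pool.relative_positions, size=(n_reps * len(idx), int(n)), replace=True
        )
        c = _quintile_counts(draws).reshape(n_reps, len(idx), 5)
        out[:, idx, :] = c / n
    return out, genes, counts


def fpr_by_count(
    roles: np.ndarray,
    counts: np.ndarray,
) -> pd.DataFrame:
    """Non-uniform fraction of simulated genes at each distinct variant count.

    ``roles`` is the (n_reps, n_genes) role array from projecting replicate
    profiles through the fitted model; ``counts`` the per-gene variant counts.
    """
    roles = np.asarray(roles, dtype=object)
    counts = np.asarray(counts, dtype=np.int64)
    rows = []
    for n in np.unique(counts):
        block = roles[:, counts == n]
        rows.append(
            {
                "n_variants": int(n),
                "n_simulated": int(block.size),
                "fpr": float(np.mean(block == "non_uniform")),
            }
        )
    return pd.DataFrame(rows, columns=["n_variants", "n_simulated", "fpr"])


def empirical_enrichment_p(
    observed_nonuniform: int, per_rep_counts: Sequence[int]
) -> float:
    """Empirical p-value with the add-one convention (strictly positive)."""
    per_rep_counts = np.asarray(per_rep_counts)
    if per_rep_counts.size < 1:
        raise ValidationError("at least one replicate is required")
    exceed = int(np.sum(per_rep_counts >= observed_nonuniform))
    return (1 + exceed) / (per_rep_counts.size + 1)


def run_null_simulation(
    pool: PositionPool,
    per_gene_counts: Mapping[str, int],
    model: PositionClusterer,
    n_reps: int = 10_000,
    seed: int | None = None,
    observed_nonuniform: int | None = None,
    batch_size: int = 200,
) -> SimulationResult:
    """Full null run: simulate, project through the model, summarise.

    Replicates are processed in batches of ``batch_size`` to bound memory.
    """
    genes = sorted(per_gene_counts)
    n_genes = len(genes)
    role_blocks = []
    done = 0
    batch_seed = np.random.SeedSequence(seed)
    while done < n_reps:
        m = min(batch_size, n_reps - done)
        sub_seed = int(batch_seed.spawn(1)[0].generate_state(1)[0] % (2**31))
        props, _, counts = simulate_genes(pool, per_gene_counts, m, sub_seed)
        roles = model.predict_roles(props.reshape(-1, 5)).reshape(m, n_genes)
        role_blocks.append(roles)
        done += m
    roles = (
        np.concatenate(role_blocks, axis=0)
        if role_blocks
        else np.zeros((0, n_genes), dtype=object)
    )
    counts = np.array([per_gene_counts[g] for g in genes], dtype=np.int64)
    nonuni = roles == "non_uniform"
    per_rep_count = nonuni.sum(axis=1)
    frac = per_rep_count / n_genes if n_genes else per_rep_count.astype(float)
    p = (
        empirical_enrichment_p(observed_nonuniform, per_rep_count)
        if (observed_nonuniform is not None and n_reps >= 1)
        else None
    )
    return SimulationResult(
        n_reps=n_reps,
        per_rep_nonuniform_fraction=frac,
        per_rep_nonuniform_count=per_rep_count,
        per_count_fpr=fpr_by_count(roles, counts) if n_reps else pd.DataFrame(
            columns=["n_variants", "n_simulated", "fpr"]
        ),
        empirical_p=p,
        seed=seed,
        observed_nonuniform=observed_nonuniform,
        per_gene_counts=dict(per_gene_counts),
    )


def write_simulation_summary(result: SimulationResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "rep": np.arange(1, result.n_reps + 1),
            "n_genes_nonuniform": result.per_rep_nonuniform_count,
        }
    ).to_csv(path, sep="\t", index=False)
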