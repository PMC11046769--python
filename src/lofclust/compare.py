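"""Cross-dataset and gene-set comparisons of positional role assignments.

Population and clinical variant sets are compared gene-by-gene after both
have been projected through the *same* fitted clustering model; genes need at
least five variants in both datasets to enter the table.  Gene sets (for
example dominant developmental-disorder genes with an absent-gene-product
mechanism) are tested for enrichment of non-uniform pLoF distributions with
Fisher's exact test against the complement; an optional resampling-based
p-value restricted to the set can be attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from ._exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named gene list with an inheritance/mechanism annotation."""

    name: str
    genes: frozenset[str]
    annotation: str = "custom"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set needs a non-empty name")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class ComparisonTable:
    """Gene-level role cross-tabulation of two datasets."""

    per_gene: pd.DataFrame   # gene_id, role_a, role_b, n_a, n_b
    n_genes: int
    n_uniform_a: int
    n_uniform_b: int
    discordant: pd.DataFrame
    binomial_p: float | None


def binomial_compare(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value of ``k`` successes in ``n`` vs ``p0``.

    Two-sided in the minimum-likelihood sense: the sum of P(x | n, p0) over
    every outcome x no more probable than k.
    """
    if not 0 <= k <= n:
        raise ValidationError(f"k={k} outside [0, {n}]")
    if not 0 < p0 < 1:
        raise ValidationError("null proportion must lie strictly inside (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def cross_dataset_table(
    assign_a: pd.DataFrame,
    assign_b: pd.DataFrame,
    min_per_class: int = 5,
) -> ComparisonTable:
    """Compare role assignments of one class across two datasets.

    Both inputs must come from the same fitted model (dataset b projected).
    Restricted to genes with >= ``min_per_class`` variants in BOTH datasets;
    the discordant set lists genes uniform in one dataset but non-uniform in
    the other.  ``binomial_p`` tests the uniform fraction in a against the
    uniform fraction in b as the null proportion.
    """
    a = assign_a[["gene_id", "role", "n"]].rename(
        columns={"role": "role_a", "n": "n_a"}
    )
    b = assign_b[["gene_id", "role", "n"]].rename(
        columns={"role": "role_b", "n": "n_b"}
    )
    merged = a.merge(b, on="gene_id", how="inner")
    if merged.empty:
        logger.warning("cross-dataset comparison: gene universes are disjoint")
    merged = merged[
        (merged["n_a"] >= min_per_class) & (merged["n_b"] >= min_per_class)
    ].reset_index(drop=True)
    discordant = merged[
        ((merged["role_a"] == "uniform") & (merged["role_b"] == "non_uniform"))
        | ((merged["role_a"] == "non_uniform") & (merged["role_b"] == "uniform"))
    ].reset_index(drop=True)
    n = len(merged)
    k_a = int((merged["role_a"] == "uniform").sum())
    k_b = int((merged["role_b"] == "uniform").sum())
    p = None
    if n > 0 and 0 < k_b < n:
        p = binomial_compare(k_a, n, k_b / n)
    return ComparisonTable(
        per_gene=merged,
        n_genes=n,
        n_uniform_a=k_a,
        n_uniform_b=k_b,
        discordant=discordant,
        binomial_p=p,
    )


def gene_set_enrichment(
    assignments: pd.DataFrame,
    sets: Iterable[GeneSet],
    simulation_p: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-set enrichment of non-uniform roles vs the complement (Fisher exact).

    ``assignments`` holds one role per eligible gene (empty-role genes are
    dropped from the universe).  Sets with no eligible genes yield an
    undefined row rather than zeros.  ``simulation_p`` optionally supplies a
    resampling p-value per set name.
    """
    df = assignments[assignments["role"] != "empty"]
    universe = df.drop_duplicates("gene_id").set_index("gene_id")["role"]
    rows = []
    for gs in sets:
        in_set = universe.index.isin(gs.genes)
        n_el = int(in_set.sum())
        if n_el == 0:
            rows.append(
                {
                    "set": gs.name,
                    "n_eligible": 0,
                    "n_uniform": 0,
                    "n_nonuniform": 0,
                    "frac_nonuniform": float("nan"),
                    "fisher_p": float("nan"),
                    "simulation_p": (simulation_p or {}).get(gs.name, float("nan")),
                    "defined": False,
                }
            )
            continue
        set_nonuni = int((universe[in_set] == "non_uniform").sum())
        set_uni = n_el - set_nonuni
        comp_nonuni = int((universe[~in_set] == "non_uniform").sum())
        comp_uni = int((~in_set).sum()) - comp_nonuni
        _, p = stats.fisher_exact(
            [[set_nonuni, set_uni], [comp_nonuni, comp_uni]], alternative="two-sided"
        )
        rows.append(
            {
                "set": gs.name,
                "n_eligible": n_el,
                "n_uniform": set_uni,
                "n_nonuniform": set_nonuni,
                "frac_nonuniform": set_nonuni / n_el,
                "fisher_p": float(p),
                "simulation_p": (simulation_p or {}).get(gs.name, float("nan")),
                "defined": True,
            }
        )
    return pd.DataFrame(rows)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a two-column TSV (gene_id, set_name)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "set_name"])
    return [
        GeneSet(name=str(name), genes=frozenset(grp["gene_id"].astype(str)))
        for name, grp in df.groupby("set_name", sort=True)
    ]
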