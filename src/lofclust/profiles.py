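"""Quintile positional profiles of variants, by gene, consequence class and dataset.

Variants arrive with a consequence class already assigned upstream (no codon
re-annotation happens here).  Each distinct variant — identity
``(transcript_id, cds_pos, ref, alt)`` within a dataset — is counted once,
irrespective of allele frequency.  For the primary analysis the two pLoF
classes (SNV and frameshift indel) are pooled into ``plof_all``; a
sensitivity mode restricts to pLoF SNVs so that patterns cannot be driven by
indels spanning quintile boundaries.

A profile is the 5-vector of per-quintile variant counts and the matching
proportion vector; a gene with no variants of a class carries the all-zero
proportion vector, the encoding the clustering stage maps to the
"no variants" role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .transcripts import TranscriptModel, quintiles_of

logger = logging.getLogger(__name__)

CONSEQUENCE_CLASSES = ("synonymous", "missense", "plof_snv", "plof_indel")
DATASETS = ("population", "clinical", "possible", "simulated")
PRIMARY_CLASSES = ("synonymous", "missense", "plof_all")
SENSITIVITY_CLASSES = ("synonymous", "missense", "plof_snv")

VARIANT_COLUMNS = [
    "gene_id",
    "transcript_id",
    "cds_pos",
    "ref",
    "alt",
    "consequence_class",
    "dataset",
]

PROFILE_COLUMNS = (
    ["gene_id", "class", "dataset", "n"]
    + [f"c{i}" for i in range(1, 6)]
    + [f"p{i}" for i in range(1, 6)]
)


@dataclass(frozen=True)
class CdsVariant:
    """One variant localised to a CDS position.

    Indels are positioned at the first (5'-most in transcript orientation)
    altered CDS base after left-alignment; ``-`` denotes an absent allele.
    """

    gene_id: str
    transcript_id: str
    cds_pos: int
    ref: str
    alt: str
    consequence_class: str
    dataset: str = "population"


def variants_to_frame(variants: Iterable[CdsVariant]) -> pd.DataFrame:
    """Convert an iterable of :class:`CdsVariant` to the canonical table."""
    return pd.DataFrame(
        [
            (v.gene_id, v.transcript_id, v.cds_pos, v.ref, v.alt,
             v.consequence_class, v.dataset)
            for v in variants
        ],
        columns=VARIANT_COLUMNS,
    )


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read the variant TSV dialect and validate its vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"variant table missing columns: {sorted(missing)}")
    bad_class = set(df["consequence_class"]) - set(CONSEQUENCE_CLASSES)
    if bad_class:
        raise ValidationError(f"unknown consequence classes: {sorted(bad_class)}")
    bad_ds = set(df["dataset"]) - set(DATASETS)
    if bad_ds:
        raise ValidationError(f"unknown datasets: {sorted(bad_ds)}")
    return df[VARIANT_COLUMNS]


def read_vcf(
    path: str | Path,
    subfields: Mapping[str, str],
    ann_field: str = "CSQ",
    dataset: str = "population",
) -> pd.DataFrame:
    """Extract the variant-table fields from an annotated VCF.

    ``subfields`` maps the canonical column names (gene_id, transcript_id,
    cds_pos, consequence_class) to the sub-field names inside the pipe-joined
    annotation INFO field (VEP ``CSQ`` convention).  One output row per
    annotation entry carrying all four sub-fields.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    header_line = vf.header.info[ann_field].description
    fmt = header_line.split("Format:")[-1].strip().strip('"').split("|")
    idx = {}
    for col in ("gene_id", "transcript_id", "cds_pos", "consequence_class"):
        name = subfields[col]
        if name not in fmt:
            raise ValidationError(f"annotation sub-field {name!r} not in {ann_field} format")
        idx[col] = fmt.index(name)
    rows = []
    for rec in vf:
        for entry in rec.info.get(ann_field, ()):
            parts = entry.split("|")
            try:
                cds_pos = int(parts[idx["cds_pos"]])
            except (ValueError, IndexError):
                continue
            for alt in rec.alts or ():
                rows.append(
                    (
                        parts[idx["gene_id"]],
                        parts[idx["transcript_id"]],
                        cds_pos,
                        rec.ref,
                        alt,
                        parts[idx["consequence_class"]],
                        dataset,
                    )
                )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _dedup(variants: pd.DataFrame) -> pd.DataFrame:
    # variant identity: (transcript, cds_pos, ref, alt) within a dataset;
    # allele frequency plays no role, each variant counts once
    return variants.drop_duplicates(
        subset=["dataset", "transcript_id", "cds_pos", "ref", "alt"]
    )


def build_profiles(
    variants: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    class_mode: str = "primary",
) -> pd.DataFrame:
    """Compute per-(gene, class, dataset) quintile count/proportion profiles.

    Variants referencing transcripts absent from ``models`` are skipped with
    a warning; the reject count is recorded in ``result.attrs["n_rejected"]``.
    Every gene in ``models`` receives a profile for every analysis class and
    every dataset present in the input; genes with no variants of a class get
    the all-zero profile.
    """
    if class_mode not in ("primary", "snv_sensitivity"):
        raise ValidationError(f"unknown class_mode {class_mode!r}")
    classes = PRIMARY_CLASSES if class_mode == "primary" else SENSITIVITY_CLASSES

    df = variants[VARIANT_COLUMNS].copy()
    known = df["transcript_id"].isin(models.keys())
    n_rejected = int((~known).sum())
    if n_rejected:
        rejected_tx = sorted(df.loc[~known, "transcript_id"].unique())
        logger.warning(
            "skipping %d variants on %d unknown transcripts (e.g. %s)",
            n_rejected, len(rejected_tx), rejected_tx[:5],
        )
        df = df[known]
    df = _dedup(df)

    if class_mode == "primary":
        df["class"] = df["consequence_class"].replace(
            {"plof_snv": "plof_all", "plof_indel": "plof_all"}
        )
    else:
        df = df[df["consequence_class"] != "plof_indel"]
        df["class"] = df["consequence_class"]

    lengths = {t: m.cds_length for t, m in models.items()}
    L = df["transcript_id"].map(lengths).to_numpy(dtype=np.int64)
    pos = df["cds_pos"].to_numpy(dtype=np.int64)
    if len(df) and (np.any(pos < 1) or np.any(pos > L)):
        bad = df.iloc[int(np.argmax((pos < 1) | (pos > L)))]
        raise ValidationError(
            f"variant at cds_pos {bad.cds_pos} outside CDS of {bad.transcript_id}"
        )
    df["quintile"] = quintiles_of(pos, L) if len(df) else np.array([], dtype=np.int64)

    datasets = sorted(variants["dataset"].unique()) if len(variants) else ["population"]
    genes = sorted({m.gene_id for m in models.values()})

    counts = (
        df.groupby(["gene_id", "class", "dataset", "quintile"], observed=True)
        .size()
        .unstack("quintile", fill_value=0)
        .reindex(columns=range(1, 6), fill_value=0)
    )
    full_index = pd.MultiIndex.from_product(
        [genes, classes, datasets], names=["gene_id", "class", "dataset"]
    )
    counts = counts.reindex(full_index, fill_value=0).astype(np.int64)

    c = counts.to_numpy()
    n = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n[:, None] > 0, c / np.maximum(n[:, None], 1), 0.0)

    out = counts.reset_index()
    out.columns = ["gene_id", "class", "dataset"] + [f"c{i}" for i in range(1, 6)]
    out.insert(3, "n", n)
    for i in range(5):
        out[f"p{i + 1}"] = p[:, i]
    out = out[PROFILE_COLUMNS]
    out.attrs["n_rejected"] = n_rejected
    return out


def profile_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Extract the (n_profiles, 5) proportion matrix from a profile table."""
    return profiles[[f"p{i}" for i in range(1, 6)]].to_numpy(dtype=float)


def eligible_genes(
    profiles: pd.DataFrame,
    min_per_class: int = 5,
    dataset: str = "population",
    classes: Iterable[str] = PRIMARY_CLASSES,
) -> set[str]:
    """Genes with at least ``min_per_class`` variants of every class.

    The study restricts reporting to transcripts with >= 5 variants of each
    consequence class; the clustering itself trains on everything.
    """
    if profiles.empty:
        return set()
    sub = profiles[profiles["dataset"] == dataset]
    if sub.empty:
        return set()
    wide = sub.pivot_table(index="gene_id", columns="class", values="n", fill_value=0)
    classes = list(classes)
    missing = set(classes) - set(wide.columns)
    if missing:
        return set()
    ok = (wide[classes] >= min_per_class).all(axis=1)
    return set(wide.index[ok])


def qc_exclude_nonuniform_background(assignments: pd.DataFrame) -> set[str]:
    """Genes whose synonymous OR missense profile carries role ``non_uniform``.

    A non-uniform background class signals regional artefacts (coverage,
    mapping, annotation) rather than selection against pLoFs, so such genes
    are removed from downstream pLoF interpretation.
    """
    mask = assignments["class"].isin(["synonymous", "missense"]) & (
        assignments["role"] == "non_uniform"
    )
    return set(assignments.loc[mask, "gene_id"])


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"profile table missing columns: {sorted(missing)}")
    return df
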