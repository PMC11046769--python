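"""Transcript models and CDS coordinate arithmetic.

A :class:`TranscriptModel` is the coordinate authority for one transcript: it
holds the exon structure and CDS extent in 1-based inclusive genomic
coordinates (GTF convention) and converts between genomic positions and
1-based CDS positions, honouring strand.  Relative positions within the CDS
use the half-open convention ``(cds_pos - 1) / L`` in ``[0, 1)``, so the last
CDS base never spills into a sixth quintile.

Splice-site and other intronic/UTR positions have no CDS coordinate;
:meth:`TranscriptModel.genomic_to_cds` returns ``None`` for them and callers
drop such variants, restricting every analysis to exonic CDS bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

TIERS = ("mane_select", "mane_plus_clinical", "other")

EXON_TABLE_COLUMNS = [
    "transcript_id",
    "gene_id",
    "chrom",
    "strand",
    "exon_start",
    "exon_end",
    "cds_start",
    "cds_end",
    "tier",
]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and CDS extent of a single transcript.

    Parameters
    ----------
    exons
        Ordered ``(genomic_start, genomic_end)`` pairs, 1-based inclusive,
        sorted by genomic start and non-overlapping.
    cds_genomic_start, cds_genomic_end
        Genomic bounds of the CDS (stop codon included).  On the minus
        strand CDS position 1 corresponds to ``cds_genomic_end``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_genomic_start: int
    cds_genomic_end: int
    tier: str = "other"
    _cds_exons: tuple[tuple[int, int], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tier not in TIERS:
            raise ValidationError(
                f"{self.transcript_id}: unknown transcript tier {self.tier!r}"
            )
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = 0
        for s, e in exons:
            if s > e:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({s}, {e}) has start > end"
                )
            if s <= prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons unsorted or overlapping at ({s}, {e})"
                )
            prev_end = e
        object.__setattr__(self, "exons", exons)
        if self.cds_genomic_start > self.cds_genomic_end:
            raise ValidationError(
                f"{self.transcript_id}: CDS start {self.cds_genomic_start} exceeds "
                f"end {self.cds_genomic_end}"
            )
        cds_exons = tuple(
            (max(s, self.cds_genomic_start), min(e, self.cds_genomic_end))
            for s, e in exons
            if e >= self.cds_genomic_start and s <= self.cds_genomic_end
        )
        if not cds_exons:
            raise ValidationError(
                f"{self.transcript_id}: CDS bounds overlap no exon"
            )
        object.__setattr__(self, "_cds_exons", cds_exons)

    @property
    def cds_length(self) -> int:
        """Number of exonic bases between the CDS bounds (stop codon included)."""
        return sum(e - s + 1 for s, e in self._cds_exons)

    @property
    def cds_exons(self) -> tuple[tuple[int, int], ...]:
        """Exon segments clipped to the CDS bounds, in genomic order."""
        return self._cds_exons

    @property
    def final_exon(self) -> tuple[int, int]:
        """The 3'-most exon in transcript orientation."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def final_exon_cds_start(self) -> int:
        """First CDS position falling in the 3'-most CDS-bearing exon."""
        last = self._cds_exons[-1] if self.strand == "+" else self._cds_exons[0]
        return self.cds_length - (last[1] - last[0] + 1) + 1

    def genomic_to_cds(self, genomic_pos: int) -> int | None:
        """Map a genomic position to its 1-based CDS position.

        Returns ``None`` for positions outside exonic CDS bases (intronic,
        UTR, or off-transcript); such variants are excluded from the
        positional analysis.
        """
        if genomic_pos < 1:
            raise ValidationError(
                f"{self.transcript_id}: genomic position must be positive"
            )
        offset = 0
        if self.strand == "+":
            for s, e in self._cds_exons:
                if s <= genomic_pos <= e:
                    return offset + (genomic_pos - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self._cds_exons):
                if s <= genomic_pos <= e:
                    return offset + (e - genomic_pos) + 1
                offset += e - s + 1
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse of :meth:`genomic_to_cds` for positions in ``[1, L]``."""
        L = self.cds_length
        if not 1 <= cds_pos <= L:
            raise ValidationError(
                f"{self.transcript_id}: CDS position {cds_pos} outside [1, {L}]"
            )
        remaining = cds_pos - 1
        segments = (
            self._cds_exons if self.strand == "+" else tuple(reversed(self._cds_exons))
        )
        for s, e in segments:
            width = e - s + 1
            if remaining < width:
                return s + remaining if self.strand == "+" else e - remaining
            remaining -= width
        raise AssertionError("unreachable")  # pragma: no cover

    def in_final_exon(self, cds_pos: int) -> bool:
        """Whether a CDS base lies in the transcript's 3'-most exon."""
        return cds_pos >= self.final_exon_cds_start()


def relative_position(cds_pos: int, L: int) -> float:
    """Relative position of a CDS base in ``[0, 1)``: ``(cds_pos - 1) / L``."""
    if not 1 <= cds_pos <= L:
        raise ValidationError(f"CDS position {cds_pos} outside [1, {L}]")
    return (cds_pos - 1) / L


def quintile_of(cds_pos: int, L: int) -> int:
    """Exon-agnostic CDS quintile in ``[1, 5]``.

    ``floor(5 * (cds_pos - 1) / L) + 1`` — half-open bins, so every base maps
    to exactly one quintile and position ``L`` maps to quintile 5.
    """
    return math.floor(5 * relative_position(cds_pos, L)) + 1


def quintiles_of(cds_pos: np.ndarray, L: np.ndarray | int) -> np.ndarray:
    """Vectorised :func:`quintile_of` (no bounds checking beyond [1, L])."""
    cds_pos = np.asarray(cds_pos, dtype=np.int64)
    L = np.asarray(L, dtype=np.int64)
    if np.any((cds_pos < 1) | (cds_pos > L)):
        raise ValidationError("CDS positions outside [1, L]")
    return (5 * (cds_pos - 1) // L) + 1


def quintile_of_relative(relative_pos: np.ndarray) -> np.ndarray:
    """Quintile of a relative position in ``[0, 1)``: ``floor(5 r) + 1``."""
    r = np.asarray(relative_pos, dtype=float)
    if np.any((r < 0) | (r >= 1)):
        raise ValidationError("relative positions must lie in [0, 1)")
    return np.floor(5 * r).astype(np.int64) + 1


def read_exon_table(path: str | Path) -> dict[str, TranscriptModel]:
    """Read the flat exon TSV dialect (one row per exon).

    Columns: transcript_id, gene_id, chrom, strand, exon_start, exon_end,
    cds_start, cds_end, tier.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(EXON_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"exon table missing columns: {sorted(missing)}")
    models: dict[str, TranscriptModel] = {}
    for tid, grp in df.groupby("transcript_id", sort=True):
        grp = grp.sort_values("exon_start")
        first = grp.iloc[0]
        models[str(tid)] = TranscriptModel(
            transcript_id=str(tid),
            gene_id=str(first["gene_id"]),
            chrom=str(first["chrom"]),
            strand=str(first["strand"]),
            exons=tuple(
                (int(r.exon_start), int(r.exon_end)) for r in grp.itertuples()
            ),
            cds_genomic_start=int(first["cds_start"]),
            cds_genomic_end=int(first["cds_end"]),
            tier=str(first["tier"]),
        )
    return models


def write_exon_table(models: Mapping[str, TranscriptModel], path: str | Path) -> None:
    """Write transcript models as the flat exon TSV dialect."""
    rows = []
    for tid in sorted(models):
        m = models[tid]
        for s, e in m.exons:
            rows.append(
                {
                    "transcript_id": m.transcript_id,
                    "gene_id": m.gene_id,
                    "chrom": m.chrom,
                    "strand": m.strand,
                    "exon_start": s,
                    "exon_end": e,
                    "cds_start": m.cds_genomic_start,
                    "cds_end": m.cds_genomic_end,
                    "tier": m.tier,
                }
            )
    pd.DataFrame(rows, columns=EXON_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gtf(path: str | Path, tier_attribute: str = "tag") -> dict[str, TranscriptModel]:
    """Read transcript models from a GTF/GFF3 file via gffutils.

    Exon and CDS features are grouped by ``transcript_id``; a transcript is
    tagged ``mane_select`` / ``mane_plus_clinical`` when the attribute named
    by ``tier_attribute`` carries ``MANE_Select`` / ``MANE_Plus_Clinical``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        info = meta.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "tier": "other",
            },
        )
        tags = feat.attributes.get(tier_attribute, [])
        if any(t.lower() == "mane_select" for t in tags):
            info["tier"] = "mane_select"
        elif any(t.lower() == "mane_plus_clinical" for t in tags):
            info["tier"] = "mane_plus_clinical"
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))
    models = {}
    for tid, info in meta.items():
        if tid not in exons or tid not in cds:
            continue
        cds_segs = sorted(cds[tid])
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            chrom=info["chrom"],
            strand=info["strand"],
            exons=tuple(sorted(exons[tid])),
            cds_genomic_start=cds_segs[0][0],
            cds_genomic_end=cds_segs[-1][1],
            tier=info["tier"],
        )
    return models


def filter_by_tier(
    models: Mapping[str, TranscriptModel],
    tiers: Iterable[str] = ("mane_select",),
) -> dict[str, TranscriptModel]:
    """Restrict a transcript set to the given tiers (MANE Select by default)."""
    tiers = set(tiers)
    unknown = tiers - set(TIERS)
    if unknown:
        raise ValidationError(f"unknown transcript tiers: {sorted(unknown)}")
    return {t: m for t, m in models.items() if m.tier in tiers}
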