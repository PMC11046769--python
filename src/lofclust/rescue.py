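"""Candidate rescue mechanisms for truncating variants.

Two mechanisms can blunt the impact of a premature stop:

* **Translation re-initiation** — the ribosome re-initiates at the first
  in-frame ATG downstream of the canonical start, producing an N-terminally
  truncated protein; truncating variants upstream of that ATG can be
  rescued.  Codon indices count the canonical start codon as codon 1.
* **NMD escape** — premature stops in the final exon usually escape
  nonsense-mediated decay, so a C-terminally truncated protein can be made.
  The default rule is plain final-exon membership; the stricter
  50-bp-upstream-of-the-last-junction refinement is available via
  ``last50bp_rule=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .transcripts import TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class RescueReport:
    """Per-transcript rescue annotation for a set of variants."""

    transcript_id: str
    gene_id: str
    alt_start_codon_index: int | None
    alt_start_cds_pos: int | None
    flags: pd.DataFrame  # cds_pos, ref, alt, upstream_of_alt_start, in_final_exon


def first_inframe_downstream_atg(cds_seq: str) -> int | None:
    """Smallest codon index >= 2 whose codon is ATG; None if none exists.

    The scan is codon-wise, so out-of-frame ATG trinucleotides are ignored.
    The terminal stop codon cannot be ATG, so it never matches.
    """
    seq = cds_seq.upper()
    if not seq.startswith("ATG"):
        logger.warning("CDS does not start with ATG; scanning from codon 2 anyway")
    for ci in range(1, len(seq) // 3):
        if seq[3 * ci : 3 * ci + 3] == "ATG":
            return ci + 1
    return None


def all_inframe_atgs(cds_seq: str) -> list[int]:
    """Codon indices (>= 2) of every in-frame ATG, for plotting tracks."""
    seq = cds_seq.upper()
    return [
        ci + 1
        for ci in range(1, len(seq) // 3)
        if seq[3 * ci : 3 * ci + 3] == "ATG"
    ]


def codon_to_cds_pos(codon_index: int) -> int:
    """First CDS base of a 1-based codon index: ``3 (c - 1) + 1``."""
    return 3 * (codon_index - 1) + 1


def flag_variants(
    variants: pd.DataFrame,
    model: TranscriptModel,
    codon_index: int | None,
    last50bp_rule: bool = False,
) -> RescueReport:
    """Flag variants for re-initiation and NMD-escape rescue.

    ``upstream_of_alt_start`` is True iff the variant's CDS position precedes
    the first base of the downstream in-frame ATG (always False when no such
    ATG exists).  ``in_final_exon`` is True iff the variant's CDS base lies
    in the transcript's 3'-most exon; with ``last50bp_rule`` the NMD-escape
    window additionally covers the last 50 bases of the penultimate exon.
    """
    df = variants.loc[
        variants["transcript_id"] == model.transcript_id,
        ["cds_pos", "ref", "alt"],
    ].copy()
    alt_start_cds_pos = codon_to_cds_pos(codon_index) if codon_index else None
    if alt_start_cds_pos is None:
        df["upstream_of_alt_start"] = False
    else:
        df["upstream_of_alt_start"] = df["cds_pos"] < alt_start_cds_pos
    boundary = model.final_exon_cds_start()
    if last50bp_rule:
        boundary = max(1, boundary - 50)
    df["in_final_exon"] = df["cds_pos"] >= boundary
    df["alt_start_codon_index"] = codon_index
    return RescueReport(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        alt_start_codon_index=codon_index,
        alt_start_cds_pos=alt_start_cds_pos,
        flags=df.reset_index(drop=True),
    )


def annotate_rescues(
    variants: pd.DataFrame,
    models: dict[str, TranscriptModel],
    cds_seqs: dict[str, str],
    last50bp_rule: bool = False,
) -> pd.DataFrame:
    """Rescue report rows for every transcript with variants.

    Output columns: transcript_id, gene_id, cds_pos, ref, alt,
    upstream_of_alt_start, in_final_exon, alt_start_codon_index.
    """
    frames = []
    for tid in sorted(variants["transcript_id"].unique()):
        if tid not in models or tid not in cds_seqs:
            continue
        ci = first_inframe_downstream_atg(cds_seqs[tid])
        rep = flag_variants(variants, models[tid], ci, last50bp_rule)
        flags = rep.flags.copy()
        flags.insert(0, "gene_id", rep.gene_id)
        flags.insert(0, "transcript_id", rep.transcript_id)
        frames.append(flags)
    cols = [
        "transcript_id", "gene_id", "cds_pos", "ref", "alt",
        "upstream_of_alt_start", "in_final_exon", "alt_start_codon_index",
    ]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def write_rescue_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
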