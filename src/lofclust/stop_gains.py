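"""Enumeration of every possible stop-gain SNV in a coding sequence.

A stop-gain SNV is a single-base substitution that converts a non-stop codon
into one of the standard stop codons (TAA, TAG, TGA).  Enumerating all such
sites gives the "possible pLoF" positional profile of a transcript: the
distribution observed pLoFs would follow if placement were constrained only
by the coding sequence itself.  The annotated terminal stop codon is never a
stop-gain site (it is already stop), and codons that are already stops are
skipped.

Only stop-gains are enumerated: splice-disrupting SNVs are intronic and the
analysis is exonic-only, and start-loss SNVs do not create premature stops.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping
import logging

import pandas as pd

from ._exceptions import ValidationError
from .transcripts import quintiles_of

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BASES = "ACGT"


@dataclass(frozen=True)
class PossibleStopGain:
    """One potential stop-gain substitution."""

    cds_pos: int
    ref: str
    alt: str
    codon_index: int
    ref_codon: str
    alt_codon: str


def enumerate_stop_gains(
    cds_seq: str, stop_codons: frozenset[str] = STOP_CODONS
) -> list[PossibleStopGain]:
    """All single-base substitutions turning a non-stop codon into a stop.

    ``cds_seq`` must be an ACGT string with length divisible by 3; it should
    end in a stop codon (a warning is logged if not).  Records are sorted by
    CDS position, then alternate base.
    """
    seq = cds_seq.upper()
    for i, ch in enumerate(seq):
        if ch not in BASES:
            raise ValidationError(f"non-ACGT character {ch!r} at CDS position {i + 1}")
    if len(seq) % 3 != 0:
        raise ValidationError(f"CDS length {len(seq)} not divisible by 3")
    n_codons = len(seq) // 3
    has_terminal_stop = n_codons > 0 and seq[-3:] in stop_codons
    if not has_terminal_stop:
        logger.warning("CDS does not end in a stop codon; scanning every codon")
    last_scanned = n_codons - 1 if has_terminal_stop else n_codons
    records: list[PossibleStopGain] = []
    for ci in range(last_scanned):
        codon = seq[3 * ci : 3 * ci + 3]
        if codon in stop_codons:  # already a stop: no gain possible
            continue
        for j in range(3):
            ref = codon[j]
            for alt in BASES:
                if alt == ref:
                    continue
                alt_codon = codon[:j] + alt + codon[j + 1 :]
                if alt_codon in stop_codons:
                    records.append(
                        PossibleStopGain(
                            cds_pos=3 * ci + j + 1,
                            ref=ref,
                            alt=alt,
                            codon_index=ci + 1,
                            ref_codon=codon,
                            alt_codon=alt_codon,
                        )
                    )
    records.sort(key=lambda r: (r.cds_pos, r.alt))
    return records


def possible_profile(
    records: Iterable[PossibleStopGain],
    L: int,
    gene_id: str = "",
) -> pd.Series:
    """Quintile profile of possible stop-gain sites (dataset ``possible``).

    Returns one row in the profile-table schema, ready for projection
    through the fitted clustering model.
    """
    counts = [0, 0, 0, 0, 0]
    positions = [r.cds_pos for r in records]
    if positions:
        for q in quintiles_of(positions, L):
            counts[q - 1] += 1
    n = sum(counts)
    props = [c / n if n else 0.0 for c in counts]
    data = {"gene_id": gene_id, "class": "plof_snv", "dataset": "possible", "n": n}
    data.update({f"c{i + 1}": counts[i] for i in range(5)})
    data.update({f"p{i + 1}": props[i] for i in range(5)})
    return pd.Series(data)


def possible_profiles_for(
    cds_seqs: Mapping[str, str],
    gene_of_transcript: Mapping[str, str],
) -> pd.DataFrame:
    """Possible-pLoF profiles for a set of transcripts keyed by id."""
    rows = []
    for tid in sorted(cds_seqs):
        recs = enumerate_stop_gains(cds_seqs[tid])
        rows.append(possible_profile(recs, len(cds_seqs[tid]), gene_of_transcript[tid]))
    from .profiles import PROFILE_COLUMNS

    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read CDS sequences keyed by transcript id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_stop_gain_table(
    records_by_transcript: Mapping[str, Iterable[PossibleStopGain]],
    path: str | Path,
) -> None:
    rows = [
        {
            "transcript_id": tid,
            "cds_pos": r.cds_pos,
            "ref": r.ref,
            "alt": r.alt,
            "ref_codon": r.ref_codon,
            "alt_codon": r.alt_codon,
            "codon_index": r.codon_index,
        }
        for tid in sorted(records_by_transcript)
        for r in records_by_transcript[tid]
    ]
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "cds_pos", "ref", "alt",
            "ref_codon", "alt_codon", "codon_index",
        ],
    ).to_csv(path, sep="\t", index=False)
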