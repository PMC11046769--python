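"""Synthetic transcript models, CDS sequences and variant tables.

The generator emulates the data the positional analysis consumes: multi-exon
transcripts with valid coding sequences (ATG start, stop end, no internal
in-frame stop), and per-gene variant sets of four consequence classes whose
positions follow configurable regimes:

* ``uniform``        — positions anywhere in the CDS;
* ``start_depleted`` — no variants in the given 5' quintiles (the
  re-initiation-rescue signature);
* ``end_depleted``   — no variants in the given 3' quintiles;
* ``end_clustered``  — variants only in the given 3' quintiles (the
  NMD-escape / gain-of-function signature);
* ``zero``           — no variants of the class at all.

With sequence-consistent generation (the default), every emitted pLoF SNV
really creates a stop codon, every synonymous variant preserves the encoded
amino acid, and every missense variant changes it — so sequence-level checks
hold by construction.  Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .stop_gains import STOP_CODONS, enumerate_stop_gains
from .transcripts import TranscriptModel, quintiles_of, write_exon_table

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CODON_TABLE = {}
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate("TCAG"):
    for _j, _b2 in enumerate("TCAG"):
        for _k, _b3 in enumerate("TCAG"):
            CODON_TABLE[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds_seq: str) -> str:
    return "".join(
        CODON_TABLE[cds_seq[i : i + 3]] for i in range(0, len(cds_seq) - 2, 3)
    )


@dataclass(frozen=True)
class Regime:
    """Positional regime: which quintiles may carry variants."""

    name: str
    allowed_quintiles: frozenset[int]

    def __post_init__(self) -> None:
        bad = set(self.allowed_quintiles) - {1, 2, 3, 4, 5}
        if bad:
            raise ValidationError(f"regime quintiles outside 1..5: {sorted(bad)}")

    @property
    def expected_role(self) -> str:
        if self.name == "uniform":
            return "uniform"
        if self.name == "zero":
            return "empty"
        return "non_uniform"


def uniform_regime() -> Regime:
    return Regime("uniform", frozenset({1, 2, 3, 4, 5}))


def start_depleted(depleted: tuple[int, ...] = (1, 2)) -> Regime:
    return Regime("start_depleted", frozenset({1, 2, 3, 4, 5}) - set(depleted))


def end_depleted(depleted: tuple[int, ...] = (4, 5)) -> Regime:
    return Regime("end_depleted", frozenset({1, 2, 3, 4, 5}) - set(depleted))


def end_clustered(clustered: tuple[int, ...] = (4, 5)) -> Regime:
    return Regime("end_clustered", frozenset(clustered))


def zero_regime() -> Regime:
    return Regime("zero", frozenset())


@dataclass(frozen=True)
class CountDistribution:
    """Per-gene variant-count distribution.

    ``negbin`` draws from a negative binomial with the given mean and
    dispersion (size) parameter, resampling until the minimum is met;
    ``fixed`` always returns ``mean``; ``uniform_int`` draws uniformly from
    ``[low, high]`` inclusive.
    """

    kind: str = "negbin"
    mean: float = 15.0
    dispersion: float = 1.0
    minimum: int = 5
    low: int = 5
    high: int = 50

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, int(self.mean), dtype=np.int64)
        if self.kind == "uniform_int":
            return rng.integers(self.low, self.high + 1, size=size)
        if self.kind != "negbin":
            raise ValidationError(f"unknown count distribution kind {self.kind!r}")
        p = self.dispersion / (self.dispersion + self.mean)
        out = rng.negative_binomial(self.dispersion, p, size=size)
        for _ in range(1000):
            low = out < self.minimum
            if not low.any():
                break
            out[low] = rng.negative_binomial(self.dispersion, p, size=int(low.sum()))
        out = np.maximum(out, self.minimum)
        return out.astype(np.int64)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition description for one synthetic cohort.

    ``plof_regimes`` lists (regime, gene count) blocks for the population
    pLoF class; genes are assigned block-wise in order, so the cohort
    composition is exactly the stated counts.  Synonymous and missense
    variants follow ``background_regime`` (uniform by default).
    """

    plof_regimes: tuple[tuple[Regime, int], ...] = (
        (uniform_regime(), 500),
        (start_depleted(), 100),
        (zero_regime(), 50),
    )
    clinical_regime: Regime = field(default_factory=uniform_regime)
    background_regime: Regime = field(default_factory=uniform_regime)
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_min: int = 30
    cds_length_range: tuple[int, int] = (300, 1500)
    counts: Mapping[str, CountDistribution] = field(
        default_factory=lambda: {
            "synonymous": CountDistribution(mean=40.0),
            "missense": CountDistribution(mean=80.0),
            "plof": CountDistribution(mean=15.0),
            "clinical_plof": CountDistribution(mean=10.0),
        }
    )
    indel_fraction: float = 0.5
    gc_content: float = 0.45
    sequence_consistent: bool = True
    generate_clinical: bool = False
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return sum(n for _, n in self.plof_regimes)

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]

    def gene_regimes(self) -> dict[str, Regime]:
        out: dict[str, Regime] = {}
        i = 0
        for regime, n in self.plof_regimes:
            for _ in range(n):
                out[f"GENE{i:04d}"] = regime
                i += 1
        return out

    def to_json(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["plof_regimes"] = [
            {"name": r.name, "allowed_quintiles": sorted(r.allowed_quintiles), "n": n}
            for r, n in self.plof_regimes
        ]
        for key in ("clinical_regime", "background_regime"):
            r = getattr(self, key)
            doc[key] = {"name": r.name, "allowed_quintiles": sorted(r.allowed_quintiles)}
        doc["counts"] = {k: dataclasses.asdict(v) for k, v in self.counts.items()}
        return doc


@dataclass
class SyntheticDataset:
    """Everything one synthetic cohort comprises."""

    spec: SyntheticSpec
    models: dict[str, TranscriptModel]
    cds_seqs: dict[str, str]
    genome: dict[str, str]
    variants: pd.DataFrame
    truth: pd.DataFrame


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random non-stop codons + one stop codon, with GC bias."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n_internal = n_codons - 2
    codons = np.empty(n_internal, dtype="<U3")
    need = np.arange(n_internal)
    while need.size:
        draws = BASES[rng.choice(4, size=(need.size, 3), p=probs)]
        cand = np.array(["".join(row) for row in draws])
        ok = ~np.isin(cand, list(STOP_CODONS))
        codons[need[ok]] = cand[ok]
        need = need[~ok]
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(codons) + stop


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=probs)])


def generate_transcripts(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, TranscriptModel], dict[str, str], dict[str, str]]:
    """Draw transcript models, their CDS sequences and genomic contigs.

    Each gene sits on its own contig; the CDS covers the exons exactly (no
    UTR), the strand is random, and on the minus strand the CDS equals the
    reverse complement of the exon concatenation in genomic order.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = spec.cds_length_range
    if lo < 6 or lo > hi:
        raise ValidationError("cds_length_range must satisfy 6 <= lo <= hi")
    models: dict[str, TranscriptModel] = {}
    cds_seqs: dict[str, str] = {}
    genome: dict[str, str] = {}
    for i, gene_id in enumerate(spec.gene_ids()):
        tid = f"TX{i:04d}"
        chrom = f"ctg{i:04d}"
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        L = 3 * n_codons
        cds = _random_cds(rng, n_codons, spec.gc_content)
        k_max = max(1, min(spec.exon_count_range[1], L // spec.exon_length_min))
        k_min = min(spec.exon_count_range[0], k_max)
        k = int(rng.integers(k_min, k_max + 1))
        if k > 1:
            cuts = np.sort(
                rng.choice(np.arange(1, L // 3), size=k - 1, replace=False) * 3
            )
            exon_lens = np.diff(np.concatenate([[0], cuts, [L]]))
        else:
            exon_lens = np.array([L])
        strand = "+" if rng.random() < 0.5 else "-"
        tx_genomic = cds if strand == "+" else revcomp(cds)
        flank = 100
        introns = [
            int(rng.integers(50, 301)) for _ in range(len(exon_lens) - 1)
        ]
        pieces = [_random_bases(rng, flank, spec.gc_content)]
        exons = []
        pos = flank + 1
        offset = 0
        for j, el in enumerate(exon_lens):
            el = int(el)
            pieces.append(tx_genomic[offset : offset + el])
            exons.append((pos, pos + el - 1))
            offset += el
            pos += el
            if j < len(introns):
                pieces.append(_random_bases(rng, introns[j], spec.gc_content))
                pos += introns[j]
        pieces.append(_random_bases(rng, flank, spec.gc_content))
        genome[chrom] = "".join(pieces)
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_genomic_start=exons[0][0],
            cds_genomic_end=exons[-1][1],
            tier="mane_select",
        )
        cds_seqs[tid] = cds
    return models, cds_seqs, genome


def _synonymous_sites(cds: str) -> list[tuple[int, str, str]]:
    """(cds_pos, ref, alt) substitutions preserving the encoded amino acid."""
    sites = []
    for ci in range(len(cds) // 3 - 1):  # skip the terminal stop codon
        codon = cds[3 * ci : 3 * ci + 3]
        aa = CODON_TABLE[codon]
        for j in range(3):
            for alt in "ACGT":
                if alt == codon[j]:
                    continue
                alt_codon = codon[:j] + alt + codon[j + 1 :]
                if CODON_TABLE[alt_codon] == aa:
                    sites.append((3 * ci + j + 1, codon[j], alt))
    return sites


def _missense_sites(cds: str) -> list[tuple[int, str, str]]:
    """Substitutions changing the amino acid to another (non-stop) one."""
    sites = []
    for ci in range(len(cds) // 3 - 1):
        codon = cds[3 * ci : 3 * ci + 3]
        aa = CODON_TABLE[codon]
        for j in range(3):
            for alt in "ACGT":
                if alt == codon[j]:
                    continue
                alt_codon = codon[:j] + alt + codon[j + 1 :]
                new_aa = CODON_TABLE[alt_codon]
                if new_aa not in ("*", aa):
                    sites.append((3 * ci + j + 1, codon[j], alt))
    return sites


def _pick_sites(
    sites: list[tuple[int, str, str]],
    allowed: frozenset[int],
    L: int,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    if not sites or n == 0 or not allowed:
        return []
    pos = np.array([s[0] for s in sites])
    mask = np.isin(quintiles_of(pos, L), list(allowed))
    pool = [s for s, m in zip(sites, mask) if m]
    if not pool:
        return []
    take = min(n, len(pool))
    idx = rng.choice(len(pool), size=take, replace=False)
    return [pool[i] for i in idx]


def generate_variants(
    models: Mapping[str, TranscriptModel],
    cds_seqs: Mapping[str, str],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-gene variant tables under the spec's regimes.

    Positions are uniform over the allowed quintiles of each regime; in
    sequence-consistent mode alleles are drawn from the actual substitution
    sites of each kind, so consequence classes are verifiable by translation.
    A regime requesting pLoFs in quintiles with no possible stop-gain site
    raises a validation error naming the gene.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    regimes = spec.gene_regimes()
    counts = spec.counts
    rows: list[tuple] = []
    for tid in sorted(models):
        m = models[tid]
        cds = cds_seqs[tid]
        L = m.cds_length
        gene = m.gene_id
        bg = spec.background_regime.allowed_quintiles
        n_syn, n_mis = (
            int(counts["synonymous"].sample(rng, 1)[0]),
            int(counts["missense"].sample(rng, 1)[0]),
        )
        if spec.sequence_consistent:
            syn_sites = _synonymous_sites(cds)
            mis_sites = _missense_sites(cds)
        else:
            syn_sites = [(p, cds[p - 1], "N") for p in range(1, L + 1)]
            mis_sites = syn_sites
        for p, ref, alt in _pick_sites(syn_sites, bg, L, n_syn, rng):
            rows.append((gene, tid, p, ref, alt, "synonymous", "population"))
        for p, ref, alt in _pick_sites(mis_sites, bg, L, n_mis, rng):
            rows.append((gene, tid, p, ref, alt, "missense", "population"))

        stop_sites = enumerate_stop_gains(cds) if spec.sequence_consistent else None
        for dataset, regime, dist_name in (
            ("population", regimes[gene], "plof"),
            ("clinical", spec.clinical_regime, "clinical_plof"),
        ):
            if dataset == "clinical" and not spec.generate_clinical:
                continue
            allowed = regime.allowed_quintiles
            if not allowed:
                continue
            n_plof = int(counts[dist_name].sample(rng, 1)[0])
            n_indel = int(rng.binomial(n_plof, spec.indel_fraction))
            n_snv = n_plof - n_indel
            if spec.sequence_consistent:
                snv_pool = [
                    (r.cds_pos, r.ref, r.alt) for r in stop_sites
                ]
                pos_arr = np.array([s[0] for s in snv_pool]) if snv_pool else np.array([])
                if n_snv > 0 and (
                    not snv_pool
                    or not np.isin(quintiles_of(pos_arr, L), list(allowed)).any()
                ):
                    raise ValidationError(
                        f"{gene}: regime {regime.name} allows no stop-gain site "
                        f"in quintiles {sorted(allowed)}"
                    )
            else:
                snv_pool = [(p, cds[p - 1], "N") for p in range(1, L + 1)]
            for p, ref, alt in _pick_sites(snv_pool, allowed, L, n_snv, rng):
                rows.append((gene, tid, p, ref, alt, "plof_snv", dataset))
            # frameshift single-base deletions, excluding the stop codon
            indel_pool = [(p, cds[p - 1], "-") for p in range(1, L - 2)]
            for p, ref, alt in _pick_sites(indel_pool, allowed, L, n_indel, rng):
                rows.append((gene, tid, p, ref, alt, "plof_indel", dataset))
    from .profiles import VARIANT_COLUMNS

    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def truth_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-gene expected pLoF role implied by the assigned regimes."""
    regimes = spec.gene_regimes()
    return pd.DataFrame(
        {
            "gene_id": list(regimes),
            "regime": [r.name for r in regimes.values()],
            "expected_role": [r.expected_role for r in regimes.values()],
        }
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full cohort: transcripts, sequences, contigs, variants, truth."""
    rng = np.random.default_rng(spec.seed)
    models, cds_seqs, genome = generate_transcripts(spec, rng)
    variants = generate_variants(models, cds_seqs, spec, rng)
    return SyntheticDataset(
        spec=spec,
        models=models,
        cds_seqs=cds_seqs,
        genome=genome,
        variants=variants,
        truth=truth_table(spec),
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write exon TSV, CDS FASTA, genome FASTA, variant TSV and metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exons": outdir / "exons.tsv",
        "cds_fasta": outdir / "cds.fasta",
        "genome_fasta": outdir / "genome.fasta",
        "variants": outdir / "variants.tsv",
        "truth": outdir / "truth.tsv",
        "metadata": outdir / "metadata.json",
    }
    write_exon_table(ds.models, paths["exons"])
    with open(paths["cds_fasta"], "w") as fh:
        for tid in sorted(ds.cds_seqs):
            fh.write(f">{tid}\n{ds.cds_seqs[tid]}\n")
    with open(paths["genome_fasta"], "w") as fh:
        for chrom in sorted(ds.genome):
            fh.write(f">{chrom}\n{ds.genome[chrom]}\n")
    ds.variants.to_csv(paths["variants"], sep="\t", index=False)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["metadata"].write_text(json.dumps(ds.spec.to_json(), indent=1))
    return paths
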