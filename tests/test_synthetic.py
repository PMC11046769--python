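import numpy as np
import pytest
from scipy import stats

from lofclust.transcripts import quintiles_of
from lofclust.synthetic import (
    CODON_TABLE,
    CountDistribution,
    SyntheticSpec,
    end_clustered,
    generate_dataset,
    generate_transcripts,
    revcomp,
    start_depleted,
    translate,
    truth_table,
    uniform_regime,
    write_dataset,
    zero_regime,
)


@pytest.fixture(scope="module")
def tiny_spec():
    return SyntheticSpec(
        plof_regimes=(
            (uniform_regime(), 12),
            (start_depleted(), 5),
            (end_clustered(), 3),
            (zero_regime(), 4),
        ),
        generate_clinical=True,
        seed=21,
    )


@pytest.fixture(scope="module")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


class TestTranscripts:
    def test_determinism_byte_identical_outputs(self, tiny_spec, tmp_path_factory):
        out1 = write_dataset(generate_dataset(tiny_spec), tmp_path_factory.mktemp("a"))
        out2 = write_dataset(generate_dataset(tiny_spec), tmp_path_factory.mktemp("b"))
        for key in ("exons", "cds_fasta", "variants", "truth"):
            assert out1[key].read_bytes() == out2[key].read_bytes()

    def test_every_cds_is_a_valid_orf(self, tiny_dataset):
        for cds in tiny_dataset.cds_seqs.values():
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = translate(cds)
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_minus_strand_exon_concatenation_reverse_complements_to_cds(self, tiny_dataset):
        checked = 0
        for tid, m in tiny_dataset.models.items():
            if m.strand != "-":
                continue
            contig = tiny_dataset.genome[m.chrom]
            genomic = "".join(contig[s - 1 : e] for s, e in m.exons)
            assert revcomp(genomic) == tiny_dataset.cds_seqs[tid]
            checked += 1
        assert checked > 0

    def test_exon_lengths_sum_to_cds_length(self, tiny_dataset):
        for tid, m in tiny_dataset.models.items():
            assert m.cds_length == len(tiny_dataset.cds_seqs[tid])


class TestVariants:
    def test_plof_snvs_create_stop_codons(self, tiny_dataset):
        snvs = tiny_dataset.variants.query("consequence_class == 'plof_snv'")
        assert len(snvs)
        for row in snvs.itertuples():
            cds = tiny_dataset.cds_seqs[row.transcript_id]
            assert cds[row.cds_pos - 1] == row.ref
            mutated = cds[: row.cds_pos - 1] + row.alt + cds[row.cds_pos :]
            ci = (row.cds_pos - 1) // 3
            assert CODON_TABLE[mutated[3 * ci : 3 * ci + 3]] == "*"

    def test_synonymous_variants_preserve_the_protein(self, tiny_dataset):
        syn = tiny_dataset.variants.query("consequence_class == 'synonymous'")
        for row in syn.sample(min(len(syn), 200), random_state=0).itertuples():
            cds = tiny_dataset.cds_seqs[row.transcript_id]
            mutated = cds[: row.cds_pos - 1] + row.alt + cds[row.cds_pos :]
            assert translate(mutated) == translate(cds)

    def test_missense_variants_change_exactly_one_residue(self, tiny_dataset):
        mis = tiny_dataset.variants.query("consequence_class == 'missense'")
        for row in mis.sample(min(len(mis), 200), random_state=0).itertuples():
            cds = tiny_dataset.cds_seqs[row.transcript_id]
            mutated = cds[: row.cds_pos - 1] + row.alt + cds[row.cds_pos :]
            p0, p1 = translate(cds), translate(mutated)
            assert sum(a != b for a, b in zip(p0, p1)) == 1
            assert "*" not in p1[:-1]

    def test_start_depleted_genes_have_no_plofs_in_depleted_quintiles(self, tiny_dataset):
        regimes = tiny_dataset.spec.gene_regimes()
        plofs = tiny_dataset.variants.query(
            "consequence_class in ('plof_snv', 'plof_indel') and dataset == 'population'"
        )
        tid_L = {t: m.cds_length for t, m in tiny_dataset.models.items()}
        for gene, regime in regimes.items():
            sub = plofs[plofs["gene_id"] == gene]
            if regime.name == "zero":
                assert sub.empty
                continue
            if sub.empty:
                continue
            L = sub["transcript_id"].map(tid_L).to_numpy()
            q = quintiles_of(sub["cds_pos"].to_numpy(), L)
            assert set(q) <= regime.allowed_quintiles

    def test_uniform_regime_positions_pass_chi_squared(self):
        spec = SyntheticSpec(
            plof_regimes=((uniform_regime(), 30),),
            counts={
                "synonymous": CountDistribution(kind="fixed", mean=5),
                "missense": CountDistribution(kind="fixed", mean=5),
                "plof": CountDistribution(kind="fixed", mean=40),
                "clinical_plof": CountDistribution(kind="fixed", mean=5),
            },
            sequence_consistent=False,
            seed=13,
        )
        ds = generate_dataset(spec)
        plofs = ds.variants.query("consequence_class in ('plof_snv', 'plof_indel')")
        tid_L = {t: m.cds_length for t, m in ds.models.items()}
        L = plofs["transcript_id"].map(tid_L).to_numpy()
        q = quintiles_of(plofs["cds_pos"].to_numpy(), L)
        counts = np.bincount(q, minlength=6)[1:]
        assert stats.chisquare(counts).pvalue > 0.001


class TestTruthTable:
    def test_regimes_map_to_expected_roles(self, tiny_spec):
        truth = truth_table(tiny_spec)
        by_regime = truth.groupby("regime")["expected_role"].unique()
        assert by_regime["uniform"].tolist() == ["uniform"]
        assert by_regime["start_depleted"].tolist() == ["non_uniform"]
        assert by_regime["end_clustered"].tolist() == ["non_uniform"]
        assert by_regime["zero"].tolist() == ["empty"]
        assert len(truth) == tiny_spec.n_genes


class TestCountDistribution:
    def test_fixed(self):
        rng = np.random.default_rng(0)
        assert set(CountDistribution(kind="fixed", mean=7).sample(rng, 10)) == {7}

    def test_uniform_int_bounds(self):
        rng = np.random.default_rng(0)
        draws = CountDistribution(kind="uniform_int", low=10, high=50).sample(rng, 500)
        assert draws.min() >= 10 and draws.max() <= 50

    def test_negbin_respects_minimum(self):
        rng = np.random.default_rng(0)
        draws = CountDistribution(mean=15.0, minimum=5).sample(rng, 500)
        assert draws.min() >= 5
        # truncation at 5 shifts the mean of a mean-15, dispersion-1 negbin up
        assert 15 <= draws.mean() <= 25
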