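"""Pair enumeration, correlation scoring, randomization test, gene validation."""

import numpy as np
import pandas as pd
import pytest

from emdperiod.coexpression import (
    ComplexDefinition,
    background_distribution,
    build_network,
    coexpression_ratio,
    coexpression_test,
    coexpression_threshold,
    enumerate_pairs,
    pair_score,
    read_complexes,
    summarize_complex,
    validate_genes,
)
from emdperiod.synthetic import make_complex_matrix


@pytest.fixture(scope="module")
def noise_matrix():
    rng = np.random.default_rng(77)
    return pd.DataFrame(
        rng.standard_normal((400, 36)), index=[f"g{i:04d}" for i in range(400)]
    )


@pytest.fixture(scope="module")
def noise_background(noise_matrix):
    return background_distribution(noise_matrix, n_samples=100_000, seed=5)


class TestEnumeratePairs:
    @pytest.mark.parametrize("m,expected", [(2, 1), (44, 946), (49, 1176), (66, 2145), (24, 276)])
    def test_pair_counts(self, m, expected):
        pairs = enumerate_pairs([f"y{i}" for i in range(m)])
        assert len(pairs) == expected == m * (m - 1) // 2
        assert len(set(map(frozenset, pairs))) == len(pairs)

    def test_fewer_than_two_members(self):
        assert enumerate_pairs(["only"]) == []


class TestPairScore:
    def test_self_correlation(self):
        x = np.random.default_rng(1).standard_normal(36)
        assert pair_score(x, x) == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.random.default_rng(2).standard_normal(36)
        assert pair_score(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pair_score(np.ones(36), np.arange(36.0))

    def test_noisy_copies_of_shared_latent(self, t36):
        rng = np.random.default_rng(42)
        latent = np.sin(2 * np.pi * t36 / 12)
        a = latent + rng.normal(0, 0.3, 36)
        b = latent + rng.normal(0, 0.3, 36)
        s = pair_score(a, b)
        assert s >= 0.8
        assert s == pytest.approx(np.corrcoef(a, b)[0, 1])


class TestBackground:
    def test_reproducible(self, noise_matrix):
        a = background_distribution(noise_matrix, n_samples=5000, seed=9)
        b = background_distribution(noise_matrix, n_samples=5000, seed=9)
        assert np.array_equal(a, b)

    def test_null_95th_percentile(self, noise_background):
        # for independent N(0,1) profiles of length 36 the correlation is
        # approximately N(0, 1/35): q95 ~ 1.645/sqrt(35) ~ 0.28
        thr = coexpression_threshold(noise_background, 95)
        assert thr == pytest.approx(1.645 / np.sqrt(35), abs=0.04)

    def test_false_positive_control(self, noise_matrix, noise_background):
        # fraction of random pairs called coexpressed ~ 5%
        rng = np.random.default_rng(123)
        thr = coexpression_threshold(noise_background, 95)
        n_hit = 0
        trials = 10_000
        x = noise_matrix.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        z = xc / np.sqrt((xc**2).sum(axis=1, keepdims=True))
        for _ in range(trials):
            i, j = rng.choice(400, 2, replace=False)
            n_hit += (z[i] @ z[j]) >= thr
        assert n_hit / trials == pytest.approx(0.05, abs=0.01)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            background_distribution(pd.DataFrame(np.zeros((5, 36))), 100, 0)


class TestCoexpressionTest:
    def test_extremes(self, noise_background):
        assert coexpression_test(noise_background.max() + 0.1, noise_background)
        assert not coexpression_test(noise_background.min() - 0.1, noise_background)

    def test_tie_at_quantile_counts(self):
        background = np.linspace(-1, 1, 101)
        thr = coexpression_threshold(background, 95)
        assert coexpression_test(thr, background)  # "at least the 95th percentile"


class TestSummarizeComplex:
    @pytest.mark.parametrize(
        "n_co,n_tot,expected", [(932, 946, 0.985), (126, 276, 0.457), (1176, 1176, 1.0), (0, 10, 0.0)]
    )
    def test_ratio_arithmetic(self, n_co, n_tot, expected):
        assert coexpression_ratio(n_co, n_tot) == expected

    def test_shared_latent_block(self):
        matrix, membership = make_complex_matrix(
            n_complexes=1, genes_per_complex=44, n_background=200, noise_sd=0.3, seed=3
        )
        background = background_distribution(matrix, n_samples=50_000, seed=3)
        cdef = ComplexDefinition(
            "C001", "synthetic complex 1", frozenset(membership["gene_id"])
        )
        summary = summarize_complex(cdef, matrix, background)
        assert summary.n_total_pairs == 946
        assert summary.ratio >= 0.9

    def test_sigma_zero_perfect_block(self):
        matrix, membership = make_complex_matrix(1, 10, 50, noise_sd=0.0, seed=1)
        background = background_distribution(matrix, n_samples=20_000, seed=1)
        cdef = ComplexDefinition("C001", "c", frozenset(membership["gene_id"]))
        summary = summarize_complex(cdef, matrix, background)
        assert all(p.score == pytest.approx(1.0) for p in summary.pairs)
        assert summary.ratio == 1.0

    def test_background_pairs_rarely_coexpressed(self, noise_matrix, noise_background):
        cdef = ComplexDefinition("B1", "noise", frozenset(noise_matrix.index[:30]))
        summary = summarize_complex(cdef, noise_matrix, noise_background)
        assert summary.ratio <= 0.1

    def test_too_few_members_present(self, noise_matrix, noise_background):
        cdef = ComplexDefinition("X1", "absent", frozenset({"nope1", "nope2"}))
        summary = summarize_complex(cdef, noise_matrix, noise_background)
        assert summary.n_total_pairs == 0
        assert summary.ratio is None


class TestValidateGenes:
    @pytest.fixture()
    def block(self):
        matrix, membership = make_complex_matrix(1, 8, 100, noise_sd=0.2, seed=11)
        background = background_distribution(matrix, n_samples=20_000, seed=11)
        cdef = ComplexDefinition("C001", "c", frozenset(membership["gene_id"]))
        summary = summarize_complex(cdef, matrix, background)
        return cdef, matrix, summary

    def test_all_periodic_complex(self, block):
        cdef, matrix, summary = block
        labels = {g: "PERIODIC" for g in cdef.members}
        validations, unmapped, edges, nodes = validate_genes(cdef, labels, matrix, summary)
        assert not unmapped
        assert all(v.category == "PERIODIC_BOTH" for v in validations)
        assert len(validations) == 8

    def test_categories_partition_members(self, block):
        cdef, matrix, summary = block
        members = sorted(cdef.members)
        labels = {}
        for i, g in enumerate(members):
            labels[g] = ["PERIODIC", "PUTATIVE_PERIODIC", "NON_DETECTABLE"][i % 3]
        validations, unmapped, edges, nodes = validate_genes(cdef, labels, matrix, summary)
        counts = nodes["category"].value_counts()
        assert counts.sum() == len(members)
        assert counts["PERIODIC_BOTH"] == 3
        assert counts["PERIODIC_EMD_ONLY"] == 3
        assert counts["PERIODIC_NEITHER"] == 2

    def test_unmapped_genes_reported(self, block):
        cdef, matrix, summary = block
        members = sorted(cdef.members)
        labels = {g: "PERIODIC" for g in members[:-2]}
        validations, unmapped, _, _ = validate_genes(cdef, labels, matrix, summary)
        assert sorted(unmapped) == members[-2:]
        assert len(validations) == len(members) - 2

    def test_network_export(self, block):
        cdef, matrix, summary = block
        labels = {g: "PUTATIVE_PERIODIC" for g in cdef.members}
        _, _, edges, nodes = validate_genes(cdef, labels, matrix, summary)
        g = build_network(edges, nodes)
        assert g.number_of_nodes() >= 8  # all members present as nodes
        assert g.number_of_edges() == len(edges)
        assert set(edges.columns) == {"gene_a", "gene_b", "score"}


def test_read_complexes_roundtrip(tmp_path):
    table = pd.DataFrame(
        {
            "complex_id": ["500.60.10"] * 3 + ["360.10.10"] * 2,
            "complex_name": ["mito ribosome large"] * 3 + ["20S proteasome"] * 2,
            "gene_id": ["YA1", "YA2", "YA3", "YB1", "YB2"],
        }
    )
    path = tmp_path / "complexes.tsv"
    table.to_csv(path, sep="\t", index=False)
    complexes = read_complexes(path)
    assert {c.complex_id for c in complexes} == {"500.60.10", "360.10.10"}
    mito = next(c for c in complexes if c.complex_id == "500.60.10")
    assert mito.members == frozenset({"YA1", "YA2", "YA3"})
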