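"""Bulk-to-single-cell matching: standardization, similarity, projection."""

import numpy as np
import pytest

from ductmap import (
    BulkPanel,
    EmbeddingResult,
    SimilarityMatrix,
    TsneParams,
    cluster_cells,
    cocluster_heatmap_order,
    ct_to_expression,
    generate_bulk,
    generate_cohort,
    match_and_project,
    scaled_study_design,
    similarity_matrix,
    standardize_overlap,
)


@pytest.fixture(scope="module")
def matched_data():
    design, programs = scaled_study_design(n_cells=250)
    ct, truth = generate_cohort(design, programs, seed=31)
    et = ct_to_expression(ct)
    bulk, bulk_truth = generate_bulk(design, programs, noise_sd=0.5, seed=32)
    return design, et, truth, bulk, bulk_truth


def fake_embedding(et, seed=0):
    rng = np.random.default_rng(seed)
    return EmbeddingResult(
        coords=rng.normal(size=(et.n_cells, 2)),
        kl_trace=np.array([[1, 1.0]]),
        params=TsneParams(),
        cell_ids=tuple(et.cell_ids),
    )


class TestStandardizeOverlap:
    def test_per_gene_zscore_within_each_dataset(self, matched_data):
        design, et, _, bulk, _ = matched_data
        sc, bk, genes = standardize_overlap(et, bulk, design.overlap_genes)
        for m in (sc, bk):
            np.testing.assert_allclose(m.mean(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(m.std(axis=0), 1.0, atol=1e-12)
        assert len(genes) == sc.shape[1] == bk.shape[1]

    def test_hand_computed_toy(self, matched_data):
        design, et, _, _, _ = matched_data
        bulk = BulkPanel(
            sample_ids=("s1", "s2", "s3"),
            cell_types=("a", "a", "b"),
            genes=("Col18a1", "Vegfa", "Tnf"),
            profiles=np.array([[1.0, 4.0, 0.0], [2.0, 6.0, 1.0], [3.0, 8.0, 5.0]]),
        )
        _, bk, genes = standardize_overlap(et, bulk, ["Col18a1", "Vegfa", "Tnf"])
        # population z-scores: (x - mean) / sd with sd = sqrt(mean((x-mean)^2))
        s = 1.2247449  # sqrt(3/2)
        col3 = (np.array([0.0, 1.0, 5.0]) - 2.0) / np.sqrt(14.0 / 3.0)
        expected = np.column_stack([[-s, 0, s], [-s, 0, s], col3])
        np.testing.assert_allclose(bk, expected, atol=1e-6)

    def test_constant_gene_dropped_from_both(self, matched_data):
        design, et, _, bulk, _ = matched_data
        profiles = bulk.profiles.copy()
        profiles[:, 0] = 5.0  # constant in bulk only
        bulk2 = BulkPanel(bulk.sample_ids, bulk.cell_types, bulk.genes, profiles)
        sc, bk, genes = standardize_overlap(et, bulk2, design.overlap_genes)
        assert bulk.genes[0] not in genes
        assert sc.shape[1] == bk.shape[1] == len(design.overlap_genes) - 1

    def test_too_few_usable_genes_rejected(self, matched_data):
        design, et, _, bulk, _ = matched_data
        with pytest.raises(ValueError):
            standardize_overlap(et, bulk, design.overlap_genes[:2])


class TestSimilarityMatrix:
    def test_bulk_copied_from_cell_has_similarity_one(self, matched_data):
        design, et, _, bulk, _ = matched_data
        sc, bk, genes = standardize_overlap(et, bulk, design.overlap_genes)
        bk2 = np.vstack([bk, sc[5]])  # bulk sample equal to cell 5's z-profile
        sim = similarity_matrix(
            sc, bk2, et.cell_ids, list(bulk.sample_ids) + ["copy"], genes
        )
        assert np.isclose(sim.values[-1, 5], 1.0)
        assert sim.values[-1].argmax() == 5

    def test_negated_profile_has_similarity_minus_one(self, matched_data):
        design, et, _, bulk, _ = matched_data
        sc, bk, genes = standardize_overlap(et, bulk, design.overlap_genes)
        sim = similarity_matrix(
            sc, -sc[7][None, :], et.cell_ids, ["neg"], genes
        )
        assert np.isclose(sim.values[0, 7], -1.0)

    def test_pairwise_correlation_oracle(self):
        rng = np.random.default_rng(33)
        cells = rng.normal(size=(4, 6))
        bulk = rng.normal(size=(3, 6))
        sim = similarity_matrix(cells, bulk, list("abcd"), list("xyz"), [f"g{i}" for i in range(6)])
        for b in range(3):
            for c in range(4):
                want = np.corrcoef(bulk[b], cells[c])[0, 1]
                assert np.isclose(sim.values[b, c], want)

    def test_invariant_to_gene_order_and_affine_rescaling(self, matched_data):
        design, et, _, bulk, _ = matched_data
        genes = list(design.overlap_genes)
        sc, bk, used = standardize_overlap(et, bulk, genes)
        sim1 = similarity_matrix(sc, bk, et.cell_ids, bulk.sample_ids, used)

        perm = np.random.default_rng(1).permutation(len(genes))
        genes_p = [genes[i] for i in perm]
        # affine rescale one gene in bulk space; z-scoring absorbs it
        profiles = bulk.profiles.copy()
        profiles[:, 3] = 2.5 * profiles[:, 3] + 7.0
        bulk2 = BulkPanel(bulk.sample_ids, bulk.cell_types, bulk.genes, profiles)
        sc2, bk2, used2 = standardize_overlap(et, bulk2, genes_p)
        sim2 = similarity_matrix(sc2, bk2, et.cell_ids, bulk.sample_ids, used2)
        np.testing.assert_allclose(sim1.values, sim2.values, atol=1e-10)


class TestMatchAndProject:
    def test_m1_projects_exactly_at_the_copied_cell(self, matched_data):
        design, et, _, bulk, _ = matched_data
        sc, bk, genes = standardize_overlap(et, bulk, design.overlap_genes)
        sim = similarity_matrix(sc, sc[9][None, :], et.cell_ids, ["copy"], genes)
        emb = fake_embedding(et)
        asg = cluster_cells(et, k=6)
        proj = match_and_project(sim, emb, asg, ["copytype"], m=1)
        row = proj.matches.iloc[0]
        assert row.matched_cell_id == et.cell_ids[9]
        assert np.isclose(row.similarity, 1.0)
        np.testing.assert_allclose([row.tsne1, row.tsne2], emb.coords[9])

    def test_distributions_sum_to_one_and_modal_is_argmax(self, matched_data):
        design, et, _, bulk, _ = matched_data
        sc, bk, genes = standardize_overlap(et, bulk, design.overlap_genes)
        sim = similarity_matrix(sc, bk, et.cell_ids, bulk.sample_ids, genes)
        emb = fake_embedding(et)
        asg = cluster_cells(et, k=6)
        proj = match_and_project(sim, emb, asg, bulk.cell_types, m=20)
        for ctype, dist in proj.cluster_distribution.items():
            assert np.isclose(sum(dist.values()), 1.0)
            assert proj.modal_cluster[ctype] == max(dist, key=lambda k: (dist[k], -k))
        assert len(proj.matches) == bulk.n_samples * 20

    def test_bulk_types_map_to_source_population_cluster(self):
        """Modal cluster of each synthetic bulk type equals its source
        population's dominant cluster in >= 90% of 20 seeded runs."""
        hits = trials = 0
        for seed in range(20):
            design, programs = scaled_study_design(n_cells=250)
            ct, truth = generate_cohort(design, programs, seed=400 + seed)
            et = ct_to_expression(ct)
            bulk, bulk_truth = generate_bulk(design, programs, noise_sd=0.5, seed=500 + seed)
            sc, bk, genes = standardize_overlap(et, bulk, design.overlap_genes)
            sim = similarity_matrix(sc, bk, et.cell_ids, bulk.sample_ids, genes)
            asg = cluster_cells(et, k=6)
            emb = fake_embedding(et, seed)
            proj = match_and_project(sim, emb, asg, bulk.cell_types, m=20)
            src = {}
            for (label, pop, _n), _ in zip(design.bulk_design, range(99)):
                src[label] = pop
            for ctype, modal in proj.modal_cluster.items():
                pop = src[ctype]
                members = asg.labels[truth.populations == pop]
                dominant = np.bincount(members).argmax()
                trials += 1
                hits += int(modal == dominant)
        assert hits / trials >= 0.9

    def test_empty_similarity_rejected(self, matched_data):
        design, et, _, bulk, _ = matched_data
        emb = fake_embedding(et)
        asg = cluster_cells(et, k=3)
        sim = SimilarityMatrix(
            values=np.zeros((0, et.n_cells)),
            bulk_ids=(),
            cell_ids=tuple(et.cell_ids),
            overlap_genes=("a", "b", "c"),
        )
        with pytest.raises(ValueError):
            match_and_project(sim, emb, asg, [], m=5)


class TestCoclusterOrder:
    def test_identical_rows_become_adjacent(self):
        rng = np.random.default_rng(34)
        base = rng.normal(size=(5, 8))
        values = np.vstack([base[0], base[1], base[0], base[2], base[3], base[4]])
        values = np.clip(values, -1, 1) * 0.5
        sim = SimilarityMatrix(
            values=values,
            bulk_ids=tuple(f"b{i}" for i in range(6)),
            cell_ids=tuple(f"c{i}" for i in range(8)),
            overlap_genes=("x", "y", "z"),
        )
        row_order, col_order = cocluster_heatmap_order(sim)
        pos = {v: i for i, v in enumerate(row_order)}
        assert abs(pos[0] - pos[2]) == 1  # duplicates adjacent
        assert sorted(row_order) == list(range(6))
        assert sorted(col_order) == list(range(8))

    def test_block_structure_is_contiguous(self):
        """Two similarity blocks end up contiguous in the leaf order."""
        values = np.full((6, 6), 0.1)
        values[:3, :3] = 0.9
        values[3:, 3:] = 0.9
        rng = np.random.default_rng(35)
        values = np.clip(values + rng.normal(0, 0.01, values.shape), -1, 1)
        sim = SimilarityMatrix(
            values=values,
            bulk_ids=tuple(f"b{i}" for i in range(6)),
            cell_ids=tuple(f"c{i}" for i in range(6)),
            overlap_genes=("x", "y", "z"),
        )
        row_order, _ = cocluster_heatmap_order(sim)
        first_block = {int(np.flatnonzero(row_order == i)[0]) for i in range(3)}
        assert first_block in ({0, 1, 2}, {3, 4, 5})
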