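"""Synthetic-data generator: determinism, planted structure, contracts."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from aascan.synth import (
    ConfigError,
    generate_cohort,
    generate_genes,
    generate_genesets_and_network,
    simulate,
    write_dataset,
)

from conftest import small_config


def dir_checksums(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(d).iterdir())
    }


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_genes", 0),
            ("driver_boost", 0.5),
            ("transcripts_per_gene", (3, 2)),
            ("network_density", 1.5),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field):
            small_config(**{field: value})

    def test_drivers_must_fit(self):
        with pytest.raises(ConfigError, match="drivers_per_cancer"):
            small_config(n_genes=10, drivers_per_cancer=10)

    def test_weights_must_sum_to_one(self):
        w = np.full((2, 96), 1.0 / 96)
        w[0, 0] += 0.01
        with pytest.raises(ConfigError, match="spectrum_weights"):
            small_config(spectrum_weights=w)


class TestGenerateGenes:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        a = generate_genes(small_config(seed=1))
        b = generate_genes(small_config(seed=1))
        assert a.reference == b.reference
        assert [
            (m.transcript_id, m.strand, m.cds_exons) for g in a.genes for m in g.transcripts
        ] == [
            (m.transcript_id, m.strand, m.cds_exons) for g in b.genes for m in g.transcripts
        ]

    def test_forced_transcript_count(self):
        g = generate_genes(small_config(transcripts_per_gene=(2, 2)))
        assert all(len(x.transcripts) == 2 for x in g.genes)

    def test_both_strands_and_isoform_length_variety(self):
        g = generate_genes(small_config())
        strands = {x.strand for x in g.genes}
        assert strands == {"+", "-"}
        multi = [x for x in g.genes if len(x.transcripts) > 1]
        assert multi
        assert any(
            len({m.protein_length for m in x.transcripts}) > 1 for x in multi
        )


class TestGenerateCohort:
    def test_empty_cohort_when_no_samples(self):
        cfg = small_config(samples_per_cancer=0)
        genome = generate_genes(cfg)
        variants, truth = generate_cohort(cfg, genome)
        assert variants.empty
        assert truth.record_consequences == []

    def test_no_planting_when_boost_is_one(self):
        """driver_boost=1: per-base missense rates in driver vs non-driver
        genes agree within 3 Monte-Carlo SDs, pooled over 10 seeds."""
        mis_d = mis_b = len_d = len_b = 0
        for seed in range(10):
            cfg = small_config(
                seed=seed, driver_boost=1.0, n_genes=60, samples_per_cancer=6
            )
            genome = generate_genes(cfg)
            variants, truth = generate_cohort(cfg, genome)
            labels = np.array(truth.record_consequences)
            drivers = set().union(*truth.driver_genes.values())
            cds_len = {
                g.gene_id: g.longest.cds_length for g in genome.genes
            }
            # locate each missense record's gene by position
            spans = [
                (g.longest.span, g.gene_id) for g in genome.genes
            ]
            pos = variants["pos"].to_numpy()
            for (s, e), gid in spans:
                n_mis = int(
                    ((pos >= s) & (pos <= e) & (labels == "missense")).sum()
                )
                if gid in drivers:
                    mis_d += n_mis
                    len_d += cds_len[gid]
                else:
                    mis_b += n_mis
                    len_b += cds_len[gid]
        rate_d = mis_d / len_d
        rate_b = mis_b / len_b
        sd = np.sqrt(mis_d) / len_d + np.sqrt(mis_b) / len_b
        assert abs(rate_d - rate_b) <= 3 * sd

    def test_driver_enrichment_when_boosted(self, small_dataset):
        ds = small_dataset
        drivers = set().union(*ds.truth.driver_genes.values())
        mis = ds.aas[ds.aas["consequence"] == "missense"]
        per_gene = mis.groupby("gene_id").size()
        cds_len = {g.gene_id: g.longest.cds_length for g in ds.genome.genes}
        d_rate = sum(per_gene.get(g, 0) for g in drivers) / sum(
            cds_len[g] for g in drivers
        )
        b_rate = sum(v for g, v in per_gene.items() if g not in drivers) / sum(
            v for g, v in cds_len.items() if g not in drivers
        )
        assert d_rate > 3 * b_rate


class TestGeneratePredictions:
    def test_stochastic_ordering_and_support(self, small_dataset):
        ds = small_dataset
        preds = ds.predictions
        assert ((preds["probability"] >= 0) & (preds["probability"] <= 1)).all()
        drivers = set().union(*ds.truth.driver_proteins.values())
        is_d = preds["protein_id"].isin(drivers)
        assert preds.loc[is_d, "probability"].mean() > preds.loc[~is_d, "probability"].mean()

    def test_one_row_per_unique_missense(self, small_dataset):
        ds = small_dataset
        keys = ds.aas[ds.aas["consequence"] == "missense"].drop_duplicates(
            subset=["protein_id", "residue_pos", "ref_aa", "alt_aa"]
        )
        assert len(ds.predictions) == len(keys)
        assert not ds.predictions.duplicated(
            subset=["protein_id", "residue_pos", "ref_aa", "alt_aa"]
        ).any()

    def test_unknown_fraction_matches_beta_mass(self, small_dataset):
        """Fraction labelled unknown equals the Beta CDF mass between the
        thresholds within 3 binomial SDs, per mixture component."""
        ds = small_dataset
        low, high = ds.config.class_thresholds
        drivers = set().union(*ds.truth.driver_proteins.values())
        for params, group in (
            (ds.config.harm_high, ds.predictions[ds.predictions.protein_id.isin(drivers)]),
            (ds.config.harm_low, ds.predictions[~ds.predictions.protein_id.isin(drivers)]),
        ):
            a, b = params
            expected = beta_dist.cdf(high, a, b) - beta_dist.cdf(low, a, b)
            got = (group["class"] == "unknown").mean()
            sd = np.sqrt(max(expected * (1 - expected), 1e-12) / len(group))
            assert abs(got - expected) <= 3 * sd + 1e-9


class TestGenesetsAndNetwork:
    def test_every_driver_in_a_planted_pathway(self, small_dataset):
        ds = small_dataset
        for cancer, drivers in ds.truth.driver_genes.items():
            planted_members = set().union(
                *(ds.pathways.sets[t] for t in ds.truth.driver_pathways[cancer])
            )
            assert set(drivers) <= planted_members

    def test_simple_graph_contract(self, small_dataset):
        import networkx as nx

        g = small_dataset.network
        assert nx.number_of_selfloops(g) == 0
        assert isinstance(g, nx.Graph)  # multi-edges impossible by type

    def test_within_pathway_density_exceeds_background(self):
        """Averaged over 10 seeds, same-pathway gene pairs are connected
        far more often than random pairs (direct edge counting)."""
        within_hits = within_tot = cross_hits = cross_tot = 0
        rng = np.random.default_rng(0)
        for seed in range(10):
            cfg = small_config(seed=seed, samples_per_cancer=0, n_genes=80)
            genome = generate_genes(cfg)
            _, truth = generate_cohort(cfg, genome)
            _, pw, net = generate_genesets_and_network(genome, truth, cfg)
            members = set()
            for s in pw.sets.values():
                ms = sorted(s)
                members |= s
                for i in range(len(ms)):
                    for j in range(i + 1, len(ms)):
                        within_tot += 1
                        within_hits += net.has_edge(ms[i], ms[j])
            nodes = sorted(net.nodes)
            for _ in range(2000):
                a, b = rng.choice(len(nodes), 2, replace=False)
                u, v = nodes[a], nodes[b]
                cross_tot += 1
                cross_hits += net.has_edge(u, v)
        assert within_hits / within_tot > cross_hits / cross_tot

    def test_pathway_size_must_fit(self):
        with pytest.raises(ConfigError, match="pathway_size"):
            small_config(pathway_size=200, n_genes=100)


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        cfg1 = small_config(seed=3)
        cfg2 = small_config(seed=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate(cfg1), d1)
        write_dataset(simulate(cfg2), d2)
        assert dir_checksums(d1) == dir_checksums(d2)

    def test_different_seed_different_cohort(self, tmp_path):
        v1, _ = generate_cohort(small_config(seed=1), generate_genes(small_config(seed=1)))
        v2, _ = generate_cohort(small_config(seed=2), generate_genes(small_config(seed=2)))
        assert not v1.equals(v2)
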