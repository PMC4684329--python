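"""Synthetic-data generator: determinism, planted effects, truth integrity."""

import numpy as np
import pandas as pd
import pytest

from helpdm.annotation import annotate_loci
from helpdm.simulate import (
    SimConfig,
    TruthTable,
    generate_annotation,
    generate_loci,
    make_design,
    simulate_dataset,
    simulate_expression,
    simulate_methylome,
)


class TestConfigValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(ValueError, match="de_rate"):
            SimConfig(de_rate=1.5)

    def test_dm_rate_keys_checked(self):
        with pytest.raises(ValueError, match="PR, GB, IG"):
            SimConfig(dm_rate_by_compartment={"PR": 0.1, "GB": 0.1})

    def test_band_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(
                delta_magnitude_distribution={
                    "negligible": 0.5, "small": 0.5, "moderate": 0.5,
                }
            )

    def test_fragment_range_checked(self):
        with pytest.raises(ValueError, match="fragment_size_range"):
            SimConfig(fragment_size_range=(2000, 200))

    def test_roundtrip_through_dict(self):
        cfg = SimConfig(seed=5, n_genes=10)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestGenerateAnnotation:
    def test_zero_genes(self):
        genes, cgis, _ = generate_annotation(SimConfig(n_genes=0))
        assert genes.empty and cgis.empty

    def test_seed_determinism_byte_identical(self):
        cfg = SimConfig(seed=123, n_genes=40)
        a_genes, a_cgis, _ = generate_annotation(cfg)
        b_genes, b_cgis, _ = generate_annotation(cfg)
        assert a_genes.to_csv() == b_genes.to_csv()
        assert a_cgis.to_csv() == b_cgis.to_csv()

    def test_full_cgi_fraction_puts_island_in_every_promoter(self):
        from helpdm.annotation import GeneModel, promoter_window

        cfg = SimConfig(
            n_genes=50, cgi_promoter_fraction=1.0,
            chrom_lengths={"chr1": 2_000_000}, seed=1,
        )
        genes, cgis, chrom_lengths = generate_annotation(cfg)
        assert len(cgis) == 50
        # each island overlaps its gene's promoter window
        hits = 0
        for _, c in cgis.iterrows():
            for g in genes.itertuples(index=False):
                pw = promoter_window(
                    GeneModel(g.gene_id, g.chrom, g.strand, g.tss, g.tes),
                    chrom_length=chrom_lengths[g.chrom],
                )
                if g.chrom == c.chrom and max(pw[0], c.start) < min(pw[1], c.end):
                    hits += 1
                    break
        assert hits == 50

    def test_genes_do_not_overlap(self):
        genes, _, _ = generate_annotation(SimConfig(seed=3, n_genes=200))
        for chrom, grp in genes.groupby("chrom"):
            spans = sorted(
                (min(t, e), max(t, e) + 1)
                for t, e in zip(grp["tss"], grp["tes"])
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_packing_raises(self):
        cfg = SimConfig(
            n_genes=100, gene_length_range=(5_000, 5_000),
            chrom_lengths={"chr1": 100_000},
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_annotation(cfg)


class TestGenerateLoci:
    def test_density_zero_is_empty(self):
        cfg = SimConfig(locus_density=0.0)
        loci = generate_loci(cfg, {"chr1": 100_000})
        assert loci.empty

    def test_direct_placement_counts_and_sizes(self):
        cfg = SimConfig(locus_density=5.0, seed=2)
        loci = generate_loci(cfg, {"chr1": 100_000})
        assert len(loci) == 50
        lengths = loci["end"] - loci["start"]
        assert lengths.between(200, 2000).all()
        assert (loci["start"] >= 0).all() and (loci["end"] <= 100_000).all()
        # non-overlapping
        srt = loci.sort_values("start")
        assert (srt["start"].to_numpy()[1:] >= srt["end"].to_numpy()[:-1]).all()

    def test_digest_mode_no_ccgg_sequence(self):
        # a pure-AT sequence has no CCGG site at all
        cfg = SimConfig(seed=4)
        loci = generate_loci(cfg, {"chr1": 3_000}, mode="random-sequence-digest")
        # random ACGT of 3 kb will usually carry sites; force the no-site case
        from helpdm.annotation import msp_digest

        assert msp_digest("AT" * 500, (1, 2000)) == []
        assert set(loci.columns) == {"locus_id", "chrom", "start", "end"}

    def test_digest_mode_fragments_are_ccgg_bounded(self):
        cfg = SimConfig(seed=5, fragment_size_range=(50, 2000))
        loci, seqs = generate_loci(
            cfg, {"chr1": 20_000}, mode="random-sequence-digest",
            return_sequences=True,
        )
        assert len(loci) > 0
        seq = seqs["chr1"]
        for r in loci.itertuples(index=False):
            # each fragment end sits one base into a CCGG site
            assert seq[r.start - 1 : r.start + 3] == "CCGG"
            assert seq[r.end - 1 : r.end + 3] == "CCGG"

    def test_infeasible_density(self):
        cfg = SimConfig(locus_density=100.0, fragment_size_range=(2000, 2000))
        with pytest.raises(ValueError, match="infeasible"):
            generate_loci(cfg, {"chr1": 100_000})


def _labelled_loci(n, compartment="GB"):
    return pd.DataFrame(
        {
            "locus_id": [f"L{i:05d}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 3000,
            "end": np.arange(n) * 3000 + 500,
            "compartment": compartment,
            "linked_gene": None,
        }
    )


class TestSimulateMethylome:
    def test_requires_compartments(self):
        cfg = SimConfig()
        with pytest.raises(ValueError, match="annotated"):
            simulate_methylome(cfg, _labelled_loci(5).drop(columns="compartment"))

    def test_no_planted_effects_under_zero_rates(self):
        cfg = SimConfig(
            dm_rate_by_compartment={"PR": 0.0, "GB": 0.0, "IG": 0.0}, seed=1
        )
        _, _, truth = simulate_methylome(cfg, _labelled_loci(500))
        assert truth.loci["is_dm"].sum() == 0
        assert (truth.loci["true_delta"] == 0).all()

    def test_noise_free_single_dm_locus_exact_delta(self):
        """With zero noise the observed paired mean difference equals the
        planted delta exactly."""
        cfg = SimConfig(
            n_subjects=4, subject_sd=0.0, residual_sd=0.0,
            dm_rate_by_compartment={"PR": 0.0, "GB": 1.0, "IG": 0.0},
            hyper_given_dm_by_compartment={"PR": 0.5, "GB": 1.0, "IG": 0.5},
            delta_magnitude_distribution={
                "negligible": 0.0, "small": 0.0, "moderate": 1.0,
            },
            seed=3,
        )
        loci = _labelled_loci(1)
        matrix, design, truth = simulate_methylome(cfg, loci)
        planted = truth.loci["true_delta"].iloc[0]
        assert planted < -1.0  # hypermethylated, moderate band
        d = (
            matrix[list(design.tumor)].to_numpy()
            - matrix[list(design.normal)].to_numpy()
        )
        assert d == pytest.approx(planted)

    def test_planted_counts_within_binomial_bounds(self):
        rates = {"PR": 0.2, "GB": 0.4, "IG": 0.1}
        cfg = SimConfig(dm_rate_by_compartment=rates, seed=8)
        loci = pd.concat(
            [_labelled_loci(3000, c) for c in ("PR", "GB", "IG")],
            ignore_index=True,
        )
        loci["locus_id"] = [f"L{i:05d}" for i in range(len(loci))]
        _, _, truth = simulate_methylome(cfg, loci)
        for comp, rate in rates.items():
            n_dm = truth.loci.loc[truth.loci["compartment"] == comp, "is_dm"].sum()
            expect = 3000 * rate
            bound = 3 * np.sqrt(3000 * rate * (1 - rate))
            assert abs(n_dm - expect) <= bound, (comp, n_dm)

    def test_truth_invariants_validated(self):
        bad = pd.DataFrame(
            {"locus_id": ["a"], "compartment": ["GB"], "is_dm": [False],
             "true_delta": [0.5]}
        )
        with pytest.raises(ValueError, match="true_delta"):
            TruthTable(loci=bad).validate()


class TestSimulateExpression:
    def test_full_coupling_makes_every_pair_canonical(self):
        cfg = SimConfig(
            n_subjects=8, canonical_coupling=1.0, de_rate=0.0, seed=6,
        )
        genes, cgis, chrom_lengths = generate_annotation(cfg)
        loci = generate_loci(cfg, chrom_lengths)
        ann = annotate_loci(loci, genes, cgis, chrom_lengths=chrom_lengths)
        _, design, truth = simulate_methylome(cfg, ann)
        _, truth = simulate_expression(cfg, genes, truth, ann, design)
        assert len(truth.pairs) > 0
        assert truth.pairs["canonical"].all()

    def test_zero_coupling_makes_no_pair_canonical(self):
        cfg = SimConfig(n_subjects=8, canonical_coupling=0.0, de_rate=0.0, seed=7)
        genes, cgis, chrom_lengths = generate_annotation(cfg)
        loci = generate_loci(cfg, chrom_lengths)
        ann = annotate_loci(loci, genes, cgis, chrom_lengths=chrom_lengths)
        _, design, truth = simulate_methylome(cfg, ann)
        _, truth = simulate_expression(cfg, genes, truth, ann, design)
        assert len(truth.pairs) > 0
        assert not truth.pairs["canonical"].any()

    def test_genes_appear_exactly_once_in_truth(self):
        cfg = SimConfig(seed=9, n_genes=80)
        data = simulate_dataset(cfg)
        truth = data["truth"]
        assert len(truth.genes) == 80
        assert not truth.genes["gene_id"].duplicated().any()
        assert not truth.pairs["gene_id"].duplicated().any()
        assert len(truth.loci) == len(data["loci"])

    def test_uncoupled_de_rate_zero(self):
        cfg = SimConfig(
            seed=10,
            de_rate=0.0,
            dm_rate_by_compartment={"PR": 0.0, "GB": 0.0, "IG": 0.0},
        )
        data = simulate_dataset(cfg)
        assert data["truth"].genes["is_de"].sum() == 0


class TestDeterminism:
    def test_same_config_same_dataset(self):
        cfg = SimConfig(seed=77, n_genes=40, chrom_lengths={"chr1": 500_000})
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a["methylation"], b["methylation"])
        pd.testing.assert_frame_equal(a["expression"], b["expression"])
        pd.testing.assert_frame_equal(a["truth"].loci, b["truth"].loci)
        pd.testing.assert_frame_equal(a["truth"].pairs, b["truth"].pairs)

    def test_different_seed_differs(self):
        cfg = SimConfig(seed=1, n_genes=20, chrom_lengths={"chr1": 300_000})
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg.with_seed(2))
        assert not a["methylation"].equals(b["methylation"])
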