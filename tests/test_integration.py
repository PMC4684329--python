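"""DM x DE linking, categorization and counts-table accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from helpdm.annotation import gene_body_region, genes_from_frame, promoter_window
from helpdm.integration import (
    build_counts_table,
    categorize,
    counts_table_stats,
    link_loci_to_genes,
    subcompartment_breakdown,
)


def make_records(spec):
    """Expand {(compartment, category): n} into a record list."""
    dirs = {
        "HyperDown": ("hyper", "down"),
        "HypoUp": ("hypo", "up"),
        "HyperUp": ("hyper", "up"),
        "HypoDown": ("hypo", "down"),
    }
    rows = []
    i = 0
    for (comp, cat), n in spec.items():
        dm_dir, de_dir = dirs[cat]
        for _ in range(n):
            i += 1
            c, canonical = categorize(comp, dm_dir, de_dir)
            rows.append(
                {
                    "locus_id": f"L{i}",
                    "gene_id": f"G{i}",
                    "compartment": comp,
                    "subcompartment": "other" if comp == "PR" else None,
                    "dm_direction": dm_dir,
                    "de_direction": de_dir,
                    "category": c,
                    "canonical": canonical,
                }
            )
    return pd.DataFrame(rows)


class TestCategorize:
    @pytest.mark.parametrize(
        "comp,dm,de,cat,canonical",
        [
            ("PR", "hyper", "down", "HyperDown", True),
            ("PR", "hypo", "up", "HypoUp", True),
            ("PR", "hypo", "down", "HypoDown", False),
            ("PR", "hyper", "up", "HyperUp", False),
            ("GB", "hyper", "up", "HyperUp", True),
            ("GB", "hypo", "down", "HypoDown", True),
            ("GB", "hyper", "down", "HyperDown", False),
            ("GB", "hypo", "up", "HypoUp", False),
        ],
    )
    def test_category_table(self, comp, dm, de, cat, canonical):
        assert categorize(comp, dm, de) == (cat, canonical)

    def test_exhaustive_and_exclusive(self):
        """Every (compartment, dm, de) triple maps to exactly one category,
        and exactly two categories per compartment are canonical."""
        for comp in ("PR", "GB"):
            canon = set()
            for dm, de in itertools.product(["hyper", "hypo"], ["up", "down"]):
                cat, flag = categorize(comp, dm, de)
                assert cat in {"HyperDown", "HypoUp", "HyperUp", "HypoDown"}
                if flag:
                    canon.add(cat)
            assert len(canon) == 2

    def test_rejects_non_significant_directions(self):
        with pytest.raises(ValueError):
            categorize("PR", "none", "up")
        with pytest.raises(ValueError):
            categorize("IG", "hyper", "up")


class TestCountsTable:
    def test_reproduces_adenocarcinoma_merge_accounting(self):
        # printed per-category cells of the adenocarcinoma DM x DE merge
        records = make_records(
            {
                ("PR", "HyperDown"): 64,
                ("PR", "HypoUp"): 16,
                ("PR", "HyperUp"): 619,
                ("PR", "HypoDown"): 620,  # 1239 "other" promoter loci
                ("GB", "HyperUp"): 138,
                ("GB", "HypoDown"): 2998,
                ("GB", "HyperDown"): 16300,
                ("GB", "HypoUp"): 16301,  # 32601 "other" gene-body loci
            }
        )
        stats = counts_table_stats(build_counts_table(records))
        assert stats["total"] == 37056
        assert stats["canonical_total"] == 3216
        assert stats["canonical_fraction_pct"] == 8.7

    def test_reproduces_all_histology_merge_accounting(self):
        records = make_records(
            {
                ("PR", "HyperDown"): 75,
                ("PR", "HypoUp"): 38,
                ("PR", "HyperUp"): 1556,
                ("PR", "HypoDown"): 1557,  # 3113 other
                ("GB", "HyperUp"): 219,
                ("GB", "HypoDown"): 3753,
                ("GB", "HyperDown"): 35771,
                ("GB", "HypoUp"): 35771,  # 71542 other
            }
        )
        counts = build_counts_table(records)
        stats = counts_table_stats(counts)
        assert stats["total"] == 78740
        assert stats["canonical_total"] == 75 + 38 + 219 + 3753  # PR 113 + GB 3972
        assert stats["canonical_fraction_pct"] == 5.2
        pooled = counts.set_index(["compartment", "category"])["n_loci"]
        assert pooled[("PR", "other")] == 3113
        assert pooled[("GB", "other")] == 71542

    def test_empty_records(self):
        stats = counts_table_stats(build_counts_table(make_records({})))
        assert stats["total"] == 0
        assert stats["canonical_fraction_pct"] is None

    def test_all_canonical_is_100(self):
        records = make_records({("PR", "HyperDown"): 7, ("GB", "HypoDown"): 3})
        stats = counts_table_stats(build_counts_table(records))
        assert stats["canonical_fraction_pct"] == 100.0

    def test_totals_conserve_record_count(self):
        rng = np.random.default_rng(0)
        spec = {
            (c, k): int(rng.integers(0, 50))
            for c in ("PR", "GB")
            for k in ("HyperDown", "HypoUp", "HyperUp", "HypoDown")
        }
        records = make_records(spec)
        assert counts_table_stats(build_counts_table(records))["total"] == len(records)


def _tables(loci, genes, dm_rows, de_rows):
    dm = pd.DataFrame(dm_rows)
    dm["q"] = dm.get("q", 0.01)
    de = pd.DataFrame(de_rows)
    de["q"] = de.get("q", 0.01)
    return dm, de


class TestLinking:
    genes = pd.DataFrame(
        [
            {"gene_id": "G1", "chrom": "chr1", "strand": "+", "tss": 10_000, "tes": 20_000},
        ]
    )

    def _link(self, locus, dm_dir, de_dir, **kw):
        dm = pd.DataFrame(
            [
                {
                    "locus_id": "L1",
                    "chrom": "chr1",
                    "start": locus[0],
                    "end": locus[1],
                    "q": 0.01,
                    "direction": dm_dir,
                    "subcompartment": "CGI",
                }
            ]
        )
        de = pd.DataFrame(
            [{"gene_id": "G1", "q": 0.01, "direction": de_dir, "log2fc": 1}]
        )
        return link_loci_to_genes(dm, de, self.genes, **kw)

    def test_promoter_hyper_down_is_canonical(self):
        rec = self._link((8_100, 8_400), "hyper", "down").iloc[0]
        assert (rec.compartment, rec.category, rec.canonical) == ("PR", "HyperDown", True)
        assert rec.subcompartment == "CGI"

    def test_gene_body_hypo_down_is_canonical(self):
        rec = self._link((15_000, 15_300), "hypo", "down").iloc[0]
        assert (rec.compartment, rec.category, rec.canonical) == ("GB", "HypoDown", True)
        assert rec.subcompartment is None

    def test_promoter_hypo_down_is_non_canonical(self):
        rec = self._link((8_100, 8_400), "hypo", "down").iloc[0]
        assert rec.canonical == False  # noqa: E712
        assert rec.category == "HypoDown"

    def test_intergenic_and_nonsignificant_never_link(self):
        assert self._link((50_000, 50_300), "hyper", "down").empty
        dm = pd.DataFrame(
            [
                {
                    "locus_id": "L1", "chrom": "chr1", "start": 8_100, "end": 8_400,
                    "q": 0.5, "direction": "none",
                }
            ]
        )
        de = pd.DataFrame([{"gene_id": "G1", "q": 0.01, "direction": "down"}])
        assert link_loci_to_genes(dm, de, self.genes).empty

    def test_matches_brute_force_all_pairs(self):
        """dedup-free linking equals an exhaustive interval check on a
        random fixture."""
        rng = np.random.default_rng(12)
        genes = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(12)],
                "chrom": "chr1",
                "strand": rng.choice(["+", "-"], size=12),
                "tss": np.arange(12) * 9_000 + 5_000,
                "tes": np.arange(12) * 9_000 + 5_000,
            }
        )
        # orient tss/tes by strand
        genes["tes"] = np.where(
            genes["strand"] == "+", genes["tss"] + 4_000, genes["tss"] - 4_000
        )
        n = 80
        starts = rng.integers(0, 110_000, size=n)
        dm = pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(n)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + rng.integers(200, 2_000, size=n),
                "q": 0.01,
                "direction": rng.choice(["hyper", "hypo"], size=n),
            }
        )
        de = pd.DataFrame(
            {
                "gene_id": genes["gene_id"],
                "q": rng.choice([0.01, 0.5], size=12),
                "direction": rng.choice(["up", "down"], size=12),
            }
        )
        got = link_loci_to_genes(dm, de, genes, dedup_locus=False)
        got_pairs = set(zip(got["locus_id"], got["gene_id"], got["compartment"]))

        expected = set()
        models = {g.gene_id: g for g in genes_from_frame(genes)}
        for lrow in dm.itertuples(index=False):
            for grow in de.itertuples(index=False):
                if grow.q >= 0.05:
                    continue
                g = models[grow.gene_id]
                pw = promoter_window(g)
                gb = gene_body_region(g)
                span = (lrow.start, lrow.end)
                if max(pw[0], span[0]) < min(pw[1], span[1]):
                    expected.add((lrow.locus_id, g.gene_id, "PR"))
                elif max(gb[0], span[0]) < min(gb[1], span[1]):
                    expected.add((lrow.locus_id, g.gene_id, "GB"))
        assert got_pairs == expected

    def test_dedup_keeps_one_record_per_locus(self):
        genes = pd.DataFrame(
            [
                {"gene_id": "GA", "chrom": "chr1", "strand": "+", "tss": 10_000, "tes": 14_000},
                {"gene_id": "GBx", "chrom": "chr1", "strand": "+", "tss": 11_000, "tes": 15_000},
            ]
        )
        dm = pd.DataFrame(
            [
                {
                    "locus_id": "L1", "chrom": "chr1", "start": 10_200, "end": 10_800,
                    "q": 0.01, "direction": "hyper",
                }
            ]
        )
        de = pd.DataFrame(
            [
                {"gene_id": "GA", "q": 0.01, "direction": "down"},
                {"gene_id": "GBx", "q": 0.01, "direction": "down"},
            ]
        )
        all_pairs = link_loci_to_genes(dm, de, genes, dedup_locus=False)
        deduped = link_loci_to_genes(dm, de, genes, dedup_locus=True)
        assert len(all_pairs) == 2
        assert len(deduped) == 1
        # locus overlaps GBx's promoter and GA's body: promoter wins
        assert deduped.iloc[0]["gene_id"] == "GBx"
        assert deduped.iloc[0]["compartment"] == "PR"


class TestSubcompartmentBreakdown:
    def test_single_cell(self):
        records = make_records({("PR", "HyperDown"): 5})
        records["subcompartment"] = "CGI"
        grid = subcompartment_breakdown(records)
        assert grid.loc["CGI", "HyperDown"] == 5
        assert grid.to_numpy().sum() == 5

    def test_counts_only_promoter_records(self):
        records = make_records({("PR", "HyperDown"): 3, ("GB", "HyperUp"): 4})
        grid = subcompartment_breakdown(records)
        assert grid.to_numpy().sum() == 3
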