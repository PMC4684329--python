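"""Merge of differential methylation with differential expression (DM x DE).

A significant DM locus is linked to a significant DE gene when it lies in
that gene's promoter window (2 kb upstream of the TSS) or gene-body region.
Each link is categorized by the joint direction of change:

==============  =======================  ==========
compartment      category                 canonical
==============  =======================  ==========
promoter (PR)    HyperDown, HypoUp        yes
promoter (PR)    HyperUp, HypoDown        no ("other")
gene body (GB)   HyperUp, HypoDown        yes
gene body (GB)   HyperDown, HypoUp        no ("other")
==============  =======================  ==========

The canonical promoter relationship is methylation repressing expression
(hypermethylation with downregulation, hypomethylation with upregulation);
in gene bodies the field's expectation is the reverse (methylation tracking
expression).  Intergenic loci never link.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from helpdm.annotation import (
    GeneModel,
    gene_body_region,
    genes_from_frame,
    promoter_window,
)

CATEGORIES = ("HyperDown", "HypoUp", "HyperUp", "HypoDown")
_CANONICAL = {
    "PR": {"HyperDown", "HypoUp"},
    "GB": {"HyperUp", "HypoDown"},
}
_CATEGORY = {
    ("hyper", "down"): "HyperDown",
    ("hypo", "up"): "HypoUp",
    ("hyper", "up"): "HyperUp",
    ("hypo", "down"): "HypoDown",
}


def categorize(
    compartment: str, dm_direction: str, de_direction: str
) -> tuple[str, bool]:
    """Map (compartment, DM direction, DE direction) to (category, canonical).

    Exhaustive and exclusive over compartments PR/GB, DM directions
    hyper/hypo and DE directions up/down.  Non-significant (``none``)
    directions are not accepted: records must be filtered to jointly
    significant pairs first.
    """
    if compartment not in ("PR", "GB"):
        raise ValueError(f"compartment must be PR or GB, got {compartment!r}")
    key = (dm_direction, de_direction)
    if key not in _CATEGORY:
        raise ValueError(f"invalid direction pair {key!r}")
    cat = _CATEGORY[key]
    return cat, cat in _CANONICAL[compartment]


def link_loci_to_genes(
    dm_table: pd.DataFrame,
    de_table: pd.DataFrame,
    genes: pd.DataFrame,
    loci: pd.DataFrame | None = None,
    alpha: float = 0.05,
    promoter_width: int = 2000,
    gb_start_offset: int = 0,
    dedup_locus: bool = True,
    chrom_lengths=None,
) -> pd.DataFrame:
    """Link significant DM loci to significant DE genes by genome location.

    Parameters
    ----------
    dm_table
        Output of :func:`helpdm.paired.run_dm`; must carry locus
        coordinates (``chrom, start, end``) and, for promoter records to
        keep their CGI/CGS labels, ``subcompartment``.
    de_table
        Output of :func:`helpdm.paired.run_de`.
    genes
        Gene models (``gene_id, chrom, strand, tss, tes``) for the DE genes'
        coordinates.
    dedup_locus
        When true (default), keep one record per locus: promoter links win
        over gene-body links, then the gene with TSS nearest the locus
        midpoint.  When false, every qualifying (locus, gene) pair is a
        record.

    Returns a DataFrame of integration records with columns ``locus_id,
    gene_id, compartment, subcompartment, dm_direction, de_direction,
    category, canonical``.
    """
    dm_sig = dm_table[
        (dm_table["q"] < alpha) & dm_table["direction"].isin(["hyper", "hypo"])
    ].copy()
    de_sig = de_table[
        (de_table["q"] < alpha) & de_table["direction"].isin(["up", "down"])
    ]
    de_dir = dict(zip(de_sig["gene_id"].astype(str), de_sig["direction"]))

    if loci is not None:
        coord_cols = ["locus_id", "chrom", "start", "end"]
        extra = [c for c in ("subcompartment",) if c in loci.columns]
        dm_sig = dm_sig.drop(
            columns=[
                c
                for c in ("chrom", "start", "end", *extra)
                if c in dm_sig.columns
            ]
        ).merge(loci[coord_cols + extra], on="locus_id", how="left")
    for col in ("chrom", "start", "end"):
        if col not in dm_sig.columns or dm_sig[col].isna().any():
            raise ValueError("DM records need locus coordinates to be linked")

    de_genes = [
        g for g in genes_from_frame(genes) if g.gene_id in de_dir
    ]
    pr_trees: dict[str, IntervalTree] = {}
    gb_trees: dict[str, IntervalTree] = {}
    for g in de_genes:
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        s, e = promoter_window(g, promoter_width, clen)
        if s < e:
            pr_trees.setdefault(g.chrom, IntervalTree()).addi(s, e, (g.gene_id, g.tss))
        s, e = gene_body_region(g, gb_start_offset)
        if s < e:
            gb_trees.setdefault(g.chrom, IntervalTree()).addi(s, e, (g.gene_id, g.tss))

    records = []
    for r in dm_sig.itertuples(index=False):
        chrom, s, e = str(r.chrom), int(r.start), int(r.end)
        mid = (s + e) / 2.0
        candidates = []  # (compartment rank, |tss - mid|, gene_id, compartment)
        seen = set()
        for rank, (comp, trees) in enumerate((("PR", pr_trees), ("GB", gb_trees))):
            tree = trees.get(chrom)
            for iv in tree.overlap(s, e) if tree is not None else ():
                gid, tss = iv.data
                if gid in seen:
                    continue  # PR link outranks a GB link to the same gene
                seen.add(gid)
                candidates.append((rank, abs(tss - mid), gid, comp))
        if not candidates:
            continue
        candidates.sort()
        if dedup_locus:
            candidates = candidates[:1]
        sub = getattr(r, "subcompartment", None)
        for rank, _, gid, comp in candidates:
            cat, canonical = categorize(comp, r.direction, de_dir[gid])
            records.append(
                {
                    "locus_id": r.locus_id,
                    "gene_id": gid,
                    "compartment": comp,
                    "subcompartment": sub if comp == "PR" else None,
                    "dm_direction": r.direction,
                    "de_direction": de_dir[gid],
                    "category": cat,
                    "canonical": canonical,
                }
            )
    cols = [
        "locus_id",
        "gene_id",
        "compartment",
        "subcompartment",
        "dm_direction",
        "de_direction",
        "category",
        "canonical",
    ]
    return pd.DataFrame(records, columns=cols)


def make_records_from_cells(cells: dict) -> pd.DataFrame:
    """Expand ``{(compartment, category): count}`` into a record table.

    Convenience for rebuilding a counts table from published per-category
    cell counts; records get synthetic ids and ``other`` subcompartments.
    """
    dirs = {
        "HyperDown": ("hyper", "down"),
        "HypoUp": ("hypo", "up"),
        "HyperUp": ("hyper", "up"),
        "HypoDown": ("hypo", "down"),
    }
    rows = []
    i = 0
    for (comp, cat), n in cells.items():
        dm_dir, de_dir = dirs[cat]
        category, canonical = categorize(comp, dm_dir, de_dir)
        for _ in range(int(n)):
            i += 1
            rows.append(
                {
                    "locus_id": f"L{i}",
                    "gene_id": f"G{i}",
                    "compartment": comp,
                    "subcompartment": "other" if comp == "PR" else None,
                    "dm_direction": dm_dir,
                    "de_direction": de_dir,
                    "category": category,
                    "canonical": canonical,
                }
            )
    cols = [
        "locus_id", "gene_id", "compartment", "subcompartment",
        "dm_direction", "de_direction", "category", "canonical",
    ]
    return pd.DataFrame(rows, columns=cols)


def build_counts_table(records: pd.DataFrame) -> pd.DataFrame:
    """Counts-table accounting of DM x DE records, shaped like the merge
    summaries of paired tumor/normal integromics studies.

    One row per (compartment, category) with non-canonical categories pooled
    into ``other``, plus ``total``, ``canonical_total`` and
    ``canonical_fraction_pct`` (percentage of all records that are
    canonical, rounded to one decimal; NA for an empty record list).
    Row counts always sum to the number of input records.
    """
    rows = []
    total = len(records)
    canonical_total = int(records["canonical"].sum()) if total else 0
    for comp in ("PR", "GB"):
        grp = records[records["compartment"] == comp] if total else records
        canon_cats = sorted(_CANONICAL[comp])
        n_other = 0
        counts = {}
        if total:
            vc = grp["category"].value_counts()
            for cat in CATEGORIES:
                c = int(vc.get(cat, 0))
                if cat in _CANONICAL[comp]:
                    counts[cat] = c
                else:
                    n_other += c
        else:
            counts = {cat: 0 for cat in canon_cats}
        for cat in sorted(counts):
            rows.append({"compartment": comp, "category": cat, "n_loci": counts[cat]})
        rows.append({"compartment": comp, "category": "other", "n_loci": n_other})
    out = pd.DataFrame(rows)
    out.attrs["total"] = total
    out.attrs["canonical_total"] = canonical_total
    out.attrs["canonical_fraction_pct"] = (
        round(100.0 * canonical_total / total, 1) if total else None
    )
    summary = pd.DataFrame(
        [
            {"compartment": "all", "category": "total", "n_loci": total},
            {
                "compartment": "all",
                "category": "canonical_total",
                "n_loci": canonical_total,
            },
        ]
    )
    return pd.concat([out, summary], ignore_index=True)


def counts_table_stats(counts: pd.DataFrame) -> dict:
    """Convenience accessor for the totals carried by a counts table."""
    total = int(counts.loc[counts["category"] == "total", "n_loci"].iloc[0])
    canonical = int(
        counts.loc[counts["category"] == "canonical_total", "n_loci"].iloc[0]
    )
    return {
        "total": total,
        "canonical_total": canonical,
        "canonical_fraction_pct": round(100.0 * canonical / total, 1)
        if total
        else None,
    }


def subcompartment_breakdown(records: pd.DataFrame) -> pd.DataFrame:
    """Promoter-record counts by subcompartment (CGI/CGS/other) x category.

    Returns the 3 x 4 count grid (rows CGI, CGS, other; columns the four
    direction categories).  Run
    :func:`helpdm.enrichment.chi_square_independence` on the grid (after
    dropping all-zero marginals) to test whether the DM x DE pattern varies
    by promoter CpG context.
    """
    pr = records[records["compartment"] == "PR"]
    grid = pd.DataFrame(
        0,
        index=pd.Index(["CGI", "CGS", "other"], name="subcompartment"),
        columns=list(CATEGORIES),
    )
    if len(pr):
        ct = pd.crosstab(pr["subcompartment"], pr["category"])
        for sub in grid.index:
            for cat in grid.columns:
                if sub in ct.index and cat in ct.columns:
                    grid.loc[sub, cat] = int(ct.loc[sub, cat])
    return grid
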