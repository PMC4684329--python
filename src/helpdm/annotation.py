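"""CCGG fragment definition and genomic compartment annotation.

The HELP assay measures CpG methylation on genomic fragments bounded by
MspI/HpaII recognition sites (C^CGG).  This module performs the in-silico
MspI digest with the assay's 200-2000 bp size selection, and assigns every
fragment locus a genomic compartment:

* ``PR`` - promoter, the 2 kb window upstream of a gene's transcription
  start site (TSS),
* ``GB`` - gene body, from the TSS (optionally offset downstream) to the
  transcription end site,
* ``IG`` - intergenic, everything else.

Promoter loci are further split by CpG-island context into ``CGI`` (overlaps
an island), ``CGS`` (overlaps a CG shore, the 2 kb flank of an island) and
``other``.

All coordinates are 0-based half-open.  Gene models carry a ``tss`` and
``tes`` in strand orientation: on the ``+`` strand ``tss < tes`` and the gene
occupies ``[tss, tes)``; on the ``-`` strand ``tss > tes`` and the gene
occupies ``[tes, tss + 1)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

COMPARTMENTS = ("PR", "GB", "IG")
SUBCOMPARTMENTS = ("CGI", "CGS", "other")

_CCGG = re.compile(r"(?=CCGG)")
_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class FragmentLocus:
    """A CCGG-bounded genomic interval, the unit of methylation measurement."""

    locus_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid locus {self.locus_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model with strand-oriented TSS and TES."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic span [start, end) irrespective of strand."""
        if self.strand == "+":
            return (self.tss, self.tes)
        return (self.tes, self.tss + 1)


@dataclass(frozen=True)
class CompartmentLabel:
    compartment: str
    linked_gene: str | None = None
    subcompartment: str | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.compartment in ("PR", "GB") and self.linked_gene is None:
            raise ValueError(f"{self.compartment} label requires a linked gene")
        if self.compartment == "IG" and self.linked_gene is not None:
            raise ValueError("IG label cannot carry a linked gene")


def msp_digest(
    sequence: str,
    size_range: tuple[int, int] = (200, 2000),
    chrom: str = "chr1",
) -> list[FragmentLocus]:
    """In-silico MspI digest of ``sequence`` with fragment size selection.

    MspI cuts C^CGG, i.e. one base into each CCGG occurrence.  Fragments are
    the intervals between consecutive cut positions, so both fragment ends
    are CCGG-bounded; the two terminal stretches of the chromosome are not
    (they end at the sequence boundary) and are discarded.  Motif matching
    is case-insensitive and overlapping (``CCGGCCGG`` contributes two cut
    sites).  Only fragments whose length falls in ``size_range`` (inclusive)
    are returned, sorted by start coordinate.
    """
    lo, hi = size_range
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid size range [{lo}, {hi}]")
    seq = sequence.upper()
    bad = next((i for i, c in enumerate(seq) if c not in _VALID_BASES), None)
    if bad is not None:
        raise ValueError(
            f"invalid character {sequence[bad]!r} at position {bad}; "
            "expected A/C/G/T/N"
        )
    cuts = [m.start() + 1 for m in _CCGG.finditer(seq)]
    frags = []
    for a, b in zip(cuts, cuts[1:]):
        if lo <= b - a <= hi:
            frags.append(
                FragmentLocus(f"{chrom}:{a}-{b}", chrom, a, b)
            )
    return frags


def promoter_window(
    gene: GeneModel,
    width: int = 2000,
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """The ``width`` bp window immediately upstream of the TSS, half-open.

    ``+`` strand: ``[tss - width, tss)``; ``-`` strand: ``[tss + 1,
    tss + width + 1)``.  Clipped to ``[0, chrom_length)`` when a chromosome
    length is given.
    """
    if gene.strand == "+":
        s, e = gene.tss - width, gene.tss
    else:
        s, e = gene.tss + 1, gene.tss + width + 1
    s = max(s, 0)
    if chrom_length is not None:
        e = min(e, chrom_length)
    if e < s:
        e = s
    return (s, e)


def gene_body_region(gene: GeneModel, gb_start_offset: int = 0) -> tuple[int, int]:
    """Strand-oriented gene body from ``tss + gb_start_offset`` to the TES.

    An offset beyond the gene length yields an empty interval (start == end),
    not an error.
    """
    if gb_start_offset < 0:
        raise ValueError("gb_start_offset must be >= 0")
    if gene.strand == "+":
        s, e = gene.tss + gb_start_offset, gene.tes
    else:
        s, e = gene.tes, gene.tss - gb_start_offset + 1
    if e <= s:
        return (s, s)
    return (s, e)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def assign_compartment(
    locus: FragmentLocus,
    genes: Iterable[GeneModel],
    promoter_width: int = 2000,
    gb_start_offset: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> CompartmentLabel:
    """Assign a single locus a PR/GB/IG label with precedence PR > GB > IG.

    Overlap of >= 1 bp with any promoter window makes the locus PR; failing
    that, overlap with any gene-body region makes it GB; otherwise IG.  When
    several genes qualify, the linked gene is the one whose TSS lies nearest
    the locus midpoint (ties broken by gene id for determinism).
    """
    span = (locus.start, locus.end)
    mid = locus.midpoint
    pr_hits: list[GeneModel] = []
    gb_hits: list[GeneModel] = []
    for g in genes:
        if g.chrom != locus.chrom:
            continue
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        if _overlaps(span, promoter_window(g, promoter_width, clen)):
            pr_hits.append(g)
        elif _overlaps(span, gene_body_region(g, gb_start_offset)):
            gb_hits.append(g)
    for comp, hits in (("PR", pr_hits), ("GB", gb_hits)):
        if hits:
            best = min(hits, key=lambda g: (abs(g.tss - mid), g.gene_id))
            return CompartmentLabel(comp, linked_gene=best.gene_id)
    return CompartmentLabel("IG")


def _shore_intervals(
    cgi: tuple[int, int], shore_width: int, shore_mode: str
) -> list[tuple[int, int]]:
    s, e = cgi
    flanks = [(max(0, s - shore_width), s)]
    if shore_mode == "both-flanks":
        flanks.append((e, e + shore_width))
    elif shore_mode != "upstream-only":
        raise ValueError(f"unknown shore_mode {shore_mode!r}")
    return [f for f in flanks if f[0] < f[1]]


def assign_subcompartment(
    locus: FragmentLocus,
    cgis: Sequence[tuple[int, int]],
    shore_width: int = 2000,
    shore_mode: str = "both-flanks",
    *,
    compartment: str = "PR",
) -> str:
    """CGI/CGS/other label for a promoter locus.

    ``cgis`` are CpG-island intervals on the locus chromosome.  A locus
    overlapping an island is ``CGI`` (islands take precedence over shores);
    otherwise overlap with a shore flank of width ``shore_width`` makes it
    ``CGS``.  CpG islands are unstranded, so in ``upstream-only`` mode the
    shore is the lower-coordinate flank; ``both-flanks`` (default) uses both.
    """
    if compartment != "PR":
        raise ValueError("subcompartments are defined only for PR loci")
    span = (locus.start, locus.end)
    if any(_overlaps(span, c) for c in cgis):
        return "CGI"
    for c in cgis:
        if any(_overlaps(span, f) for f in _shore_intervals(c, shore_width, shore_mode)):
            return "CGS"
    return "other"


# ---------------------------------------------------------------------------
# Bulk annotation over DataFrames (the pipeline path)
# ---------------------------------------------------------------------------

def genes_from_frame(genes: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tss=int(r.tss),
            tes=int(r.tes),
        )
        for r in genes.itertuples(index=False)
    ]


def _region_trees(
    genes: Sequence[GeneModel],
    promoter_width: int,
    gb_start_offset: int,
    chrom_lengths: Mapping[str, int] | None,
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    pr: dict[str, IntervalTree] = {}
    gb: dict[str, IntervalTree] = {}
    for g in genes:
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        for trees, (s, e) in (
            (pr, promoter_window(g, promoter_width, clen)),
            (gb, gene_body_region(g, gb_start_offset)),
        ):
            if s < e:
                trees.setdefault(g.chrom, IntervalTree()).addi(s, e, (g.gene_id, g.tss))
    return pr, gb


def annotate_loci(
    loci: pd.DataFrame,
    genes: pd.DataFrame,
    cgis: pd.DataFrame | None = None,
    promoter_width: int = 2000,
    gb_start_offset: int = 0,
    shore_width: int = 2000,
    shore_mode: str = "both-flanks",
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Annotate a locus table with compartment and subcompartment labels.

    Parameters
    ----------
    loci
        DataFrame with columns ``locus_id, chrom, start, end``.
    genes
        DataFrame with columns ``gene_id, chrom, strand, tss, tes``.
    cgis
        Optional CpG-island DataFrame with ``chrom, start, end``; when absent
        every PR locus gets subcompartment ``other``.

    Returns a copy of ``loci`` with ``length, compartment, linked_gene,
    subcompartment`` columns.  Labels partition the locus set: every locus
    receives exactly one compartment.
    """
    gene_models = genes_from_frame(genes)
    pr_trees, gb_trees = _region_trees(
        gene_models, promoter_width, gb_start_offset, chrom_lengths
    )
    cgi_by_chrom: dict[str, IntervalTree] = {}
    shore_by_chrom: dict[str, IntervalTree] = {}
    if cgis is not None and len(cgis):
        for r in cgis.itertuples(index=False):
            chrom, s, e = str(r.chrom), int(r.start), int(r.end)
            cgi_by_chrom.setdefault(chrom, IntervalTree()).addi(s, e)
            for fs, fe in _shore_intervals((s, e), shore_width, shore_mode):
                shore_by_chrom.setdefault(chrom, IntervalTree()).addi(fs, fe)

    comps: list[str] = []
    linked: list[str | None] = []
    subs: list[str | None] = []
    for r in loci.itertuples(index=False):
        chrom, s, e = str(r.chrom), int(r.start), int(r.end)
        mid = (s + e) / 2.0
        comp, gene = "IG", None
        for name, trees in (("PR", pr_trees), ("GB", gb_trees)):
            tree = trees.get(chrom)
            hits = tree.overlap(s, e) if tree is not None else ()
            if hits:
                comp = name
                gene = min(
                    hits, key=lambda iv: (abs(iv.data[1] - mid), iv.data[0])
                ).data[0]
                break
        sub = None
        if comp == "PR":
            sub = "other"
            ctree = cgi_by_chrom.get(chrom)
            stree = shore_by_chrom.get(chrom)
            if ctree is not None and ctree.overlap(s, e):
                sub = "CGI"
            elif stree is not None and stree.overlap(s, e):
                # shore flanks may overlap a neighboring island; island wins
                sub = "CGS"
        comps.append(comp)
        linked.append(gene)
        subs.append(sub)

    out = loci.copy()
    out["length"] = out["end"] - out["start"]
    out["compartment"] = comps
    out["linked_gene"] = linked
    out["subcompartment"] = subs
    return out
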