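"""Synthetic paired methylome + transcriptome data with planted ground truth.

The generator emulates the statistical structure of a paired tumor /
non-tumor (T/NT) restriction-fragment methylome study:

* a small genome with non-overlapping gene models, CpG islands overlapping
  a configurable fraction of promoters, and CCGG-style fragment loci
  (either placed directly or cut from random sequence by in-silico digest),
* per-locus normalized methylation scores with a Gaussian
  subject-plus-residual error model: ``NT = mu_i + b_is + eps``,
  ``T = mu_i + delta_i + b_is + eps``, where ``b_is ~ N(0, subject_sd^2)``
  is a subject-level baseline shared by both tissues (it cancels in the
  paired test) and ``eps ~ N(0, residual_sd^2)`` is residual noise,
* differential methylation planted per locus at compartment-specific rates,
  hypermethylated (``delta < 0``, HELP sign convention) with a
  compartment-specific probability, |delta| drawn from a three-band mixture
  (negligible [0, 0.5), small [0.5, 1), moderate/large [1, 2]),
* paired log2 expression for each gene, where a gene whose promoter or gene
  body contains a planted DM locus is always differentially expressed -
  in the canonical direction with probability ``canonical_coupling``,
  anti-canonical otherwise - and unlinked genes are DE at ``de_rate`` with
  random sign.

Every planted quantity is recorded in a :class:`TruthTable` so that the
downstream testing, integration and classification stages can be scored
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd

from helpdm.annotation import annotate_loci, msp_digest
from helpdm.integration import categorize
from helpdm.paired import PairedDesign

_BANDS = {
    "negligible": (0.0, 0.5),
    "small": (0.5, 1.0),
    "moderate": (1.0, 2.0),
}
# stream ids for per-stage child seeds, so each stage is individually
# reproducible from the one config seed
_STREAMS = {"annotation": 1, "loci": 2, "methylome": 3, "expression": 4}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study; defaults emulate a 16-pair cohort.

    Rates are motivated by the genomic distribution reported for HELP-array
    lung cohorts: DM is most frequent in gene bodies, promoter loci are the
    rarest compartment, and hypomethylation dominates everywhere but most
    extremely in intergenic loci.  Noise scales are on the normalized
    log-ratio score scale.
    """

    n_subjects: int = 16
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_000_000}
    )
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    cgi_promoter_fraction: float = 0.6
    locus_density: float = 5.0  # expected fragments per 10 kb
    fragment_size_range: tuple[int, int] = (200, 2_000)
    dm_rate_by_compartment: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 0.21, "GB": 0.45, "IG": 0.32}
    )
    hyper_given_dm_by_compartment: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 0.31, "GB": 0.25, "IG": 0.06}
    )
    delta_magnitude_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"negligible": 0.35, "small": 0.45, "moderate": 0.20}
    )
    subject_sd: float = 0.2
    residual_sd: float = 0.3
    de_rate: float = 0.35
    log2fc_magnitude: float = 1.0
    canonical_coupling: float = 0.087
    promoter_width: int = 2000
    gb_start_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "cgi_promoter_fraction": self.cgi_promoter_fraction,
            "de_rate": self.de_rate,
            "canonical_coupling": self.canonical_coupling,
            **{f"dm_rate[{k}]": v for k, v in self.dm_rate_by_compartment.items()},
            **{
                f"hyper_given_dm[{k}]": v
                for k, v in self.hyper_given_dm_by_compartment.items()
            },
            **{
                f"delta_band[{k}]": v
                for k, v in self.delta_magnitude_distribution.items()
            },
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if set(self.dm_rate_by_compartment) != {"PR", "GB", "IG"}:
            raise ValueError("dm_rate_by_compartment needs exactly keys PR, GB, IG")
        if set(self.hyper_given_dm_by_compartment) != {"PR", "GB", "IG"}:
            raise ValueError(
                "hyper_given_dm_by_compartment needs exactly keys PR, GB, IG"
            )
        if set(self.delta_magnitude_distribution) != set(_BANDS):
            raise ValueError(
                f"delta_magnitude_distribution needs keys {sorted(_BANDS)}"
            )
        total = sum(self.delta_magnitude_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"delta band probabilities must sum to 1, got {total}")
        # zero is allowed so noise-free limiting cases can be simulated
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("subject_sd and residual_sd must be >= 0")
        lo, hi = self.fragment_size_range
        if lo < 1 or lo > hi:
            raise ValueError("fragment_size_range must satisfy 1 <= min <= max")
        lo, hi = self.gene_length_range
        if lo < 1 or lo > hi:
            raise ValueError("gene_length_range must satisfy 1 <= min <= max")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be nonempty")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chrom_lengths"] = dict(self.chrom_lengths)
        d["gene_length_range"] = list(self.gene_length_range)
        d["fragment_size_range"] = list(self.fragment_size_range)
        for k in (
            "dm_rate_by_compartment",
            "hyper_given_dm_by_compartment",
            "delta_magnitude_distribution",
        ):
            d[k] = dict(d[k])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for k in ("gene_length_range", "fragment_size_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class TruthTable:
    """Ground truth of a synthetic dataset.

    ``loci``: per-locus ``is_dm`` flag, signed ``true_delta`` (0 when not
    DM), compartment and linked gene.  ``genes``: per-gene ``is_de`` flag
    and signed ``true_log2fc``.  ``pairs``: one row per planted
    (locus, gene) coupling with its category and canonical flag.
    """

    loci: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("duplicate locus ids in truth table")
        bad = (~self.loci["is_dm"]) & (self.loci["true_delta"] != 0)
        if bad.any():
            raise ValueError("non-DM loci must have true_delta == 0")
        if len(self.genes):
            if self.genes["gene_id"].duplicated().any():
                raise ValueError("duplicate gene ids in truth table")
            bad = (~self.genes["is_de"]) & (self.genes["true_log2fc"] != 0)
            if bad.any():
                raise ValueError("non-DE genes must have true_log2fc == 0")


def _pack_intervals(
    rng: np.random.Generator, chrom_len: int, lengths: np.ndarray, what: str
) -> np.ndarray:
    """Random non-overlapping starts for intervals of given lengths.

    The free space left after accounting for the interval mass is split
    into random gaps, so placements are uniform-ish and never overlap.
    """
    n = len(lengths)
    if n == 0:
        return np.array([], dtype=int)
    free = chrom_len - int(lengths.sum())
    if free < 0:
        raise ValueError(
            f"infeasible packing: {what} mass {int(lengths.sum())} exceeds "
            f"chromosome length {chrom_len}"
        )
    offsets = np.sort(rng.integers(0, free + 1, size=n))
    return offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])


def _allocate_by_length(
    n: int, chrom_lengths: Mapping[str, int]
) -> dict[str, int]:
    """Deterministic largest-remainder split of n items across chromosomes."""
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    raw = {c: n * chrom_lengths[c] / total for c in chroms}
    alloc = {c: int(raw[c]) for c in chroms}
    rem = n - sum(alloc.values())
    for c in sorted(chroms, key=lambda c: (raw[c] - int(raw[c]), c), reverse=True)[
        :rem
    ]:
        alloc[c] += 1
    return alloc


def generate_annotation(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Generate gene models and CpG islands on the configured chromosomes.

    Genes are non-overlapping on the strand-agnostic axis; each carries a
    random strand with TSS/TES in strand orientation.  For
    ``cgi_promoter_fraction`` of genes a CpG island is placed overlapping
    the promoter window.  Deterministic given ``cfg.seed``.
    """
    rng = cfg.rng("annotation")
    chrom_lengths = dict(cfg.chrom_lengths)
    alloc = _allocate_by_length(cfg.n_genes, chrom_lengths)
    gene_rows, cgi_rows = [], []
    gid = 0
    for chrom in chrom_lengths:
        n = alloc[chrom]
        L = chrom_lengths[chrom]
        lengths = rng.integers(
            cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n
        )
        starts = _pack_intervals(rng, L, lengths, "gene")
        strands = rng.choice(["+", "-"], size=n)
        has_cgi = rng.random(n) < cfg.cgi_promoter_fraction
        for i in range(n):
            gid += 1
            s, e = int(starts[i]), int(starts[i] + lengths[i])
            strand = str(strands[i])
            if strand == "+":
                tss, tes = s, e
                pw = (max(0, tss - cfg.promoter_width), tss)
            else:
                tss, tes = e - 1, s
                pw = (tss + 1, min(L, tss + 1 + cfg.promoter_width))
            gene_id = f"G{gid:05d}"
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "tes": tes,
                }
            )
            if has_cgi[i] and pw[0] < pw[1]:
                cgi_len = int(rng.integers(300, 1001))
                cgi_start = int(rng.integers(pw[0], pw[1]))
                cgi_end = min(cgi_start + cgi_len, L)
                if cgi_start < cgi_end:
                    cgi_rows.append(
                        {"chrom": chrom, "start": cgi_start, "end": cgi_end}
                    )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "tss", "tes"]
    )
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    return genes, cgis, chrom_lengths


def generate_loci(
    cfg: SimConfig,
    chrom_lengths: Mapping[str, int],
    mode: str = "direct-placement",
    return_sequences: bool = False,
):
    """Generate fragment loci, either by placement or by in-silico digest.

    ``direct-placement`` puts non-overlapping fragments with lengths uniform
    in ``fragment_size_range`` at ``locus_density`` expected fragments per
    10 kb.  ``random-sequence-digest`` draws a random A/C/G/T sequence per
    chromosome and keeps the MspI fragments passing the size filter; with
    ``return_sequences=True`` the sequences are returned alongside for
    FASTA export.  Deterministic given ``cfg.seed``.
    """
    rng = cfg.rng("loci")
    rows = []
    sequences: dict[str, str] = {}
    for chrom, L in chrom_lengths.items():
        if mode == "direct-placement":
            n = int(round(cfg.locus_density * L / 10_000))
            if n == 0:
                continue
            lengths = rng.integers(
                cfg.fragment_size_range[0], cfg.fragment_size_range[1] + 1, size=n
            )
            try:
                starts = _pack_intervals(rng, L, lengths, "fragment")
            except ValueError as err:
                raise ValueError(f"locus density infeasible on {chrom}: {err}")
            for s, l in zip(starts, lengths):
                rows.append(
                    {"chrom": chrom, "start": int(s), "end": int(s + l)}
                )
        elif mode == "random-sequence-digest":
            seq = "".join(rng.choice(list("ACGT"), size=L))
            sequences[chrom] = seq
            for frag in msp_digest(seq, cfg.fragment_size_range, chrom=chrom):
                rows.append(
                    {"chrom": frag.chrom, "start": frag.start, "end": frag.end}
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], kind="mergesort"
    )
    loci.insert(
        0,
        "locus_id",
        [f"L{i:06d}" for i in range(1, len(loci) + 1)],
    )
    loci = loci.reset_index(drop=True)
    if return_sequences:
        return loci, sequences
    return loci


def make_design(cfg: SimConfig) -> PairedDesign:
    subjects = tuple(f"S{i:03d}" for i in range(1, cfg.n_subjects + 1))
    return PairedDesign(
        subjects,
        tuple(f"{s}_T" for s in subjects),
        tuple(f"{s}_NT" for s in subjects),
    )


def _draw_deltas(
    rng: np.random.Generator, cfg: SimConfig, compartments: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (is_dm, true_delta) with compartment-specific rates."""
    n = len(compartments)
    rates = np.array(
        [cfg.dm_rate_by_compartment[c] for c in compartments], dtype=float
    )
    hyper_p = np.array(
        [cfg.hyper_given_dm_by_compartment[c] for c in compartments], dtype=float
    )
    is_dm = rng.random(n) < rates
    # hypermethylated-in-tumor loci carry delta < 0 (HELP convention)
    sign = np.where(rng.random(n) < hyper_p, -1.0, 1.0)
    band_names = list(_BANDS)
    band_p = np.array([cfg.delta_magnitude_distribution[b] for b in band_names])
    bands = rng.choice(len(band_names), size=n, p=band_p)
    lo = np.array([_BANDS[b][0] for b in band_names])[bands]
    hi = np.array([_BANDS[b][1] for b in band_names])[bands]
    mag = rng.uniform(lo, hi)
    delta = np.where(is_dm, sign * mag, 0.0)
    return is_dm, delta


def simulate_methylome(
    cfg: SimConfig,
    loci_annotated: pd.DataFrame,
) -> tuple[pd.DataFrame, PairedDesign, TruthTable]:
    """Simulate the loci x samples methylation score matrix.

    ``loci_annotated`` must carry ``compartment`` (and ``linked_gene``)
    columns from :func:`helpdm.annotation.annotate_loci`.  Returns the
    score matrix (rows = locus ids, columns = sample ids), the paired
    design, and the truth table with planted DM flags and deltas.
    """
    if "compartment" not in loci_annotated.columns:
        raise ValueError("loci must be annotated with compartments first")
    rng = cfg.rng("methylome")
    design = make_design(cfg)
    n_loci = len(loci_annotated)
    n_sub = cfg.n_subjects
    compartments = loci_annotated["compartment"].to_numpy()
    is_dm, delta = _draw_deltas(rng, cfg, compartments)

    mu = rng.normal(0.0, 1.0, size=n_loci)
    b = rng.normal(0.0, cfg.subject_sd, size=(n_loci, n_sub))
    eps_nt = rng.normal(0.0, cfg.residual_sd, size=(n_loci, n_sub))
    eps_t = rng.normal(0.0, cfg.residual_sd, size=(n_loci, n_sub))
    nt = mu[:, None] + b + eps_nt
    t = mu[:, None] + delta[:, None] + b + eps_t

    matrix = pd.DataFrame(
        np.hstack([t, nt]),
        index=pd.Index(loci_annotated["locus_id"].astype(str), name="locus_id"),
        columns=[*design.tumor, *design.normal],
    )
    truth_loci = pd.DataFrame(
        {
            "locus_id": loci_annotated["locus_id"].astype(str).to_numpy(),
            "compartment": compartments,
            "linked_gene": loci_annotated.get("linked_gene"),
            "is_dm": is_dm,
            "true_delta": delta,
        }
    )
    truth = TruthTable(loci=truth_loci)
    truth.validate()
    return matrix, design, truth


def simulate_expression(
    cfg: SimConfig,
    genes: pd.DataFrame,
    truth: TruthTable,
    loci_annotated: pd.DataFrame,
    design: PairedDesign | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate the genes x samples log2 expression matrix.

    A gene whose promoter/gene-body region contains a planted DM locus
    (``linked_gene`` points at the gene) is coupled to its *nearest* such
    locus (by TSS-to-locus-midpoint distance; one gene couples to at most
    one locus).  Coupled genes are always DE: in the canonical direction
    with probability ``canonical_coupling``, anti-canonical otherwise.
    Unlinked genes are DE at ``de_rate`` with random sign.  The paired
    noise structure matches the methylome.  Updates and returns the truth
    table with per-gene DE truth and the planted coupling categories.
    """
    rng = cfg.rng("expression")
    design = design or make_design(cfg)
    n_genes = len(genes)
    gene_ids = genes["gene_id"].astype(str).to_numpy()
    tss = dict(zip(gene_ids, genes["tss"].astype(int)))

    planted = truth.loci[truth.loci["is_dm"]].merge(
        loci_annotated[["locus_id", "start", "end"]], on="locus_id"
    )
    planted = planted[planted["compartment"].isin(["PR", "GB"])]
    planted = planted[planted["linked_gene"].notna()]

    coupled: dict[str, dict] = {}
    for r in planted.itertuples(index=False):
        gid = str(r.linked_gene)
        if gid not in tss:
            continue
        dist = abs(tss[gid] - (r.start + r.end) / 2.0)
        prev = coupled.get(gid)
        if prev is None or dist < prev["dist"]:
            coupled[gid] = {
                "locus_id": r.locus_id,
                "compartment": r.compartment,
                "dm_direction": "hyper" if r.true_delta < 0 else "hypo",
                "dist": dist,
            }

    is_de = np.zeros(n_genes, dtype=bool)
    log2fc = np.zeros(n_genes)
    pair_rows = []
    for i, gid in enumerate(gene_ids):
        if gid in coupled:
            info = coupled[gid]
            canonical = bool(rng.random() < cfg.canonical_coupling)
            # canonical promoter DM represses (hyper -> down); canonical
            # gene-body DM tracks expression (hyper -> up)
            if info["compartment"] == "PR":
                down = info["dm_direction"] == "hyper"
            else:
                down = info["dm_direction"] == "hypo"
            if not canonical:
                down = not down
            is_de[i] = True
            log2fc[i] = -cfg.log2fc_magnitude if down else cfg.log2fc_magnitude
            cat, canon_flag = categorize(
                info["compartment"], info["dm_direction"], "down" if down else "up"
            )
            pair_rows.append(
                {
                    "locus_id": info["locus_id"],
                    "gene_id": gid,
                    "compartment": info["compartment"],
                    "category": cat,
                    "canonical": canon_flag,
                }
            )
        else:
            if rng.random() < cfg.de_rate:
                is_de[i] = True
                log2fc[i] = cfg.log2fc_magnitude * (
                    1.0 if rng.random() < 0.5 else -1.0
                )

    n_sub = cfg.n_subjects
    mu = rng.normal(8.0, 1.0, size=n_genes)
    b = rng.normal(0.0, cfg.subject_sd, size=(n_genes, n_sub))
    eps_nt = rng.normal(0.0, cfg.residual_sd, size=(n_genes, n_sub))
    eps_t = rng.normal(0.0, cfg.residual_sd, size=(n_genes, n_sub))
    nt = mu[:, None] + b + eps_nt
    t = mu[:, None] + log2fc[:, None] + b + eps_t
    matrix = pd.DataFrame(
        np.hstack([t, nt]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[*design.tumor, *design.normal],
    )
    truth_genes = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": is_de, "true_log2fc": log2fc}
    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["locus_id", "gene_id", "compartment", "category", "canonical"],
    )
    updated = TruthTable(loci=truth.loci, genes=truth_genes, pairs=pairs)
    updated.validate()
    return matrix, updated


def simulate_dataset(cfg: SimConfig, loci_mode: str = "direct-placement") -> dict:
    """End-to-end convenience wrapper: annotation, loci, methylome, expression.

    Returns a dict with keys ``genes, cgis, chrom_lengths, loci,
    loci_annotated, methylation, expression, design, truth``.
    """
    genes, cgis, chrom_lengths = generate_annotation(cfg)
    loci = generate_loci(cfg, chrom_lengths, mode=loci_mode)
    loci_ann = annotate_loci(
        loci,
        genes,
        cgis,
        promoter_width=cfg.promoter_width,
        gb_start_offset=cfg.gb_start_offset,
        chrom_lengths=chrom_lengths,
    )
    meth, design, truth = simulate_methylome(cfg, loci_ann)
    expr, truth = simulate_expression(cfg, genes, truth, loci_ann, design)
    return {
        "genes": genes,
        "cgis": cgis,
        "chrom_lengths": chrom_lengths,
        "loci": loci,
        "loci_annotated": loci_ann,
        "methylation": meth,
        "expression": expr,
        "design": design,
        "truth": truth,
    }
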