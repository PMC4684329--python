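"""Paired tumor vs non-tumor testing with BH-FDR, shared by DM and DE calls.

Each feature (methylation locus or expression gene) is tested with a plain
paired t-test over subjects: ``d_s = T_s - NT_s``, ``t = mean(d) /
(sd(d)/sqrt(n))``, two-sided p from the t distribution with ``n - 1``
degrees of freedom.  P-values are adjusted with the Benjamini-Hochberg
step-up procedure and features with ``q < alpha`` are called significant.

Sign convention (HELP delta): the score is a normalized MspI/HpaII log
ratio, so a locus *hypermethylated* in tumor has ``delta < 0`` and a
hypomethylated locus has ``delta > 0``.  Magnitude classes follow the
|delta| bands negligible [0, 0.5), small [0.5, 1), moderate/large [1, inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class PairedDesign:
    """Subjects x {T, NT} sample mapping.

    ``tumor[s]`` and ``normal[s]`` give the tumor and non-tumor sample ids
    of subject ``subjects[s]``; every subject has exactly one of each.
    """

    subjects: tuple[str, ...]
    tumor: tuple[str, ...]
    normal: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.subjects)
        if len(self.tumor) != n or len(self.normal) != n:
            raise ValueError("subjects, tumor and normal must have equal length")
        if len(set(self.subjects)) != n:
            raise ValueError("duplicate subject ids in design")
        samples = list(self.tumor) + list(self.normal)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids in design")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_sample_sheet(cls, sheet: pd.DataFrame) -> "PairedDesign":
        """Build a design from a sample sheet (sample_id, subject_id, tissue).

        Raises a ``ValueError`` naming the offending subjects when any
        subject does not have exactly one T and one NT sample.
        """
        required = {"sample_id", "subject_id", "tissue"}
        missing = required - set(sheet.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        bad_tissue = sorted(set(sheet["tissue"]) - {"T", "NT"})
        if bad_tissue:
            raise ValueError(f"tissue values must be T or NT, got {bad_tissue}")
        subjects, tum, nor, offenders = [], [], [], []
        for subj, grp in sheet.groupby("subject_id", sort=True):
            t = grp.loc[grp["tissue"] == "T", "sample_id"].tolist()
            n = grp.loc[grp["tissue"] == "NT", "sample_id"].tolist()
            if len(t) != 1 or len(n) != 1:
                offenders.append(str(subj))
                continue
            subjects.append(str(subj))
            tum.append(str(t[0]))
            nor.append(str(n[0]))
        if offenders:
            raise ValueError(
                "subjects without exactly one T and one NT sample: "
                + ", ".join(offenders)
            )
        return cls(tuple(subjects), tuple(tum), tuple(nor))

    def subset(self, subjects: list[str]) -> "PairedDesign":
        idx = {s: i for i, s in enumerate(self.subjects)}
        keep = [idx[s] for s in subjects]
        return PairedDesign(
            tuple(self.subjects[i] for i in keep),
            tuple(self.tumor[i] for i in keep),
            tuple(self.normal[i] for i in keep),
        )


def paired_t_test(
    values_t: np.ndarray, values_nt: np.ndarray
) -> tuple[float, float, float]:
    """Paired t-test of subject-aligned T vs NT values.

    Returns ``(mean_diff, t_stat, p)``.  Missing values are handled
    pairwise-complete (a pair is dropped if either member is NaN).
    Degenerate cases: all differences zero -> ``t = 0, p = 1``; zero spread
    with a nonzero mean -> ``p = 0`` with an infinite t (flagged by a
    warning).  Fewer than two complete pairs raises a ``ValueError``.
    """
    t_arr = np.asarray(values_t, dtype=float)
    n_arr = np.asarray(values_nt, dtype=float)
    if t_arr.shape != n_arr.shape:
        raise ValueError("T and NT vectors must be subject-aligned (equal length)")
    d = t_arr - n_arr
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.0, 1.0
        warnings.warn(
            "degenerate paired t-test: zero variance with nonzero mean",
            RuntimeWarning,
            stacklevel=2,
        )
        return mean, float(np.sign(mean)) * float("inf"), 0.0
    t_stat = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 1))
    return mean, float(t_stat), p


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_direction(delta: float, q: float, alpha: float = ALPHA_DEFAULT) -> str:
    """hyper / hypo / none from the HELP sign convention at FDR level alpha.

    ``delta < 0`` with ``q < alpha`` is hypermethylated-in-tumor; ``delta >
    0`` hypomethylated; non-significant or exactly-zero deltas are ``none``.
    """
    if q >= alpha or delta == 0:
        return "none"
    return "hyper" if delta < 0 else "hypo"


def classify_magnitude(delta: float) -> str:
    """|delta| band: negligible [0, 0.5), small [0.5, 1), moderate/large >= 1."""
    a = abs(delta)
    if a < 0.5:
        return "negligible"
    if a < 1.0:
        return "small"
    return "moderate_large"


def _paired_stats_matrix(
    matrix: pd.DataFrame, design: PairedDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized paired t over all rows; returns (mean, t, p, n_pairs)."""
    missing = [s for s in (*design.tumor, *design.normal) if s not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks design samples: {missing}")
    t_mat = matrix[list(design.tumor)].to_numpy(dtype=float)
    n_mat = matrix[list(design.normal)].to_numpy(dtype=float)
    d = t_mat - n_mat
    valid = ~np.isnan(d)
    n = valid.sum(axis=1)
    d0 = np.where(valid, d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = d0.sum(axis=1) / n
        resid = np.where(valid, d0 - mean[:, None], 0.0)
        var = (resid**2).sum(axis=1) / np.maximum(n - 1, 1)
        sd = np.sqrt(var)
        t_stat = mean / (sd / np.sqrt(n))
    p = np.full(mean.shape, np.nan)
    ok = (n >= 2) & (sd > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), df=n[ok] - 1)
    zero_sd = (n >= 2) & (sd == 0)
    t_stat[zero_sd & (mean == 0)] = 0.0
    p[zero_sd & (mean == 0)] = 1.0
    deg = zero_sd & (mean != 0)
    if deg.any():
        warnings.warn(
            f"{int(deg.sum())} feature(s) with zero variance and nonzero "
            "mean difference; p set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        t_stat[deg] = np.sign(mean[deg]) * np.inf
        p[deg] = 0.0
    return mean, t_stat, p, n


def run_dm(
    matrix: pd.DataFrame,
    design: PairedDesign,
    annotation: pd.DataFrame | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Differential-methylation table: one record per locus.

    Parameters
    ----------
    matrix
        Methylation scores, rows indexed by locus id, columns sample ids.
    design
        The paired T/NT design.
    annotation
        Optional annotated-locus table (``locus_id, chrom, start, end,
        compartment, linked_gene, subcompartment``) merged onto results.

    Returns a DataFrame sorted by ``q`` ascending, then |delta| descending,
    then locus id, with columns ``locus_id, delta, t_stat, p, q, direction,
    magnitude`` plus any annotation columns.  Features with fewer than two
    complete pairs are dropped with a warning.
    """
    mean, t_stat, p, n = _paired_stats_matrix(matrix, design)
    skip = n < 2
    if skip.any():
        warnings.warn(
            f"skipping {int(skip.sum())} feature(s) with < 2 complete pairs",
            RuntimeWarning,
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "locus_id": matrix.index.astype(str),
            "delta": mean,
            "t_stat": t_stat,
            "p": p,
            "n_pairs": n,
        }
    )[~skip].reset_index(drop=True)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["direction"] = [
        classify_direction(d, q, alpha) for d, q in zip(out["delta"], out["q"])
    ]
    out["magnitude"] = [classify_magnitude(d) for d in out["delta"]]
    if annotation is not None:
        cols = [
            c
            for c in ("chrom", "start", "end", "compartment", "linked_gene", "subcompartment")
            if c in annotation.columns
        ]
        ann = annotation[["locus_id", *cols]].astype({"locus_id": str})
        out = out.merge(ann, on="locus_id", how="left")
    out = out.sort_values(
        by=["q", "delta", "locus_id"],
        key=lambda s: -s.abs() if s.name == "delta" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def run_de(
    matrix: pd.DataFrame,
    design: PairedDesign,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Differential-expression table: one record per gene.

    Same engine as :func:`run_dm` on a genes x samples log2 expression
    matrix; ``log2fc`` is the mean paired difference and direction is
    ``up``/``down``/``none`` from its sign at ``q < alpha``.
    """
    mean, t_stat, p, n = _paired_stats_matrix(matrix, design)
    skip = n < 2
    if skip.any():
        warnings.warn(
            f"skipping {int(skip.sum())} gene(s) with < 2 complete pairs",
            RuntimeWarning,
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "gene_id": matrix.index.astype(str),
            "log2fc": mean,
            "t_stat": t_stat,
            "p": p,
            "n_pairs": n,
        }
    )[~skip].reset_index(drop=True)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["direction"] = [
        "none" if (q >= alpha or f == 0) else ("up" if f > 0 else "down")
        for f, q in zip(out["log2fc"], out["q"])
    ]
    out = out.sort_values(
        by=["q", "log2fc", "gene_id"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return out
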