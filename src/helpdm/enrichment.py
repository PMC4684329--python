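"""Compartment over-representation of DM loci and categorical chi-square tests.

The permutation test asks whether differentially methylated loci are
over-represented in a target genomic compartment (gene bodies, in the
motivating analysis): each iteration draws as many loci as were called DM,
uniformly without replacement from all loci on the array, and records how
many land in the target compartment.  The empirical one-sided p-value is
``(1 + #{null >= observed}) / (B + 1)``, which can never be smaller than
``1/(B+1)``; a Gaussian-approximation p computed from the null draws is
reported alongside for effects far beyond that resolution.  Because the
null is sampling without replacement, the exact reference distribution is
hypergeometric, which ``mode="exact"`` evaluates directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    target: str
    observed: int
    n_dm: int
    n_universe: int
    empirical_p: float
    gaussian_p: float
    null_mean: float
    null_sd: float
    B: int
    seed: int | None
    mode: str
    null_draws: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "observed": self.observed,
            "n_dm": self.n_dm,
            "n_universe": self.n_universe,
            "empirical_p": self.empirical_p,
            "gaussian_p": self.gaussian_p,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "B": self.B,
            "seed": self.seed,
            "mode": self.mode,
        }


def permutation_compartment_test(
    dm_locus_ids,
    universe: pd.DataFrame,
    target: str = "GB",
    B: int = 1000,
    seed: int | None = None,
    mode: str = "montecarlo",
) -> EnrichmentResult:
    """Over-representation of DM loci in ``target`` among all array loci.

    Parameters
    ----------
    dm_locus_ids
        Ids of the significant DM loci; must be a subset of the universe.
    universe
        DataFrame with ``locus_id`` and ``compartment`` for every locus on
        the array.
    mode
        ``"montecarlo"`` runs ``B`` random-sampling iterations (seeded);
        ``"exact"`` evaluates the hypergeometric upper tail, which is the
        limit the Monte-Carlo procedure converges to.

    In exact mode ``empirical_p`` carries the hypergeometric tail
    probability and no +1 smoothing applies.
    """
    ids = pd.Index(pd.unique(pd.Series(list(dm_locus_ids), dtype=str)))
    uni_ids = universe["locus_id"].astype(str)
    if not ids.isin(uni_ids).all():
        raise ValueError("dm locus ids must be a subset of the universe")
    n_uni = len(universe)
    n_dm = len(ids)
    if n_dm > n_uni:
        raise ValueError("more DM loci than universe loci")
    if B < 1:
        raise ValueError("B must be >= 1")
    is_target = (universe["compartment"].astype(str) == target).to_numpy()
    k_target = int(is_target.sum())
    observed = int(
        (universe.loc[uni_ids.isin(ids), "compartment"].astype(str) == target).sum()
    )

    if mode == "exact":
        # sampling without replacement => hypergeometric null, upper tail
        p = float(stats.hypergeom.sf(observed - 1, n_uni, k_target, n_dm))
        mu = n_dm * k_target / n_uni
        sd = float(np.sqrt(stats.hypergeom.var(n_uni, k_target, n_dm)))
        gp = _gaussian_tail(observed, mu, sd)
        return EnrichmentResult(
            target, observed, n_dm, n_uni, p, gp, mu, sd, B, seed, mode, None
        )
    if mode != "montecarlo":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    draws = np.empty(B, dtype=np.int64)
    for b in range(B):
        picks = rng.choice(n_uni, size=n_dm, replace=False)
        draws[b] = int(is_target[picks].sum())
    empirical_p = (1 + int((draws >= observed).sum())) / (B + 1)
    mu = float(draws.mean())
    sd = float(draws.std(ddof=1)) if B > 1 else 0.0
    gp = _gaussian_tail(observed, mu, sd)
    return EnrichmentResult(
        target, observed, n_dm, n_uni, empirical_p, gp, mu, sd, B, seed, mode, draws
    )


def _gaussian_tail(observed: float, mu: float, sd: float) -> float:
    if sd == 0:
        return 1.0 if observed <= mu else 0.0
    return float(stats.norm.sf((observed - mu) / sd))


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; df = (r-1)(c-1).  A zero row or column
    marginal is an error; expected counts below 5 only trigger a warning.
    Returns ``(chi2, df, p)``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("table must contain nonnegative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column marginal")
    res = stats.chi2_contingency(arr, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn(
            "chi-square expected count below 5; asymptotic p may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(res.statistic), int(res.dof), float(res.pvalue)


def compartment_summary(
    dm_table: pd.DataFrame, universe: pd.DataFrame
) -> pd.DataFrame:
    """Genomic distribution of DM loci, one row per compartment.

    Columns: ``n_on_array`` (universe loci), ``n_dm`` (loci with a
    hyper/hypo call), ``pct_of_represented`` (DM as % of array loci),
    ``pct_hypo`` / ``pct_hyper`` (% of the DM count, rounded to integer).
    Percentages are NA for compartments with no DM loci.  The residual of
    hyper% + hypo% from 100 is rounding plus any nominally significant
    loci with direction ``none``.
    """
    rows = []
    uni_counts = universe.groupby("compartment")["locus_id"].count()
    sig = dm_table[dm_table["direction"].isin(["hyper", "hypo"])]
    for comp in ("PR", "GB", "IG"):
        n_arr = int(uni_counts.get(comp, 0))
        grp = sig[sig["compartment"] == comp]
        n_dm = len(grp)
        if n_dm:
            pct_hypo = round(100.0 * (grp["direction"] == "hypo").sum() / n_dm)
            pct_hyper = round(100.0 * (grp["direction"] == "hyper").sum() / n_dm)
        else:
            pct_hypo = pct_hyper = np.nan
        rows.append(
            {
                "compartment": comp,
                "n_on_array": n_arr,
                "n_dm": n_dm,
                "pct_of_represented": (
                    round(100.0 * n_dm / n_arr) if n_arr and n_dm else np.nan
                ),
                "pct_hypo": pct_hypo,
                "pct_hyper": pct_hyper,
            }
        )
    return pd.DataFrame(rows)
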