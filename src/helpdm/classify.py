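"""Tumor vs non-tumor discrimination from top-ranked DM loci.

The discriminatory-classifier analysis repeatedly splits subjects 2/3 train
and 1/3 test (a subject's T and NT samples always travel together, so a
pair never straddles the split), re-runs the paired DM test on the training
subjects only, takes the top ``k`` loci by FDR, and evaluates a
nearest-centroid classifier on the held-out samples.  Loci selected in
every iteration are reported as stable discriminators.

The module also implements loco-regional consistency ranking: a significant
locus scores one point for every other significant locus on the same
chromosome, in the same compartment, changing in the same direction, within
a configurable edge-to-edge distance.  High scores nominate loci whose
methylation change is regionally reproduced, the candidates worth
independent technical validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from helpdm.paired import PairedDesign, run_dm


@dataclass
class IterationResult:
    selected: list[str]
    accuracy: float
    sensitivity: float
    specificity: float
    n_test_t: int
    n_test_nt: int


@dataclass
class ClassifierReport:
    k: int
    n_iterations: int
    seed: int | None
    iterations: list[IterationResult]
    selection_frequency: dict[str, int]

    @property
    def mean_accuracy(self) -> float:
        """Average of the per-iteration (per-split) accuracies."""
        return float(np.mean([it.accuracy for it in self.iterations]))

    @property
    def pooled_accuracy(self) -> float:
        """Accuracy over all test samples pooled across iterations."""
        correct = sum(
            it.accuracy * (it.n_test_t + it.n_test_nt) for it in self.iterations
        )
        n = sum(it.n_test_t + it.n_test_nt for it in self.iterations)
        return float(correct / n)

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([it.sensitivity for it in self.iterations]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([it.specificity for it in self.iterations]))

    @property
    def stable_loci(self) -> list[str]:
        """Loci selected in every iteration."""
        return sorted(
            l for l, c in self.selection_frequency.items() if c == self.n_iterations
        )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "mean_accuracy": self.mean_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "stable_loci": self.stable_loci,
            "selection_frequency": dict(
                sorted(self.selection_frequency.items(), key=lambda kv: (-kv[1], kv[0]))
            ),
            "iterations": [
                {
                    "accuracy": it.accuracy,
                    "sensitivity": it.sensitivity,
                    "specificity": it.specificity,
                    "selected": it.selected,
                }
                for it in self.iterations
            ],
        }


def split_by_subject(
    design: PairedDesign,
    train_fraction: float = 2 / 3,
    seed: int | None = None,
) -> tuple[PairedDesign, PairedDesign]:
    """Random subject-level partition into train and test designs.

    Subjects (not samples) are shuffled and split so each subject's T and NT
    samples stay on one side.  The train size is ``train_fraction`` of the
    subjects rounded to the nearest count, kept within [1, n-1] so both
    sides are nonempty.
    """
    n = design.n_subjects
    if n < 3:
        raise ValueError(f"need >= 3 subjects to split, got {n}")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    subjects = np.array(design.subjects)
    train = sorted(subjects[order[:n_train]].tolist())
    test = sorted(subjects[order[n_train:]].tolist())
    return design.subset(train), design.subset(test)


def select_top_k(dm_table: pd.DataFrame, k: int) -> list[str]:
    """Top ``k`` loci by q ascending, |delta| descending, then locus id.

    Returns min(k, available) loci, warning when fewer than ``k`` exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = dm_table.sort_values(
        by=["q", "delta", "locus_id"],
        key=lambda s: -s.abs() if s.name == "delta" else s,
        kind="mergesort",
    )
    if len(ranked) < k:
        warnings.warn(
            f"requested top {k} loci but only {len(ranked)} available",
            RuntimeWarning,
            stacklevel=2,
        )
    return ranked["locus_id"].head(k).tolist()


def fit_and_evaluate(
    train_matrix: pd.DataFrame,
    test_matrix: pd.DataFrame,
    selected: list[str],
    train_design: PairedDesign,
    test_design: PairedDesign,
) -> tuple[float, float, float]:
    """Nearest-centroid classification of test samples over selected loci.

    Class centroids (T and NT) are means of the training samples in the
    selected-locus subspace; each test sample is assigned to the nearest
    centroid by Euclidean distance (ties go to NT).  Returns ``(accuracy,
    sensitivity, specificity)`` where sensitivity is tumor recall and
    specificity non-tumor recall.
    """
    if not selected:
        raise ValueError("empty locus selection")
    missing = [l for l in selected if l not in train_matrix.index]
    missing += [l for l in selected if l not in test_matrix.index]
    if missing:
        raise ValueError(f"selected loci absent from matrix: {sorted(set(missing))}")
    tr = train_matrix.loc[selected]
    te = test_matrix.loc[selected]
    cen_t = tr[list(train_design.tumor)].to_numpy().mean(axis=1)
    cen_nt = tr[list(train_design.normal)].to_numpy().mean(axis=1)

    def _predict(samples: list[str]) -> np.ndarray:
        x = te[samples].to_numpy()  # loci x samples
        d_t = ((x - cen_t[:, None]) ** 2).sum(axis=0)
        d_nt = ((x - cen_nt[:, None]) ** 2).sum(axis=0)
        return d_t < d_nt  # True -> called tumor; tie -> NT

    pred_t = _predict(list(test_design.tumor))
    pred_nt = _predict(list(test_design.normal))
    tp = int(pred_t.sum())
    tn = int((~pred_nt).sum())
    n_t, n_nt = len(pred_t), len(pred_nt)
    sensitivity = tp / n_t
    specificity = tn / n_nt
    accuracy = (tp + tn) / (n_t + n_nt)
    return accuracy, sensitivity, specificity


def iterate_classification(
    matrix: pd.DataFrame,
    design: PairedDesign,
    k: int = 25,
    n_iterations: int = 10,
    seed: int | None = None,
    train_fraction: float = 2 / 3,
    alpha: float = 0.05,
) -> ClassifierReport:
    """Repeated 2/3-1/3 holdout: select top-k DM loci on train, test on rest.

    Locus selection and centroids are computed from training subjects only,
    so held-out data never leak into the model.  ``seed`` drives every
    split; the same seed reproduces the report exactly.
    """
    rng = np.random.default_rng(seed)
    iterations: list[IterationResult] = []
    freq: dict[str, int] = {}
    for _ in range(n_iterations):
        split_seed = int(rng.integers(2**31))
        train_d, test_d = split_by_subject(design, train_fraction, split_seed)
        dm_train = run_dm(matrix, train_d, alpha=alpha)
        selected = select_top_k(dm_train, k)
        acc, sens, spec = fit_and_evaluate(matrix, matrix, selected, train_d, test_d)
        for l in selected:
            freq[l] = freq.get(l, 0) + 1
        iterations.append(
            IterationResult(
                selected, acc, sens, spec, test_d.n_subjects, test_d.n_subjects
            )
        )
    return ClassifierReport(k, n_iterations, seed, iterations, freq)


def consistency_rank(
    dm_sig: pd.DataFrame, window: int = 2000
) -> pd.DataFrame:
    """Loco-regional consistency scores for significant DM loci.

    ``score(L)`` counts other significant loci on the same chromosome, in
    the same compartment, with the same direction, whose edge-to-edge
    distance to ``L`` is strictly less than ``window`` (overlapping loci
    have distance 0; ``window=0`` therefore scores everything 0).  The
    result is ranked by score descending, then q ascending, then locus id.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    required = {"locus_id", "chrom", "start", "end", "compartment", "direction", "q"}
    missing = required - set(dm_sig.columns)
    if missing:
        raise ValueError(f"dm table missing columns: {sorted(missing)}")
    scores = np.zeros(len(dm_sig), dtype=int)
    df = dm_sig.reset_index(drop=True)
    for _, grp in df.groupby(["chrom", "compartment", "direction"], sort=False):
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        idx, starts, ends = idx[order], starts[order], ends[order]
        if window == 0:
            continue
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                # starts are sorted, so the edge-to-edge gap to locus i only
                # grows with j and we can stop at the first too-distant one
                gap = starts[j] - ends[i]
                if gap >= window:
                    break
                scores[idx[i]] += 1
                scores[idx[j]] += 1
    out = df[["locus_id", "chrom", "start", "end", "compartment", "direction", "q"]].copy()
    out["score"] = scores
    out["window"] = window
    return out.sort_values(
        by=["score", "q", "locus_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
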