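"""Dissimilarity-rating studies and their matrix analyses.

A :class:`RatingStudy` holds per-subject stimulus-by-stimulus dissimilarity
matrices on a 1–9 scale (rows = first-presented stimulus), with each stimulus
tagged as a ``recording`` or a ``transformation``.  The analyses implemented
here are:

* cell-wise mean matrices, optionally pooled over presentation order;
* order asymmetry: lower-minus-upper triangular differences (identical pairs
  excluded), split into recording–recording (RR), transformation–
  transformation (TT) and mixed (RT) pairs, tested against zero with
  Bonferroni-corrected one-sample t-tests plus Shapiro–Wilk normality checks;
* inter-rater correlation (IRC): mean Fisher-transformed pairwise Pearson
  correlation between subjects, back-transformed, with percentile-bootstrap
  confidence intervals over resampled comparison sets;
* complete-linkage hierarchical clustering with a 70 %-of-maximal-linkage
  cutoff and the cophenetic correlation of the tree.

Stimuli are conventionally ordered recordings first; the sign convention for
mixed-pair asymmetries is transformation-first minus recording-first, so a
positive mean means transformation-then-recording presentations are rated
more dissimilar.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "RatingStudy",
    "MeanDissimilarityMatrix",
    "DifferenceVector",
    "mean_matrix",
    "asymmetry_differences",
    "asymmetry_test",
    "irc",
    "bootstrap_irc",
    "cluster_tree",
    "subset_cells",
]

RECORDING = "recording"
TRANSFORMATION = "transformation"
_Z_CLIP = 1.0 - 1e-15  # |r| clip before the Fisher transform


@dataclass
class RatingStudy:
    """Per-subject n x n rating matrices (NaN marks unobserved cells)."""

    ratings: np.ndarray  # n_subjects x n x n
    stimuli: list
    classes: list
    scale: tuple = (1.0, 9.0)

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=np.float64)
        n = len(self.stimuli)
        if self.ratings.ndim != 3 or self.ratings.shape[1:] != (n, n):
            raise ValueError("ratings must be n_subjects x n x n")
        if len(self.classes) != n:
            raise ValueError("one class label per stimulus required")
        bad = {c for c in self.classes} - {RECORDING, TRANSFORMATION}
        if bad:
            raise ValueError(f"unknown stimulus classes: {bad}")
        obs = self.ratings[~np.isnan(self.ratings)]
        lo, hi = self.scale
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise ValueError("ratings outside the rating scale")

    @property
    def n_subjects(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def is_full_design(self) -> bool:
        """True when every subject rated both orders of every pair."""
        iu = np.triu_indices(self.n_stimuli, k=1)
        both = (~np.isnan(self.ratings[:, iu[0], iu[1]])
                & ~np.isnan(self.ratings[:, iu[1], iu[0]]))
        return bool(np.all(both))

    def to_frame(self) -> pd.DataFrame:
        """Long format: subject, row_stimulus, col_stimulus, rating."""
        recs = [
            (s, self.stimuli[i], self.stimuli[j], self.ratings[s, i, j])
            for s in range(self.n_subjects)
            for i in range(self.n_stimuli)
            for j in range(self.n_stimuli)
            if not np.isnan(self.ratings[s, i, j])
        ]
        return pd.DataFrame(recs, columns=["subject", "row_stimulus",
                                           "col_stimulus", "rating"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, classes: dict,
                   scale: tuple = (1.0, 9.0)) -> "RatingStudy":
        stimuli = sorted(set(frame["row_stimulus"]) | set(frame["col_stimulus"]),
                         key=lambda s: (classes[s] != RECORDING, s))
        idx = {s: i for i, s in enumerate(stimuli)}
        subjects = sorted(frame["subject"].unique())
        mats = np.full((len(subjects), len(stimuli), len(stimuli)), np.nan)
        for k, subj in enumerate(subjects):
            sub = frame[frame["subject"] == subj]
            for _, row in sub.iterrows():
                mats[k, idx[row["row_stimulus"]], idx[row["col_stimulus"]]] = \
                    row["rating"]
        return cls(mats, stimuli, [classes[s] for s in stimuli], scale)


@dataclass
class MeanDissimilarityMatrix:
    values: np.ndarray
    counts: np.ndarray
    stimuli: list
    order_averaged: bool


@dataclass
class DifferenceVector:
    values: np.ndarray
    pairs: list          # (row_stimulus, col_stimulus) of the minuend cell
    subset: str          # all | RR | TT | RT


def mean_matrix(study: RatingStudy,
                average_order: bool = False) -> MeanDissimilarityMatrix:
    """Cell-wise mean over subjects; optionally pool (i,j) with (j,i)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(study.ratings, axis=0)
    counts = np.sum(~np.isnan(study.ratings), axis=0)
    if average_order:
        sums = np.nansum(np.nan_to_num(study.ratings), axis=0)
        pooled_counts = counts + counts.T
        np.fill_diagonal(pooled_counts, np.diag(counts))
        pooled = sums + sums.T
        np.fill_diagonal(pooled, np.diag(sums))
        if np.any(pooled_counts == 0):
            raise ValueError("cell with zero observations")
        m = pooled / pooled_counts
        counts = pooled_counts
    elif np.any(counts == 0):
        raise ValueError("cell with zero observations")
    return MeanDissimilarityMatrix(m, counts, list(study.stimuli),
                                   average_order)


def _pair_subset(classes: list, i: int, j: int) -> str:
    ci, cj = classes[i], classes[j]
    if ci == cj:
        return "RR" if ci == RECORDING else "TT"
    return "RT"


def asymmetry_differences(matrix: np.ndarray, classes: list,
                          subset: str = "all") -> DifferenceVector:
    """Order differences per unordered pair, identical pairs excluded.

    For same-class pairs the difference is lower-triangle minus
    upper-triangle.  For mixed pairs it is the transformation-first cell
    minus the recording-first cell regardless of matrix ordering, which with
    the recordings-first convention coincides with lower minus upper.
    """
    m = np.asarray(matrix, dtype=np.float64)
    n = m.shape[0]
    if m.shape != (n, n):
        raise ValueError("matrix must be square")
    if np.any(np.isnan(m)):
        raise ValueError("asymmetry requires full (both-order) data")
    if len(classes) != n:
        raise ValueError("one class per stimulus required")
    vals, pairs = [], []
    labels = list(range(n))
    for i in range(n):
        for j in range(i):
            kind = _pair_subset(classes, i, j)
            if subset != "all" and kind != subset:
                continue
            if kind == "RT" and classes[i] == RECORDING:
                # ensure transformation-first cell is the minuend
                vals.append(m[j, i] - m[i, j])
                pairs.append((labels[j], labels[i]))
            else:
                vals.append(m[i, j] - m[j, i])
                pairs.append((labels[i], labels[j]))
    return DifferenceVector(np.asarray(vals), pairs, subset)


def asymmetry_test(diff_vectors: dict, alpha: float = 0.05,
                   n_comparisons: int = 6) -> pd.DataFrame:
    """Two-sided one-sample t-tests of order differences against zero.

    One row per subset with t, df, p, the Shapiro–Wilk normality p, and a
    Bonferroni-corrected significance flag (threshold ``alpha /
    n_comparisons``).
    """
    rows = []
    crit = alpha / n_comparisons
    for name, dv in diff_vectors.items():
        d = dv.values if isinstance(dv, DifferenceVector) else np.asarray(dv)
        if d.size < 3:
            raise ValueError(f"subset {name!r}: need >= 3 differences")
        if np.ptp(d) == 0:
            t, p = (0.0, 1.0) if d[0] == 0 else (np.inf, 0.0)
            sw_p = np.nan
        else:
            t, p = stats.ttest_1samp(d, 0.0)
            sw_p = stats.shapiro(d).pvalue
        rows.append({"subset": name, "mean": float(np.mean(d)),
                     "t": float(t), "df": d.size - 1, "p": float(p),
                     "normality_p": float(sw_p),
                     "alpha_crit": crit, "significant": float(p) < crit})
    return pd.DataFrame(rows).set_index("subset")


def subset_cells(study: RatingStudy, subset: str = "all") -> list:
    """Unordered comparison cells (i, j), i >= j, belonging to a subset.

    Identical pairs are included for ``all``, ``RR`` and ``TT`` (matching the
    28 = C(7,2) + 7 cardinality of the study's smallest subsets); mixed (RT)
    pairs have no identical members by construction.
    """
    cells = []
    for i in range(study.n_stimuli):
        for j in range(i + 1):
            if i == j:
                kind = "RR" if study.classes[i] == RECORDING else "TT"
            else:
                kind = _pair_subset(study.classes, i, j)
            if subset == "all" or kind == subset:
                cells.append((i, j))
    return cells


def _subject_vectors(study: RatingStudy, cells: list) -> np.ndarray:
    """Per-subject unordered-pair values (mean of whichever orders exist)."""
    vecs = np.full((study.n_subjects, len(cells)), np.nan)
    for k, (i, j) in enumerate(cells):
        a = study.ratings[:, i, j]
        b = study.ratings[:, j, i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vecs[:, k] = np.nanmean(np.stack([a, b]), axis=0)
    return vecs


def _mean_pairwise_r(vecs: np.ndarray) -> float:
    """Fisher-averaged pairwise Pearson r over subjects (rows)."""
    zs = []
    for a, b in itertools.combinations(range(vecs.shape[0]), 2):
        x, y = vecs[a], vecs[b]
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3:
            continue
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            warnings.warn("constant ratings for a subject pair; skipped")
            continue
        r = np.corrcoef(x[ok], y[ok])[0, 1]
        zs.append(np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP)))
    if not zs:
        raise ValueError("no valid subject pairs for IRC")
    return float(np.tanh(np.mean(zs)))


def irc(study: RatingStudy, subset: str = "all") -> float:
    """Inter-rater correlation for one subset of comparisons."""
    if study.n_subjects < 2:
        raise ValueError("IRC needs at least 2 subjects")
    return _mean_pairwise_r(_subject_vectors(study, subset_cells(study, subset)))


def bootstrap_irc(study: RatingStudy, subset: str = "all",
                  n_draw: int = 28, n_boot: int = 1000,
                  seed: int | None = None) -> dict:
    """Percentile-bootstrap CI of the IRC over resampled comparison sets.

    Every bootstrap sample draws ``n_draw`` comparisons with replacement
    (a fixed draw size keeps IRC comparable across subsets of different
    cardinality); 2.5/97.5 percentiles of the resampled IRC form the CI.
    """
    if study.n_subjects < 2:
        raise ValueError("IRC needs at least 2 subjects")
    cells = subset_cells(study, subset)
    vecs = _subject_vectors(study, cells)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(cells), size=n_draw)
        boots[b] = _mean_pairwise_r(vecs[:, idx])
    return {
        "point": _mean_pairwise_r(vecs),
        "mean": float(np.mean(boots)),
        "ci_low": float(np.percentile(boots, 2.5)),
        "ci_high": float(np.percentile(boots, 97.5)),
    }


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_tree(matrix: np.ndarray, labels: list | None = None,
                 cutoff_frac: float = 0.70) -> dict:
    """Complete-linkage clustering of a symmetric dissimilarity matrix.

    Flat clusters are cut at ``cutoff_frac`` of the maximal linkage height;
    the cophenetic correlation measures how faithfully the tree's merge
    heights reproduce the input dissimilarities.  Returns the scipy linkage
    matrix, flat cluster ids, the cophenetic correlation, and a Newick string.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("clustering requires a symmetric (order-averaged) matrix")
    if labels is None:
        labels = [str(i) for i in range(m.shape[0])]
    condensed = squareform(m, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    height = Z[:, 2].max()
    flat = hierarchy.fcluster(Z, t=cutoff_frac * height, criterion="distance")
    coph_r, _ = hierarchy.cophenet(Z, condensed)
    newick = _to_newick(hierarchy.to_tree(Z), list(labels)) + ";"
    return {"linkage": Z, "clusters": flat, "n_clusters": int(flat.max()),
            "cophenetic_r": float(coph_r), "newick": newick,
            "labels": list(labels)}
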