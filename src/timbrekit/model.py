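"""Acoustic + categorical dissimilarity model via SIMPLS partial
least-squares regression.

Pairwise dissimilarity ratings are regressed on absolute descriptor
differences ("deltas") between the two stimuli of each pair, optionally
augmented with binary categorical predictors:

* four within-recordings indicators (instrument family, impulsive/continuous
  excitation, excitation mechanism, resonator type), 1 when the two
  recordings differ on that scheme;
* a mixed-pair indicator for recording/transformation comparisons, or two
  order-split indicators (recording-then-transformation and the reverse) for
  designs that keep both presentation orders.

Predictors and response are z-normalized before fitting.  SIMPLS (de Jong,
1993) extracts ``k`` latent components maximizing the covariance between
predictor scores and the response; regression coefficients on the original
columns are recovered through beta = W (P'W)^-1 q.  Model complexity is
chosen by seeded k-fold cross-validation, and coefficient significance by a
case-resampling percentile bootstrap (a coefficient is significant when its
95 % CI excludes zero).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CategoryTable",
    "DesignMatrix",
    "PLSRFit",
    "make_pairs",
    "build_design",
    "encode_categories",
    "encode_cross_and_order",
    "zscore",
    "simpls_fit",
    "select_components",
    "bootstrap_beta",
    "evaluate",
    "cross_set_evaluate",
    "compare_r2",
]

CATEGORY_SCHEMES = ["family", "excitation1", "excitation2", "resonator"]

FAMILIES = {"woodwind", "brass", "keyboard", "string", "percussion"}
EXCITATION1 = {"impulsive", "continuous"}
EXCITATION2 = {"blown", "bowed", "struck", "pluck"}
RESONATORS = {"string", "air column", "bar"}


@dataclass
class CategoryTable:
    """Per-recording instrument categories (transformations stay unlabeled)."""

    table: pd.DataFrame  # index: stimulus label; columns: CATEGORY_SCHEMES

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORY_SCHEMES if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing category columns: {missing}")
        checks = [("family", FAMILIES), ("excitation1", EXCITATION1),
                  ("excitation2", EXCITATION2), ("resonator", RESONATORS)]
        for col, vocab in checks:
            bad = set(self.table[col]) - vocab
            if bad:
                raise ValueError(f"unknown {col} values: {bad}")

    def __contains__(self, label) -> bool:
        return label in self.table.index

    def row(self, label) -> pd.Series:
        return self.table.loc[label]


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: list
    row_pairs: list          # (stimulus_a, stimulus_b) per row
    y: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float | None = None
    y_sd: float | None = None
    zscored: bool = False
    dropped_columns: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.columns)
        frame.insert(0, "stim_a", [a for a, _ in self.row_pairs])
        frame.insert(1, "stim_b", [b for _, b in self.row_pairs])
        if self.y is not None:
            frame["y"] = self.y
        return frame


@dataclass
class PLSRFit:
    W: np.ndarray            # p x k weights (T = Xz W, T orthonormal)
    P: np.ndarray            # p x k predictor loadings
    q: np.ndarray            # k response loadings
    T: np.ndarray            # m x k scores
    k: int
    beta: np.ndarray         # p standardized coefficients
    r2: float
    x_var_explained: float
    columns: list
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float


def make_pairs(labels: list, ordered: bool = False,
               include_identical: bool = True) -> list:
    """Pair rows of a design: unordered (i <= j) or both orders (i != j).

    14 stimuli give 105 unordered pairs with identicals, 91 without, and 182
    ordered pairs without identicals.
    """
    if ordered:
        return [(a, b) for a in labels for b in labels if a != b]
    pairs = list(itertools.combinations(labels, 2))
    if include_identical:
        pairs = [(a, a) for a in labels] + pairs
        pairs.sort(key=lambda p: (labels.index(p[0]), labels.index(p[1])))
    return pairs


def encode_categories(stim_a, stim_b, table: CategoryTable) -> np.ndarray:
    """Four binaries: 1 when the pair differs on a category scheme."""
    for s in (stim_a, stim_b):
        if s not in table:
            raise KeyError(f"stimulus {s!r} has no category labels")
    ra, rb = table.row(stim_a), table.row(stim_b)
    return np.array([float(ra[c] != rb[c]) for c in CATEGORY_SCHEMES])


def encode_cross_and_order(stim_a, stim_b, classes: dict,
                           split_order: bool = False) -> np.ndarray:
    """Mixed-pair indicator(s) for recording/transformation comparisons.

    Unsplit: one indicator, 1 for any mixed pair.  Split: two indicators,
    (recording-then-transformation, transformation-then-recording).
    """
    ca, cb = classes[stim_a], classes[stim_b]
    mixed = ca != cb
    if not split_order:
        return np.array([float(mixed)])
    rt = float(mixed and ca == "recording")
    tr = float(mixed and ca == "transformation")
    return np.array([rt, tr])


def build_design(descriptors: pd.DataFrame, pairs: list | None = None,
                 include_identical: bool = True,
                 categories: CategoryTable | None = None,
                 classes: dict | None = None,
                 cross_term: bool = False,
                 split_order: bool = False,
                 y_matrix: np.ndarray | None = None,
                 stimuli_order: list | None = None) -> DesignMatrix:
    """Assemble the pair-wise delta design matrix.

    Rows follow ``pairs`` (defaults to all unordered pairs of the descriptor
    table's index, or all ordered non-identical pairs when ``split_order``);
    acoustic columns are absolute descriptor differences.  Categorical
    columns code 1 for pairs of recordings differing on a scheme and 0 both
    for agreeing pairs and for any pair involving an unlabeled stimulus.
    ``y_matrix`` (stimulus-order indexed mean ratings) fills the response:
    cell (a, b) for ordered rows, the symmetric average for unordered ones.
    """
    labels = list(descriptors.index)
    if pairs is None:
        pairs = make_pairs(labels, ordered=split_order,
                           include_identical=include_identical and not split_order)
    for a, b in pairs:
        if a not in descriptors.index or b not in descriptors.index:
            raise KeyError(f"missing descriptors for pair ({a!r}, {b!r})")
    D = descriptors.to_numpy(dtype=np.float64)
    idx = {lab: i for i, lab in enumerate(descriptors.index)}
    rows = [np.abs(D[idx[a]] - D[idx[b]]) for a, b in pairs]
    X = np.asarray(rows)
    columns = list(descriptors.columns)

    if categories is not None:
        cat_rows = []
        for a, b in pairs:
            if a in categories and b in categories:
                cat_rows.append(encode_categories(a, b, categories))
            else:
                if classes is None:
                    raise ValueError("categorical coding requested for "
                                     f"unlabeled pair ({a!r}, {b!r})")
                cat_rows.append(np.zeros(len(CATEGORY_SCHEMES)))
        X = np.hstack([X, np.asarray(cat_rows)])
        columns += [f"cat_{c}" for c in CATEGORY_SCHEMES]

    if cross_term or split_order:
        if classes is None:
            raise ValueError("cross/order terms need class labels")
        ind = np.asarray([encode_cross_and_order(a, b, classes, split_order)
                          for a, b in pairs])
        X = np.hstack([X, ind])
        columns += (["order_rec_trans", "order_trans_rec"] if split_order
                    else ["cross_category"])

    y = None
    if y_matrix is not None:
        order = stimuli_order or labels
        pos = {lab: i for i, lab in enumerate(order)}
        y = np.empty(len(pairs))
        for r, (a, b) in enumerate(pairs):
            if split_order:
                y[r] = y_matrix[pos[a], pos[b]]
            else:
                y[r] = 0.5 * (y_matrix[pos[a], pos[b]]
                              + y_matrix[pos[b], pos[a]])
    return DesignMatrix(X, columns, list(pairs), y)


def zscore(design: DesignMatrix) -> DesignMatrix:
    """Standardize columns and response to zero mean and unit sd.

    Constant columns are dropped with a warning; normalization statistics
    are retained on the returned design for back-transformation and for
    scoring new data.
    """
    if design.y is None:
        raise ValueError("design has no response attached")
    sd = design.X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(design.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}")
    X = design.X[:, keep]
    mean = X.mean(axis=0)
    sdk = sd[keep]
    y_mean = float(np.mean(design.y))
    y_sd = float(np.std(design.y, ddof=1))
    if y_sd == 0:
        raise ValueError("degenerate (constant) response")
    return replace(design,
                   X=(X - mean) / sdk,
                   columns=[c for c, k in zip(design.columns, keep) if k],
                   y=(design.y - y_mean) / y_sd,
                   x_mean=mean, x_sd=sdk, y_mean=y_mean, y_sd=y_sd,
                   zscored=True, dropped_columns=dropped)


def _simpls_core(X: np.ndarray, y: np.ndarray, k: int):
    """SIMPLS for a univariate response on centered data.

    Returns W (weights giving orthonormal scores), P, q, T.  The covariance
    vector is deflated against an orthonormal basis of the predictor
    loadings after each component.
    """
    m, p = X.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((m, k))
    V = np.zeros((p, k))
    s = X.T @ y
    norm0 = None
    for a in range(k):
        r = s.copy()
        t = X @ r
        t -= t.mean()
        norm = np.linalg.norm(t)
        if norm0 is None:
            norm0 = max(norm, np.finfo(float).tiny)
        if norm < 1e-10 * norm0 or norm < 1e-12:
            # response explained / predictors exhausted; truncate
            return W[:, :a], P[:, :a], q[:a], T[:, :a]
        t /= norm
        r /= norm
        if a > 0:
            # re-orthogonalize scores against earlier components (guards
            # against floating-point drift in the deflation); two passes
            # keep precision even for nearly exhausted directions
            for _ in range(2):
                proj = T[:, :a].T @ t
                t -= T[:, :a] @ proj
                r -= W[:, :a] @ proj
            tn = np.linalg.norm(t)
            if tn < 1e-10:
                return W[:, :a], P[:, :a], q[:a], T[:, :a]
            t /= tn
            r /= tn
        pvec = X.T @ t
        q[a] = float(y @ t)
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ v)
            v -= V[:, :a] @ (V[:, :a].T @ v)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        W[:, a], P[:, a], T[:, a], V[:, a] = r, pvec, t, v
    return W, P, q, T


def _beta_from_loadings(W: np.ndarray, P: np.ndarray, q: np.ndarray,
                        p: int) -> np.ndarray:
    """beta = W (P'W)^-1 q, with a least-squares fallback if P'W is singular
    (possible when the requested k exceeds the numerical rank)."""
    if not q.size:
        return np.zeros(p)
    try:
        return W @ np.linalg.solve(P.T @ W, q)
    except np.linalg.LinAlgError:
        return W @ np.linalg.lstsq(P.T @ W, q, rcond=None)[0]


def simpls_fit(design: DesignMatrix, k: int) -> PLSRFit:
    """Fit a k-component SIMPLS regression on a (z-scored) design.

    Designs that are not yet standardized are z-scored internally.  The
    coefficient vector satisfies beta = W (P'W)^-1 q and reproduces the
    score-space predictions exactly.
    """
    if not design.zscored:
        design = zscore(design)
    m, p = design.X.shape
    if not (1 <= k <= min(m - 1, p)):
        raise ValueError(f"k must lie in [1, min(m-1, p)] = "
                         f"[1, {min(m - 1, p)}]")
    W, P, q, T = _simpls_core(design.X, design.y, k)
    k_eff = q.size
    beta = _beta_from_loadings(W, P, q, p)
    y_hat = design.X @ beta
    ss_tot = float(np.sum(design.y ** 2))
    r2 = 1.0 - float(np.sum((design.y - y_hat) ** 2)) / ss_tot
    x_var = float(np.sum((T @ P.T) ** 2) / np.sum(design.X ** 2)) if k_eff else 0.0
    return PLSRFit(W, P, q, T, k_eff, beta, r2, x_var,
                   list(design.columns), design.x_mean, design.x_sd,
                   design.y_mean, design.y_sd)


def select_components(design: DesignMatrix, folds: int = 6,
                      k_max: int | None = None,
                      seed: int | None = None,
                      rule: str = "1se") -> int:
    """Choose the number of latent components by k-fold cross-validation.

    Folds are a seeded random partition of the rows.  With ``rule="min"``
    the k with minimal mean held-out squared error wins (ties -> smallest
    k); the default ``rule="1se"`` applies the one-standard-error rule —
    the smallest k whose CV error is within one standard error of the
    minimum — which guards against the coin-flip over-selection that plain
    argmin exhibits when extra components only chase noise.
    """
    if not design.zscored:
        design = zscore(design)
    m, p = design.X.shape
    if m < folds:
        raise ValueError("fewer rows than folds")
    k_cap = min(m - int(np.ceil(m / folds)) - 1, p)
    k_max = k_cap if k_max is None else min(k_max, k_cap)
    if k_max < 1:
        raise ValueError("no admissible number of components")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(np.arange(m) % folds)
    fold_mse = np.zeros((folds, k_max))
    for f in range(folds):
        test = assignment == f
        Xtr, ytr = design.X[~test], design.y[~test]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        ym = ytr.mean()
        W, P, q, _ = _simpls_core((Xtr - mu) / sd, ytr - ym, k_max)
        Xte = (design.X[test] - mu) / sd
        for k in range(1, k_max + 1):
            kk = min(k, q.size)
            beta = _beta_from_loadings(W[:, :kk], P[:, :kk], q[:kk],
                                       design.X.shape[1])
            pred = ym + Xte @ beta
            fold_mse[f, k - 1] = float(np.mean((design.y[test] - pred) ** 2))
    mean = fold_mse.mean(axis=0)
    k_min = int(np.argmin(mean))
    if rule == "min":
        return k_min + 1
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds)
    return int(np.flatnonzero(mean <= mean[k_min] + se[k_min])[0]) + 1


def bootstrap_beta(design: DesignMatrix, k: int, n_boot: int = 1000,
                   seed: int | None = None, method: str = "case",
                   max_redraws: int = 100) -> pd.DataFrame:
    """Percentile bootstrap of standardized coefficients.

    ``method="case"`` resamples rows with replacement, re-standardizes and
    refits per replicate (replicates with degenerate columns or response are
    redrawn and counted).  ``method="residual"`` keeps the predictor matrix
    fixed and resamples the fitted model's residuals — appropriate when the
    error can be assumed exchangeable across rows, and better calibrated
    than case resampling when the row count is only a small multiple of the
    column count (resampled duplicates then inflate coefficient spread).
    A coefficient is significant when its 95 % CI excludes zero.
    """
    if method not in ("case", "residual"):
        raise ValueError("method must be 'case' or 'residual'")
    base = zscore(design) if not design.zscored else design
    # raw values of the retained columns (resamples are re-standardized)
    raw_X = base.X * base.x_sd + base.x_mean
    raw_y = base.y * base.y_sd + base.y_mean
    m = raw_X.shape[0]
    rng = np.random.default_rng(seed)
    betas = np.empty((n_boot, base.X.shape[1]))
    redraws = 0
    b = 0
    if method == "residual":
        k_eff = min(k, m - 1, base.p)
        ref = simpls_fit(base, k_eff)
        y_hat = base.y_mean + base.y_sd * (base.X @ ref.beta)
        resid = raw_y - y_hat
        resid = resid - resid.mean()
        # fitted residuals understate the error sd; rescale by the model's
        # degrees of freedom (k components + intercept)
        resid *= np.sqrt(m / max(m - k_eff - 1, 1))
    while b < n_boot:
        if method == "case":
            idx = rng.integers(0, m, size=m)
            Xb, yb = raw_X[idx], raw_y[idx]
        else:
            Xb = raw_X
            yb = y_hat + resid[rng.integers(0, m, size=m)]
        sd = Xb.std(axis=0, ddof=1)
        if np.any(sd == 0) or np.std(yb, ddof=1) == 0:
            redraws += 1
            if redraws > max_redraws * n_boot:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        Xz = (Xb - Xb.mean(axis=0)) / sd
        yz = (yb - yb.mean()) / np.std(yb, ddof=1)
        W, P, q, _ = _simpls_core(Xz, yz, min(k, m - 1, Xz.shape[1]))
        beta_z = _beta_from_loadings(W, P, q, Xz.shape[1])
        if method == "residual":
            # express on the base design's standardized scale
            beta_z = beta_z * (np.std(yb, ddof=1) / base.y_sd)
        betas[b] = beta_z
        b += 1
    fit = simpls_fit(base, min(k, base.m - 1, base.p))
    lo = np.percentile(betas, 2.5, axis=0)
    hi = np.percentile(betas, 97.5, axis=0)
    frame = pd.DataFrame({
        "beta": fit.beta, "ci_low": lo, "ci_high": hi,
        "significant": (lo > 0) | (hi < 0),
    }, index=base.columns)
    frame.attrs["redraws"] = redraws
    return frame


def _predict(fit: PLSRFit, design: DesignMatrix) -> np.ndarray:
    """Predict on the original rating scale using the fit's normalization."""
    cols = [design.columns.index(c) for c in fit.columns]
    X = design.X[:, cols]
    Xz = (X - fit.x_mean) / fit.x_sd
    return fit.y_mean + fit.y_sd * (Xz @ fit.beta)


def evaluate(fit: PLSRFit, design: DesignMatrix) -> float:
    """R^2 = 1 - SS_res/SS_tot of the fit's predictions on a design's y.

    The design must be un-normalized (raw deltas and ratings); the training
    normalization travels with the fit.
    """
    if design.y is None:
        raise ValueError("design has no response attached")
    if design.zscored:
        raise ValueError("evaluate expects a raw (not z-scored) design")
    missing = [c for c in fit.columns if c not in design.columns]
    if missing:
        raise ValueError(f"design lacks fitted columns: {missing}")
    y_hat = _predict(fit, design)
    ss_tot = float(np.sum((design.y - np.mean(design.y)) ** 2))
    return 1.0 - float(np.sum((design.y - y_hat) ** 2)) / ss_tot


def cross_set_evaluate(fit: PLSRFit, design_b: DesignMatrix) -> float:
    """Generalization: score a model fitted on one set against another set."""
    return evaluate(fit, design_b)


def compare_r2(r2_a: float, r2_b: float, m_a: int, m_b: int) -> dict:
    """Fisher z test for two independent multiple correlations.

    The correlations r = sqrt(R^2) are Fisher-transformed and compared with
    z = (atanh(r_a) - atanh(r_b)) / sqrt(1/(m_a - 3) + 1/(m_b - 3)); the
    p-value is two-tailed.  Treating the two fits as independent samples is
    an approximation.
    """
    for r2 in (r2_a, r2_b):
        if not (0 <= r2 < 1):
            raise ValueError("R^2 must lie in [0, 1)")
    if min(m_a, m_b) <= 3:
        raise ValueError("need more than 3 observations per model")
    za = np.arctanh(np.sqrt(r2_a))
    zb = np.arctanh(np.sqrt(r2_b))
    z = (za - zb) / np.sqrt(1.0 / (m_a - 3) + 1.0 / (m_b - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p)}
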