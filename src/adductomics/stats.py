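"""Statistical battery for site discrimination and exposure-adduct association.

Covers the full evaluation chain applied to a dG-normalized adduct table and
site metadata: log/Pareto and log/z-score transformations, Pearson
correlation maps between adducts and sediment contaminants, PERMANOVA (Type
III, sum-to-zero coding) with PERMDISP, SIMPER feature selection on
Bray-Curtis dissimilarity, OPLS-DA with VIP and cross-validated Q2, ROC/AUC
with bootstrap confidence intervals, and volcano-style group contrasts.

All permutation and resampling procedures take explicit seeds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SiteMetadata",
    "TransformSpec",
    "PermanovaResult",
    "OplsModel",
    "RocResult",
    "VolcanoParams",
    "log_half_min",
    "pareto_scale",
    "zscore",
    "transform",
    "pearson_matrix",
    "correlation_sign_test",
    "permanova",
    "permdisp",
    "simper",
    "oplsda",
    "roc",
    "volcano",
]


# ---------------------------------------------------------------------------
# metadata and transformations


@dataclass
class SiteMetadata:
    """Per-sample station/basin/status plus contaminant concentrations.

    ``status`` must be 'C' (contaminated) or 'R' (reference); ``basin``
    distinguishes the two sea basins. ``contaminants`` holds non-negative
    concentrations (PAH congeners and their low/high molecular sums, trace
    metals, and the pollution load index), one row per sample.
    """

    station: pd.Series
    basin: pd.Series
    status: pd.Series
    contaminants: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.status.unique()) - {"C", "R"}
        if bad:
            raise ValueError(f"status labels must be 'C' or 'R', got {bad}")
        if (self.contaminants < 0).any().any():
            raise ValueError("contaminant concentrations must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.status.index)


@dataclass(frozen=True)
class TransformSpec:
    """Column-wise transformations ahead of the multivariate analyses."""

    adduct_transform: str = "log-pareto"
    contaminant_transform: str = "log-zscore"
    drop_invariant: bool = True


def log_half_min(frame: pd.DataFrame) -> pd.DataFrame:
    """Natural log after replacing zeros by half the column's minimum
    positive value (columns with no positive value are left at zero and will
    be dropped as invariant downstream)."""
    out = frame.astype(float).copy()
    for col in out.columns:
        v = out[col].to_numpy()
        pos = v[v > 0]
        if pos.size == 0:
            continue
        v = np.where(v <= 0, pos.min() / 2.0, v)
        out[col] = np.log(v)
    return out


def pareto_scale(frame: pd.DataFrame) -> pd.DataFrame:
    """Center each column and divide by the square root of its standard
    deviation, damping the dominance of high-abundance features."""
    sd = frame.std(ddof=1)
    return (frame - frame.mean()) / np.sqrt(sd)


def zscore(frame: pd.DataFrame) -> pd.DataFrame:
    return (frame - frame.mean()) / frame.std(ddof=1)


def _drop_invariant(frame: pd.DataFrame, label: str) -> pd.DataFrame:
    keep = frame.columns[frame.nunique() >= 2]
    dropped = sorted(set(frame.columns) - set(keep))
    if dropped:
        warnings.warn(f"dropping invariant {label} column(s): {dropped}", stacklevel=3)
    return frame[keep]


def transform(
    norm_area: pd.DataFrame,
    meta: SiteMetadata,
    spec: TransformSpec = TransformSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adduct matrix X (Pareto-scaled log of dG-normalized areas) and
    contaminant matrix Z (column z-scores of logged concentrations)."""
    adducts = log_half_min(norm_area.loc[meta.samples])
    contams = log_half_min(meta.contaminants.loc[meta.samples])
    if spec.drop_invariant:
        adducts = _drop_invariant(adducts, "adduct")
        contams = _drop_invariant(contams, "contaminant")
    return pareto_scale(adducts), zscore(contams)


# ---------------------------------------------------------------------------
# correlations


def pearson_matrix(
    X: pd.DataFrame, Z: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-tailed p for every (column of X, column of Z) pair.

    p-values come from the exact t transform t = r sqrt((n-2)/(1-r^2)).
    Zero-variance columns yield NaN entries.
    """
    n = len(X)
    if n < 3 or len(Z) != n:
        raise ValueError("need >=3 paired observations")
    xs = X.to_numpy(float)
    zs = Z.to_numpy(float)
    xc = xs - xs.mean(axis=0)
    zc = zs - zs.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    zn = np.linalg.norm(zc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ zc) / np.outer(xn, zn)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return (
        pd.DataFrame(r, index=X.columns, columns=Z.columns),
        pd.DataFrame(p, index=X.columns, columns=Z.columns),
    )


def correlation_sign_test(
    r_high: np.ndarray | pd.Series, r_low: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Welch t-test comparing per-adduct mean contaminant correlations of
    high-mass vs low-mass adducts. Returns (t, two-tailed p)."""
    a = np.asarray(r_high, float)
    b = np.asarray(r_low, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP


@dataclass
class PermanovaResult:
    terms: pd.DataFrame  # index: term; columns: df, ss, pseudo_F, R2, p
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    dispersion_p: dict[str, float] = field(default_factory=dict)


def _sum_to_zero_codes(labels: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError(f"factor needs >=2 levels, got {levels}")
    cols = []
    for lev in levels[:-1]:
        col = np.where(labels == lev, 1.0, 0.0)
        col = col - np.where(labels == levels[-1], 1.0, 0.0)
        cols.append(col)
    return np.column_stack(cols)


def _hat(M: np.ndarray) -> np.ndarray:
    return M @ np.linalg.pinv(M.T @ M) @ M.T


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def permanova(
    X: pd.DataFrame | np.ndarray,
    factors: pd.DataFrame,
    terms: tuple[str, ...] = ("status", "basin", "status:basin"),
    n_perm: int | str = 999,
    seed: int | None = None,
    metric: str = "euclidean",
    precomputed: bool = False,
    run_permdisp: bool = True,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with Type III (marginal) tests.

    Factors are coded sum-to-zero; each term's SS is the marginal reduction
    against the model containing all other terms; significance comes from
    free permutation of the observations (``n_perm`` permutations, p =
    (exceedances + 1)/(n_perm + 1)), or exhaustive enumeration with
    ``n_perm="exact"``. PERMDISP accompanies each main-effect factor.
    """
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    D = Xa if precomputed else squareform(pdist(Xa, metric=metric))
    n = D.shape[0]
    for name in factors.columns:
        counts = factors[name].value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"factor {name!r} has singleton level(s): {small}")

    blocks: dict[str, np.ndarray] = {}
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            A, B = blocks[a], blocks[b]
            blocks[term] = np.column_stack(
                [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
            )
        else:
            blocks[term] = _sum_to_zero_codes(factors[term])

    intercept = np.ones((n, 1))
    M_full = np.column_stack([intercept] + [blocks[t] for t in terms])
    H_full = _hat(M_full)
    rank_full = np.linalg.matrix_rank(M_full)
    df_res = n - rank_full
    H_drop = {}
    for term in terms:
        M_red = np.column_stack([intercept] + [blocks[t] for t in terms if t != term])
        H_drop[term] = H_full - _hat(M_red)
    H_resid = np.eye(n) - H_full

    def stats_for(G: np.ndarray) -> tuple[dict[str, float], float]:
        ss_res = float(np.sum(H_resid * G))
        f = {}
        for term in terms:
            ss_t = float(np.sum(H_drop[term] * G))
            df_t = blocks[term].shape[1]
            f[term] = (ss_t / df_t) / (ss_res / df_res)
        return f, ss_res

    G = _gower_center(D)
    total_ss = float(np.trace(G))
    f_obs, ss_res = stats_for(G)
    ss_terms = {t: float(np.sum(H_drop[t] * G)) for t in terms}

    exceed = {t: 0 for t in terms}
    if n_perm == "exact":
        perms = list(itertools.permutations(range(n)))
        for idx in perms:
            idx = np.asarray(idx)
            f_p, _ = stats_for(G[np.ix_(idx, idx)])
            for t in terms:
                if f_p[t] >= f_obs[t] - 1e-12:
                    exceed[t] += 1
        denom = len(perms)
        p = {t: exceed[t] / denom for t in terms}
        n_perm_used = denom
    else:
        rng = np.random.default_rng(seed)
        for _ in range(int(n_perm)):
            idx = rng.permutation(n)
            f_p, _ = stats_for(G[np.ix_(idx, idx)])
            for t in terms:
                if f_p[t] >= f_obs[t] - 1e-12:
                    exceed[t] += 1
        p = {t: (exceed[t] + 1) / (int(n_perm) + 1) for t in terms}
        n_perm_used = int(n_perm)

    table = pd.DataFrame(
        {
            "df": [blocks[t].shape[1] for t in terms],
            "ss": [ss_terms[t] for t in terms],
            "pseudo_F": [f_obs[t] for t in terms],
            "R2": [ss_terms[t] / total_ss for t in terms],
            "p": [p[t] for t in terms],
        },
        index=list(terms),
    )
    disp = {}
    if run_permdisp:
        for term in terms:
            if ":" in term:
                continue
            disp[term] = permdisp(
                D, factors[term], n_perm=999 if n_perm == "exact" else int(n_perm), seed=seed
            )
    return PermanovaResult(table, df_res, ss_res, total_ss, n_perm_used, disp)


def permdisp(
    D: np.ndarray, groups: pd.Series, n_perm: int = 999, seed: int | None = None
) -> float:
    """Permutation test for homogeneity of multivariate dispersions.

    Samples are embedded by principal coordinates; each sample's distance to
    its group centroid is the dispersion measure; a one-way ANOVA F on those
    distances is referred to a permutation distribution of group labels.
    """
    G = _gower_center(np.asarray(D, float))
    vals, vecs = np.linalg.eigh(G)
    keep = vals > 1e-10
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    labels = np.asarray(groups)

    def centroid_dists(lab: np.ndarray) -> np.ndarray:
        d = np.empty(len(lab))
        for lev in np.unique(lab):
            m = lab == lev
            cent = coords[m].mean(axis=0)
            d[m] = np.linalg.norm(coords[m] - cent, axis=1)
        return d

    def anova_f(d: np.ndarray, lab: np.ndarray) -> float:
        grand = d.mean()
        ssb = ssw = 0.0
        k = 0
        for lev in np.unique(lab):
            m = lab == lev
            k += 1
            ssb += m.sum() * (d[m].mean() - grand) ** 2
            ssw += float(np.sum((d[m] - d[m].mean()) ** 2))
        dfb, dfw = k - 1, len(d) - k
        return (ssb / dfb) / (ssw / dfw) if ssw > 0 else np.inf

    d_obs = centroid_dists(labels)
    f_obs = anova_f(d_obs, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p = anova_f(d_obs, labels[rng.permutation(len(labels))])
        if f_p >= f_obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# SIMPER


def simper(
    abundances: pd.DataFrame, groups: pd.Series, cutoff: float = 80.0
) -> pd.DataFrame:
    """Similarity-percentage decomposition of Bray-Curtis dissimilarity.

    For every between-group sample pair the contribution of variable k is
    |x_ik - x_jk| / sum_k (x_ik + x_jk); contributions are averaged over
    pairs and expressed as percent of the average dissimilarity. ``selected``
    marks the smallest descending-sorted prefix whose cumulative contribution
    reaches ``cutoff`` percent.
    """
    A = abundances.to_numpy(float)
    if (A < 0).any():
        raise ValueError("SIMPER requires non-negative abundances")
    zero_rows = abundances.index[A.sum(axis=1) == 0].tolist()
    if zero_rows:
        raise ValueError(f"all-zero sample(s): {zero_rows}")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("SIMPER compares exactly two groups")
    ia = np.nonzero((groups == levels[0]).to_numpy())[0]
    ib = np.nonzero((groups == levels[1]).to_numpy())[0]
    contrib = np.zeros(A.shape[1])
    n_pairs = 0
    for i in ia:
        diff = np.abs(A[i] - A[ib])  # pairs with every member of group B
        denom = (A[i] + A[ib]).sum(axis=1)
        contrib += (diff / denom[:, None]).sum(axis=0)
        n_pairs += len(ib)
    contrib /= n_pairs
    total = contrib.sum()
    if total == 0:
        warnings.warn("groups are identical: zero Bray-Curtis dissimilarity", stacklevel=2)
        pct = np.zeros_like(contrib)
    else:
        pct = contrib / total * 100.0
    out = pd.DataFrame(
        {"average_contribution": contrib, "contribution_pct": pct},
        index=abundances.columns,
    ).sort_values("contribution_pct", ascending=False)
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    if total == 0:
        out["selected"] = False
    else:
        crossed = out["cumulative_pct"] >= cutoff
        first_cross = int(np.argmax(crossed.to_numpy())) if crossed.any() else len(out) - 1
        out["selected"] = np.arange(len(out)) <= first_cross
    out.attrs["average_dissimilarity"] = float(total)
    return out


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OplsModel:
    """Orthogonal-signal-corrected PLS with one predictive component.

    ``weights``/``loadings``/``scores`` belong to the predictive component;
    the orthogonal components (``orth_*``) capture systematic variation in X
    uncorrelated with class. VIP is reported on the predictive component and
    satisfies mean(VIP^2) = 1.
    """

    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    q: float
    y_mean: float
    x_mean: np.ndarray
    orth_weights: list[np.ndarray]
    orth_loadings: list[np.ndarray]
    orth_scores: list[np.ndarray]
    r2y: float
    q2: float
    vip: np.ndarray
    variables: list[str] | None = None

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Continuous class score for new observations (same preprocessing
        as the training matrix is assumed)."""
        Xc = (np.asarray(X, float) - self.x_mean).copy()
        for w_o, p_o in zip(self.orth_weights, self.orth_loadings):
            t_o = Xc @ w_o
            Xc -= np.outer(t_o, p_o)
        return (Xc @ self.weights) * self.q + self.y_mean


def _fit_opls_core(Xc: np.ndarray, yc: np.ndarray, n_orth: int):
    w = Xc.T @ yc
    w /= np.linalg.norm(w)
    orth_w, orth_p, orth_t = [], [], []
    Xd = Xc.copy()
    for _ in range(n_orth):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        orth_w.append(w_o)
        orth_p.append(p_o)
        orth_t.append(t_o)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    return w, p, t, q, orth_w, orth_p, orth_t


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for lev in np.unique(y):
        idx = np.nonzero(y == lev)[0]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f)) for f in folds if f]


def oplsda(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    n_orth: int = 1,
    folds: int = 10,
    seed: int | None = None,
) -> OplsModel:
    """Fit OPLS-DA (one predictive + ``n_orth`` orthogonal components).

    ``y`` is binary (any two labels). R2Y is the fraction of class variance
    explained on the full fit; Q2 = 1 - PRESS/TSS from seeded stratified
    ``folds``-fold cross-validation refitting the whole model per fold.
    """
    variables = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, float)
    y_arr = np.asarray(y)
    classes = np.unique(y_arr)
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {list(classes)}")
    if np.any(Xa.std(axis=0) == 0):
        raise ValueError("X contains zero-variance columns; drop them first")
    yn = np.where(y_arr == classes[1], 1.0, 0.0)

    x_mean = Xa.mean(axis=0)
    y_mean = yn.mean()
    Xc = Xa - x_mean
    yc = yn - y_mean
    w, p, t, q, orth_w, orth_p, orth_t = _fit_opls_core(Xc, yc, n_orth)
    y_hat = t * q
    r2y = 1.0 - float(np.sum((yc - y_hat) ** 2) / np.sum(yc**2))

    rng = np.random.default_rng(seed)
    press = 0.0
    for test_idx in _stratified_folds(yn, folds, rng):
        train = np.setdiff1d(np.arange(len(yn)), test_idx)
        if len(np.unique(yn[train])) < 2:
            continue
        xm = Xa[train].mean(axis=0)
        ym = yn[train].mean()
        wf, pf, tf, qf, ow, op, _ = _fit_opls_core(Xa[train] - xm, yn[train] - ym, n_orth)
        Xt = Xa[test_idx] - xm
        for w_o, p_o in zip(ow, op):
            t_o = Xt @ w_o
            Xt = Xt - np.outer(t_o, p_o)
        pred = (Xt @ wf) * qf + ym
        press += float(np.sum((yn[test_idx] - pred) ** 2))
    tss = float(np.sum((yn - y_mean) ** 2))
    q2 = 1.0 - press / tss

    n_vars = Xa.shape[1]
    vip = np.sqrt(n_vars * w**2 / np.sum(w**2))
    return OplsModel(
        weights=w, loadings=p, scores=t, q=float(q), y_mean=float(y_mean),
        x_mean=x_mean, orth_weights=orth_w, orth_loadings=orth_p,
        orth_scores=orth_t, r2y=r2y, q2=q2, vip=vip, variables=variables,
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lo: float
    ci_hi: float
    threshold: float
    misclassification: float  # percent at the Youden-optimal threshold


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = sps.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """AUC by the rank (Mann-Whitney) statistic with ties counted 0.5,
    a stratified-bootstrap 95% CI, and the misclassification rate at the
    Youden-optimal threshold."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    yb = (y == classes[1]).astype(int)
    auc = _auc_rank(s, yb)

    rng = np.random.default_rng(seed)
    pos = np.nonzero(yb == 1)[0]
    neg = np.nonzero(yb == 0)[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True)]
        )
        boots[b] = _auc_rank(s[idx], yb[idx])
    ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5])
    ci_lo, ci_hi = min(ci_lo, auc), max(ci_hi, auc)

    uniq = np.unique(s)
    cand = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best_j, best_thr = -np.inf, cand[0]
    for thr in cand:
        pred = (s > thr).astype(int)
        sens = (pred[yb == 1] == 1).mean()
        spec = (pred[yb == 0] == 0).mean()
        if sens + spec - 1.0 > best_j + 1e-12:
            best_j, best_thr = sens + spec - 1.0, thr
    mis = float(((s > best_thr).astype(int) != yb).mean() * 100.0)
    return RocResult(auc, float(ci_lo), float(ci_hi), float(best_thr), mis)


# ---------------------------------------------------------------------------
# volcano


@dataclass(frozen=True)
class VolcanoParams:
    """Volcano significance cutoffs.

    ``fc_threshold`` is on the fold-change (ratio) scale, the usual volcano
    convention: the default 2 flags adducts with |log2 FC| >= 1.
    """

    fc_threshold: float = 2.0
    p_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1 or self.p_threshold <= 0:
            raise ValueError("fc_threshold must exceed 1 and p_threshold be positive")

    @property
    def log2_fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


def volcano(
    norm_area: pd.DataFrame,
    groups: pd.Series,
    params: VolcanoParams = VolcanoParams(),
    contaminated_label: str = "C",
) -> pd.DataFrame:
    """Per-adduct log2 fold change (contaminated over reference), Welch
    t-test on log-transformed areas, and up/down/ns flags."""
    lab = groups.loc[norm_area.index]
    mask_c = (lab == contaminated_label).to_numpy()
    if mask_c.sum() < 2 or (~mask_c).sum() < 2:
        raise ValueError("both groups need >=2 samples")
    logged = log_half_min(norm_area)
    rows = []
    for col in norm_area.columns:
        v = norm_area[col].to_numpy(float)
        substituted = False
        mean_c, mean_r = v[mask_c].mean(), v[~mask_c].mean()
        if mean_c <= 0 or mean_r <= 0:
            pos = v[v > 0]
            if pos.size == 0:
                rows.append({"adduct_id": col, "log2_fc": np.nan, "p": np.nan,
                             "flag": "ns", "substituted": True})
                continue
            v2 = np.where(v <= 0, pos.min() / 2.0, v)
            mean_c, mean_r = v2[mask_c].mean(), v2[~mask_c].mean()
            substituted = True
        fc = float(np.log2(mean_c / mean_r))
        lg = logged[col].to_numpy(float)
        if np.allclose(lg[mask_c], lg[mask_c][0]) and np.allclose(lg[~mask_c], lg[~mask_c][0]) \
                and np.isclose(lg[mask_c][0], lg[~mask_c][0]):
            p = 1.0
        else:
            p = float(sps.ttest_ind(lg[mask_c], lg[~mask_c], equal_var=False).pvalue)
        thr = params.log2_fc_threshold
        if fc >= thr and p <= params.p_threshold:
            flag = "up"
        elif fc <= -thr and p <= params.p_threshold:
            flag = "down"
        else:
            flag = "ns"
        rows.append({"adduct_id": col, "log2_fc": fc, "p": p, "flag": flag,
                     "substituted": substituted})
    return pd.DataFrame(rows).set_index("adduct_id")
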