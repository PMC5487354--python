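"""Within-subject inference: factorial repeated-measures ANOVA with partial
eta-squared, normality screening, cluster-based permutation tests on
time-resolved profiles, and design power.

The ANOVA is the classical univariate balanced within-subject
decomposition: every effect (main or interaction) is tested against its
own effect-by-subject interaction as the error term, with uncorrected
degrees of freedom (a Greenhouse-Geisser epsilon is available behind a
flag).  Partial eta-squared is SS_effect / (SS_effect + SS_error).

Time-resolved profiles (100 normalized-time samples) violate pointwise
independence, so condition contrasts are tested with cluster-based
permutation statistics: pointwise statistics are thresholded at the
parametric critical value, contiguous supra-threshold runs form clusters
scored by their summed statistic, and each observed cluster mass is
compared with the distribution of the maximum cluster mass under random
within-subject relabelings of the conditions — a max-statistic correction
for multiple comparisons across time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinematics import MissingCellError

FACTORS = ("action", "addressee", "sign")


# ---------------------------------------------------------------------------
# Cell means
# ---------------------------------------------------------------------------

def cell_means(
    trials: pd.DataFrame,
    params: list[str] | tuple[str, ...],
    factors: tuple[str, ...] = FACTORS,
    subject: str = "subject",
) -> pd.DataFrame:
    """Per-subject condition-cell means of the given parameters.

    Raises :class:`MissingCellError` naming the first subject x cell with
    no trials; with the full 2 x 2 x 3 design every subject must
    contribute 12 means per parameter.
    """
    levels = [sorted(trials[f].unique()) for f in factors]
    means = trials.groupby([subject, *factors], sort=True)[list(params)].mean()
    full = pd.MultiIndex.from_product(
        [sorted(trials[subject].unique()), *levels], names=[subject, *factors]
    )
    missing = full.difference(means.index)
    if len(missing):
        raise MissingCellError(f"subject/cell without trials: {tuple(missing[0])}")
    return means.reindex(full).reset_index()


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-effect F, degrees of freedom, p, and partial eta-squared."""

    table: pd.DataFrame  # index: effect name; columns F, df1, df2, p, eta_p2

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _effect_name(factors: tuple[str, ...]) -> str:
    return ":".join(factors)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, ...] = FACTORS,
    subject: str = "subject",
    gg_correction: bool = False,
) -> AnovaResult:
    """Balanced fully-within-subject factorial ANOVA.

    ``data`` holds exactly one observation (a condition-cell mean) per
    subject per cell.  Sums of squares come from the marginal-means
    (Moebius inversion) decomposition, exact for balanced designs; each
    effect's F uses its effect-by-subject interaction as error.  With
    ``gg_correction`` the p-value (not the printed dfs) is
    Greenhouse-Geisser adjusted.
    """
    subjects = sorted(data[subject].unique())
    levels = [sorted(data[w].unique()) for w in within]
    shape = (len(subjects), *map(len, levels))
    if len(data) != np.prod(shape):
        raise ValueError(
            f"expected one observation per subject per cell "
            f"({np.prod(shape)}), got {len(data)}"
        )
    wide = data.set_index([subject, *within])[dv].sort_index()
    if wide.isna().any():
        raise ValueError("missing cells in ANOVA table")
    Y = wide.to_numpy().reshape(shape)

    n_axes = Y.ndim
    all_axes = tuple(range(n_axes))

    def marginal(keep: frozenset[int]) -> np.ndarray:
        drop = tuple(a for a in all_axes if a not in keep)
        return Y.mean(axis=drop, keepdims=True) if drop else Y

    marg = {frozenset(c): marginal(frozenset(c))
            for r in range(n_axes + 1)
            for c in itertools.combinations(all_axes, r)}

    def ss(term: frozenset[int]) -> float:
        e = np.zeros_like(marg[term])
        for r in range(len(term) + 1):
            for sub in itertools.combinations(sorted(term), r):
                e = e + (-1) ** (len(term) - r) * marg[frozenset(sub)]
        rest = np.prod([shape[a] for a in all_axes if a not in term])
        return float(np.sum(e**2) * rest)

    # scale-aware floor: sums of squares below round-off of the total are
    # treated as exact zeros so degenerate inputs give F = 0, not 0/0 noise
    ss_total = float(np.sum((Y - Y.mean()) ** 2))
    tiny = 1e-12 * max(ss_total, np.finfo(float).tiny)

    rows = []
    factor_axes = list(range(1, n_axes))
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(factor_axes, r):
            names = tuple(within[a - 1] for a in combo)
            df1 = int(np.prod([shape[a] - 1 for a in combo]))
            df2 = df1 * (shape[0] - 1)
            ss_eff = ss(frozenset(combo))
            ss_err = ss(frozenset((0, *combo)))
            if ss_eff < tiny:
                ss_eff = 0.0
            ms_eff, ms_err = ss_eff / df1, ss_err / df2
            if ss_eff == 0.0:
                F = 0.0
            elif ms_err > 0:
                F = ms_eff / ms_err
            else:
                F = np.inf
            if gg_correction:
                eps = _gg_epsilon(Y, combo)
                p = float(sps.f.sf(F, df1 * eps, df2 * eps))
            else:
                p = float(sps.f.sf(F, df1, df2))
            rows.append(
                {
                    "effect": _effect_name(names),
                    "F": F,
                    "df1": df1,
                    "df2": df2,
                    "p": p,
                    "eta_p2": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                }
            )
    table = pd.DataFrame(rows).set_index("effect")
    return AnovaResult(table=table)


def _gg_epsilon(Y: np.ndarray, combo: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for one within effect."""
    # collapse to subjects x effect-cells, average over other factors
    other = [a for a in range(1, Y.ndim) if a not in combo]
    Z = Y.mean(axis=tuple(other)) if other else Y
    Z = Z.reshape(Z.shape[0], -1)
    k = Z.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(Z.T, ddof=1)
    mean_diag = np.trace(S) / k
    num = (k * mean_diag - S.mean()) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=0) ** 2)
                     + k**2 * S.mean() ** 2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0)) if den > 0 else 1.0


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta-squared recovered from an F statistic and its dfs."""
    return F * df1 / (F * df1 + df2)


# ---------------------------------------------------------------------------
# Normality screen
# ---------------------------------------------------------------------------

@dataclass
class KSResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def ks_normality(values) -> KSResult:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample
    mean and standard deviation (reporting only, no gating)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError("need at least 5 values for the normality screen")
    sd = x.std(ddof=1)
    if sd == 0:
        return KSResult(statistic=np.nan, pvalue=np.nan, degenerate=True)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return KSResult(statistic=float(stat), pvalue=float(p))


# ---------------------------------------------------------------------------
# Cluster-based permutation inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermConfig:
    n_permutations: int = 10_000
    alpha: float = 0.05
    tail: str = "two-sided"  # 'two-sided', 'greater', 'less'
    cluster_threshold: float | None = None  # parametric critical value if None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tail not in ("two-sided", "greater", "less"):
            raise ValueError(f"unknown tail {self.tail!r}")


@dataclass
class Cluster:
    start: int  # first sample index (inclusive)
    stop: int  # past-the-end sample index
    mass: float  # summed statistic over the run
    p: float
    sign: int = 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.stop)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    n_permutations: int
    tail: str
    exact: bool  # full enumeration of relabelings
    pointwise_stat: np.ndarray
    null_max: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= 0.05]

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def _max_cluster_masses(T: np.ndarray, threshold: float, two_sided: bool) -> np.ndarray:
    """Row-wise maximum cluster mass (absolute) of a statistic matrix.

    Clusters are maximal runs of contiguous samples beyond ``threshold``;
    mass is the summed statistic.  Vectorized across rows by flattening
    with a sentinel column so runs cannot span rows.
    """
    T = np.atleast_2d(T)
    P, K = T.shape

    def _one_sided(vals: np.ndarray) -> np.ndarray:
        mask = vals > threshold
        padded = np.zeros((P, K + 1), dtype=bool)
        padded[:, :K] = mask
        flat = padded.ravel()
        d = np.diff(np.concatenate(([0], flat.astype(np.int8))))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        out = np.zeros(P)
        if starts.size:
            v = np.zeros((P, K + 1))
            v[:, :K] = np.where(mask, vals, 0.0)
            cs = np.concatenate(([0.0], np.cumsum(v.ravel())))
            masses = cs[stops] - cs[starts]
            rows = starts // (K + 1)
            np.maximum.at(out, rows, masses)
        return out

    if two_sided:
        return np.maximum(_one_sided(T), _one_sided(-T))
    return _one_sided(T)


def _cluster_spans(stat: np.ndarray, threshold: float, sign: int) -> list[tuple[int, int, float]]:
    vals = stat if sign > 0 else -stat
    mask = vals > threshold
    spans = []
    i = 0
    K = len(mask)
    while i < K:
        if mask[i]:
            j = i
            while j < K and mask[j]:
                j += 1
            spans.append((i, j, float(vals[i:j].sum()) * sign))
            i = j
        else:
            i += 1
    return spans


def _sign_matrix(n: int, cfg: PermConfig, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    if 2**n <= cfg.n_permutations:
        combos = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        return combos, True
    return rng.choice((1.0, -1.0), size=(cfg.n_permutations, n)), False


def cluster_permutation_ttest(
    diffs: np.ndarray,
    cfg: PermConfig = PermConfig(),
) -> ClusterResult:
    """Cluster permutation test on per-subject condition-difference curves.

    ``diffs`` is ``(n_subjects, n_samples)``: one within-subject paired
    difference profile per subject.  The pointwise statistic is the
    one-sample t over subjects; the null exchanges condition labels within
    subject (sign flips).  Exact (full enumeration) when 2^n does not
    exceed ``n_permutations``; Monte-Carlo with the +1-corrected p
    otherwise.
    """
    D = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, K = D.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(cfg.seed)
    two_sided = cfg.tail == "two-sided"
    if cfg.cluster_threshold is not None:
        thr = cfg.cluster_threshold
    elif two_sided:
        thr = float(sps.t.ppf(1 - cfg.alpha / 2, n - 1))
    else:
        thr = float(sps.t.ppf(1 - cfg.alpha, n - 1))

    ssq = np.sum(D**2, axis=0)  # invariant under sign flips

    def t_stats(signs: np.ndarray) -> np.ndarray:
        m = signs @ D / n
        var = (ssq / n - m**2) * n / (n - 1)
        var = np.clip(var, 1e-300, None)
        return m / np.sqrt(var / n)

    t_obs = t_stats(np.ones((1, n)))[0]
    if cfg.tail == "less":
        spans = _cluster_spans(t_obs, thr, -1)
    elif cfg.tail == "greater":
        spans = _cluster_spans(t_obs, thr, +1)
    else:
        spans = sorted(
            _cluster_spans(t_obs, thr, +1) + _cluster_spans(t_obs, thr, -1)
        )

    signs, exact = _sign_matrix(n, cfg, rng)
    T_null = t_stats(signs)
    if cfg.tail == "less":
        null_max = _max_cluster_masses(-T_null, thr, False)
    else:
        null_max = _max_cluster_masses(T_null, thr, two_sided)

    n_perm = signs.shape[0]
    clusters = []
    for (start, stop, mass) in spans:
        b = int(np.sum(null_max >= abs(mass) - 1e-12))
        p = b / n_perm if exact else (b + 1) / (n_perm + 1)
        clusters.append(Cluster(start, stop, mass, p, sign=1 if mass >= 0 else -1))
    return ClusterResult(
        clusters=clusters,
        threshold=thr,
        n_permutations=n_perm,
        tail=cfg.tail,
        exact=exact,
        pointwise_stat=t_obs,
        null_max=null_max,
    )


def _pointwise_rm_f(X: np.ndarray) -> np.ndarray:
    """One-way repeated-measures F per sample; X is (S, M, K)."""
    S, M, K = X.shape
    g = X.mean(axis=(0, 1))
    L = X.mean(axis=0)  # (M, K) level means
    P = X.mean(axis=1)  # (S, K) subject means
    ss_eff = S * np.sum((L - g) ** 2, axis=0)
    resid = X - L[None, :, :] - P[:, None, :] + g
    ss_err = np.sum(resid**2, axis=(0, 1))
    df1, df2 = M - 1, (S - 1) * (M - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_eff / df1) / np.where(ss_err > 0, ss_err / df2, np.inf)
    return F


def cluster_permutation_ftest(
    data: np.ndarray,
    cfg: PermConfig = PermConfig(),
) -> ClusterResult:
    """Cluster permutation test with a pointwise one-way rm-ANOVA F.

    ``data`` is ``(n_subjects, n_levels, n_samples)``; the null permutes
    the level labels independently within each subject.  F is one-sided by
    nature, so ``cfg.tail`` is ignored here.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 3:
        raise ValueError("data must be (n_subjects, n_levels, n_samples)")
    S, M, K = X.shape
    if S < 2 or M < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    rng = np.random.default_rng(cfg.seed)
    df1, df2 = M - 1, (S - 1) * (M - 1)
    thr = (
        cfg.cluster_threshold
        if cfg.cluster_threshold is not None
        else float(sps.f.ppf(1 - cfg.alpha, df1, df2))
    )
    F_obs = _pointwise_rm_f(X)
    spans = _cluster_spans(F_obs, thr, +1)

    null_max = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        perm = np.argsort(rng.random((S, M)), axis=1)
        Xp = np.take_along_axis(X, perm[:, :, None], axis=1)
        null_max[i] = _max_cluster_masses(_pointwise_rm_f(Xp), thr, False)[0]

    clusters = []
    for (start, stop, mass) in spans:
        b = int(np.sum(null_max >= mass - 1e-12))
        clusters.append(Cluster(start, stop, mass, (b + 1) / (cfg.n_permutations + 1)))
    return ClusterResult(
        clusters=clusters,
        threshold=thr,
        n_permutations=cfg.n_permutations,
        tail="greater",
        exact=False,
        pointwise_stat=F_obs,
        null_max=null_max,
    )


# ---------------------------------------------------------------------------
# Power for the within-subject design
# ---------------------------------------------------------------------------

def rm_anova_power(
    eta_p2: float,
    n_subjects: int,
    n_levels: int = 2,
    corr: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Power (1 - beta) of a repeated-measures ANOVA within-factor effect.

    Follows the standard within-factors convention: the effect size
    f^2 = eta_p2 / (1 - eta_p2) is inflated by the repeated-measures
    correlation ``corr`` (default 0.5), giving noncentrality
    lambda = f^2 * n * m / (1 - corr); power is the noncentral-F upper
    tail beyond the central-F critical value with df1 = m - 1 and
    df2 = (n - 1) * df1.
    """
    if not 0 <= eta_p2 < 1:
        raise ValueError("eta_p2 must lie in [0, 1)")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 <= corr < 1:
        raise ValueError("corr must lie in [0, 1)")
    f2 = eta_p2 / (1.0 - eta_p2)
    df1 = max(n_levels - 1, 1)
    df2 = (n_subjects - 1) * df1
    lam = f2 * n_subjects * n_levels / (1.0 - corr)
    crit = sps.f.ppf(1 - alpha, df1, df2)
    if lam == 0.0:  # ncf is numerically unreliable at zero noncentrality
        return float(sps.f.sf(crit, df1, df2))
    return float(sps.ncf.sf(crit, df1, df2, lam))
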