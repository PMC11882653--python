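"""Species comparisons and habitat-rank inference.

Implements the study-design statistics directly (classical one-way
ANOVA sums of squares, Tukey studentized-range post-hoc with a compact
letter display, product-moment correlation, and a proportional-odds
ordinal regression fitted by maximum likelihood with observed-information
standard errors).  scipy supplies only reference distributions
(F, studentized range, t, normal) and the optimizer; the statistics
themselves are computed here so they can be checked against independent
oracles in the test suite.

No multiple-testing correction is applied across parameter scans — each
core parameter is tested univariately, and callers should interpret the
family of p-values accordingly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

ALPHA = 0.05


# ---------------------------------------------------------------------------
# normality screening


@dataclass(frozen=True)
class ScreenResult:
    shapiro_p: float  # on residuals after the chosen transformation
    transformation: str  # identity | log | sqrt
    shapiro_p_identity: float
    skipped_groups: Tuple[str, ...]  # groups with n < 3, excluded from the test
    warning: Optional[str] = None


def _residuals(groups: Mapping[str, Sequence[float]], min_n: int) -> Tuple[np.ndarray, Tuple[str, ...]]:
    res, skipped = [], []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < min_n:
            skipped.append(str(name))
            continue
        res.append(v - v.mean())
    if not res:
        raise ValueError("no group has enough values for a normality screen")
    return np.concatenate(res), tuple(skipped)


def normality_screen(
    groups: Mapping[str, Sequence[float]], *, alpha: float = ALPHA, min_n: int = 3
) -> ScreenResult:
    """Shapiro–Wilk on pooled within-group residuals, with transform fallback.

    Groups with fewer than ``min_n`` values are skipped (too small to
    inform the test).  If residual normality fails at ``alpha``, a log
    then a sqrt transformation is tried; the first that passes is kept,
    otherwise identity is retained with a warning.
    """
    res, skipped = _residuals(groups, min_n)
    p_id = float(sps.shapiro(res).pvalue)
    if p_id >= alpha:
        return ScreenResult(p_id, "identity", p_id, skipped)

    all_vals = np.concatenate([np.asarray(v, float) for v in groups.values()])
    candidates = []
    if np.all(all_vals > 0):
        candidates.append(("log", np.log))
    if np.all(all_vals >= 0):
        candidates.append(("sqrt", np.sqrt))
    for name, fn in candidates:
        transformed = {k: fn(np.asarray(v, float)) for k, v in groups.items()}
        res_t, _ = _residuals(transformed, min_n)
        p_t = float(sps.shapiro(res_t).pvalue)
        if p_t >= alpha:
            return ScreenResult(p_t, name, p_id, skipped)
    msg = "no transformation restored residual normality; keeping identity"
    warnings.warn(msg, stacklevel=2)
    return ScreenResult(p_id, "identity", p_id, skipped, warning=msg)


TRANSFORMS = {"identity": lambda x: x, "log": np.log, "sqrt": np.sqrt}


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey compact letter display


@dataclass
class AnovaResult:
    parameter: str
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    group_means: Dict[str, float]
    group_n: Dict[str, int]
    transformation: str = "identity"
    shapiro_p: Optional[float] = None
    tukey_letters: Optional[Dict[str, str]] = None


def one_way_anova(
    groups: Mapping[str, Sequence[float]], *, parameter: str = ""
) -> AnovaResult:
    """Classical between/within variance decomposition.

    Zero within-group variance everywhere yields an infinite-F sentinel
    (p = 0) rather than a division error.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs ≥ 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if all(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs ≥ 2 values in at least one group")
    n_i = np.array([len(a) for a in arrays])
    m_i = np.array([a.mean() for a in arrays])
    N = int(n_i.sum())
    grand = float(np.concatenate(arrays).mean())
    ssb = float((n_i * (m_i - grand) ** 2).sum())
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, m_i)))
    dfb = len(names) - 1
    dfw = N - len(names)
    msb = ssb / dfb
    if ssw == 0.0:
        F = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        msw = 0.0
    else:
        msw = ssw / dfw
        F = msb / msw
        p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(
        parameter=parameter,
        F=F,
        df_between=dfb,
        df_within=dfw,
        p=p,
        ms_within=msw,
        group_means={k: float(m) for k, m in zip(names, m_i)},
        group_n={k: int(n) for k, n in zip(names, n_i)},
    )


@dataclass(frozen=True)
class TukeyResult:
    pairwise_p: Dict[Tuple[str, str], float]
    letters: Dict[str, str]


def tukey_pairwise(
    groups: Mapping[str, Sequence[float]], anova: Optional[AnovaResult] = None
) -> Dict[Tuple[str, str], float]:
    """Tukey–Kramer studentized-range p-values for every group pair."""
    if anova is None:
        anova = one_way_anova(groups)
    names = list(groups)
    k, dfw, msw = len(names), anova.df_within, anova.ms_within
    out: Dict[Tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = math.sqrt(msw / 2.0 * (1.0 / anova.group_n[a] + 1.0 / anova.group_n[b]))
            if se == 0.0:
                q = math.inf if anova.group_means[a] != anova.group_means[b] else 0.0
            else:
                q = abs(anova.group_means[a] - anova.group_means[b]) / se
            p = float(sps.studentized_range.sf(q, k, dfw)) if math.isfinite(q) else 0.0
            out[(a, b)] = p
    return out


def compact_letter_display(
    names: Sequence[str],
    means: Mapping[str, float],
    pairwise_p: Mapping[Tuple[str, str], float],
    *,
    alpha: float = ALPHA,
) -> Dict[str, str]:
    """Insert-and-absorb letter assignment.

    Starting from one letter covering all groups, every significant pair
    splits the letters containing both members; letters that become
    subsets of others are absorbed.  The result satisfies the defining
    property: two groups share a letter iff they are not significantly
    different at ``alpha``.
    """
    order = sorted(names, key=lambda n: means[n])
    letters: List[set] = [set(order)]
    sig = [(a, b) for (a, b), p in pairwise_p.items() if p < alpha]
    for a, b in sig:
        for s in [s for s in letters if a in s and b in s]:
            letters.remove(s)
            letters.extend([s - {a}, s - {b}])
        # absorb: drop letters contained in another
        letters = [
            s
            for i, s in enumerate(letters)
            if s and not any(s < t or (s == t and i > j) for j, t in enumerate(letters))
        ]
    # stable label assignment: letters ordered by the smallest member mean
    letters.sort(key=lambda s: min(order.index(n) for n in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: Dict[str, str] = {n: "" for n in names}
    for idx, s in enumerate(letters):
        ch = alphabet[idx % len(alphabet)]
        for n in order:
            if n in s:
                assigned[n] += ch
    return assigned


def tukey_cld(
    groups: Mapping[str, Sequence[float]],
    anova: Optional[AnovaResult] = None,
    *,
    alpha: float = ALPHA,
) -> TukeyResult:
    if anova is None:
        anova = one_way_anova(groups)
    pw = tukey_pairwise(groups, anova)
    letters = compact_letter_display(list(groups), anova.group_means, pw, alpha=alpha)
    return TukeyResult(pairwise_p=pw, letters=letters)


# ---------------------------------------------------------------------------
# correlation


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    df: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t test on n − 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson needs two equal-length vectors with n ≥ 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    xc, yc = x - x.mean(), y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float(xc @ yc) / (sx * sy)
    df = len(x) - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=float(np.sign(r)), p=0.0, df=df)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, df=df)


# ---------------------------------------------------------------------------
# proportional-odds ordinal regression


@dataclass
class OrdinalFit:
    predictor: str
    beta: float
    se_beta: float
    t: float
    p: float
    zeta: Tuple[float, ...]
    converged: bool
    loglik: float
    n: int

    def __post_init__(self) -> None:
        for a, b in zip(self.zeta, self.zeta[1:]):
            if not b > a:
                raise ValueError("zeta thresholds must be strictly increasing")


_BETA_CAP = 50.0  # |β·sd(x)| beyond this is treated as separation


def _polr_nll(params: np.ndarray, x: np.ndarray, y: np.ndarray, J: int) -> float:
    # params: beta, zeta_1, log-increments — enforces zeta monotonicity
    beta = params[0]
    zeta = np.concatenate([[params[1]], params[1] + np.cumsum(np.exp(params[2:]))])
    eta = beta * x
    # cumulative logits; z_0 = -inf, z_J = +inf
    upper = np.where(y < J, zeta[np.minimum(y, J - 1) - 1] - eta, np.inf)
    lower = np.where(y > 1, zeta[np.maximum(y - 2, 0)] - eta, -np.inf)
    with np.errstate(over="ignore"):
        prob = sps.logistic.cdf(upper) - sps.logistic.cdf(lower)
    prob = np.clip(prob, 1e-300, 1.0)
    return -float(np.log(prob).sum())


def _numeric_hessian(fn, x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                fn(x0 + ei + ej) - fn(x0 + ei - ej) - fn(x0 - ei + ej) + fn(x0 - ei - ej)
            ) / (4 * h * h)
    return H


def fit_proportional_odds(
    rank: Sequence[int], x: Sequence[float], *, predictor: str = "x"
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit of an ordinal response.

    Model: P(Y ≤ j | x) = logistic(ζ_j − βx) with ordered thresholds ζ
    (so a positive β moves probability mass toward higher categories).
    Thresholds are parameterized as a base plus log-increments, keeping
    them ordered throughout optimization.  Standard errors come from the
    inverse observed information (numerical Hessian of the negative
    log-likelihood in the natural β/ζ parameterization) at the optimum.
    Complete separation is flagged (``converged=False``) with |β| capped,
    never returned as a silent finite number.
    """
    y_raw = np.asarray(rank)
    x = np.asarray(x, dtype=float)
    if len(y_raw) != len(x):
        raise ValueError("rank and x must have equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite predictor values")
    cats = np.unique(y_raw)
    if len(cats) < 2:
        raise ValueError("ordinal fit needs ≥ 2 observed categories")
    # recode observed categories to 1..J
    y = np.searchsorted(cats, y_raw) + 1
    J = len(cats)
    n = len(y)

    x_sd = float(x.std()) or 1.0
    # start at β = 0 with zeta at the empirical cumulative logits
    cum = np.cumsum([np.mean(y == j) for j in range(1, J)])
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    z0 = np.log(cum / (1 - cum))
    z0 = np.maximum.accumulate(z0 + np.arange(J - 1) * 1e-6)
    incr = np.diff(z0)
    p0 = np.concatenate([[0.0], [z0[0]], np.log(np.maximum(incr, 1e-3))])

    res = optimize.minimize(
        _polr_nll, p0, args=(x, y, J), method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    beta = float(res.x[0])
    zeta = np.concatenate([[res.x[1]], res.x[1] + np.cumsum(np.exp(res.x[2:]))])
    loglik = -float(res.fun)

    separated = abs(beta) * x_sd > _BETA_CAP
    converged = bool(res.success) and not separated
    if separated:
        warnings.warn(
            f"{predictor}: apparent complete separation (|β|·sd(x) > {_BETA_CAP}); "
            "estimate capped and flagged non-converged",
            stacklevel=2,
        )
        beta = math.copysign(_BETA_CAP / x_sd, beta)

    # observed information in the natural (beta, zeta) parameterization
    def nll_nat(params: np.ndarray) -> float:
        b, z = params[0], np.asarray(params[1:])
        eta = b * x
        upper = np.where(y < J, z[np.minimum(y, J - 1) - 1] - eta, np.inf)
        lower = np.where(y > 1, z[np.maximum(y - 2, 0)] - eta, -np.inf)
        with np.errstate(over="ignore"):
            prob = sps.logistic.cdf(upper) - sps.logistic.cdf(lower)
        return -float(np.log(np.clip(prob, 1e-300, 1.0)).sum())

    theta = np.concatenate([[beta], zeta])
    se = math.nan
    try:
        H = _numeric_hessian(nll_nat, theta)
        cov = np.linalg.inv(H)
        if cov[0, 0] > 0:
            se = math.sqrt(cov[0, 0])
    except np.linalg.LinAlgError:
        converged = False
    t = beta / se if se and math.isfinite(se) and se > 0 else math.nan
    p = 2.0 * float(sps.norm.sf(abs(t))) if math.isfinite(t) else math.nan
    return OrdinalFit(
        predictor=predictor,
        beta=beta,
        se_beta=se,
        t=t,
        p=p,
        zeta=tuple(float(z) for z in zeta),
        converged=converged,
        loglik=loglik,
        n=n,
    )


#: Core parameters scanned against habitat rank, in reporting order.
SCAN_PARAMETERS = (
    "max_wc_mm",
    "min_wc_mm",
    "opt_wc_mm",
    "lcp",
    "lsp",
    "max_np",
    "dr_max",
    "cge",
    "chl_a",
)


def habitat_association_scan(
    core_params: pd.DataFrame,
    ranks: Mapping[str, int],
    *,
    parameters: Sequence[str] = SCAN_PARAMETERS,
    species_means: bool = False,
) -> List[OrdinalFit]:
    """Univariate proportional-odds fits of habitat rank on each parameter.

    Per-sample rows inherit their species' rank (the default, matching a
    per-replicate design); ``species_means`` collapses to one row per
    species first (sensitivity mode).  Results are sorted by |t|,
    largest first.  Parameters that are entirely missing are skipped.
    """
    df = core_params.copy()
    missing = set(df["species_code"]) - set(ranks)
    if missing:
        raise ValueError(f"no habitat rank for species {sorted(missing)}")
    df["rank"] = df["species_code"].map(ranks)
    if species_means:
        numeric = [p for p in parameters if p in df.columns]
        for p in numeric:
            df[p] = pd.to_numeric(df[p], errors="coerce")
        df = df.groupby("species_code", as_index=False)[["rank", *numeric]].mean()
    fits: List[OrdinalFit] = []
    for param in parameters:
        if param not in df.columns:
            continue
        sub = df[["rank", param]].copy()
        sub[param] = pd.to_numeric(sub[param], errors="coerce")
        sub = sub.dropna()
        sub = sub[np.isfinite(sub[param])]  # e.g. infinite CGE when DR ~ 0
        if len(sub) < 3 or sub[param].nunique() < 2:
            continue
        fits.append(
            fit_proportional_odds(
                sub["rank"].astype(int).to_numpy(),
                sub[param].to_numpy(),
                predictor=param,
            )
        )
    fits.sort(key=lambda f: -abs(f.t) if math.isfinite(f.t) else math.inf)
    return fits


# ---------------------------------------------------------------------------
# published-summary utilities


def reconstruct_group(mean: float, sd: float, n: int) -> np.ndarray:
    """Smallest symmetric sample with exactly the given mean and sample SD.

    Uses equally spaced points rescaled to the target SD (n = 3 gives
    {m − s, m, m + s}; n = 2 gives m ± s/√2).  Useful for recomputing
    moment-based statistics from published group summaries.
    """
    if n < 2:
        return np.array([mean])
    base = np.arange(n, dtype=float) - (n - 1) / 2.0
    base /= base.std(ddof=1)
    return mean + sd * base


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int], *, parameter: str = ""
) -> AnovaResult:
    """One-way ANOVA computed exactly from group means, SDs and sizes."""
    groups = {
        f"g{i}": reconstruct_group(m, s, n)
        for i, (m, s, n) in enumerate(zip(means, sds, ns))
    }
    return one_way_anova(groups, parameter=parameter)
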