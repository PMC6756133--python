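"""Psychometric fitting and the permutation-statistics battery.

Covers the inferential toolkit of an envelope-tracking study:

* logistic psychometric fits yielding the speech reception threshold (SRT)
  and slope, with optional free guess/lapse rates for fitting tracking
  correlations instead of word scores,
* 1-D k-means binning of the tested SNRs,
* comparison of two dependent overlapping correlations (Hittner's
  back-transformed-average Fisher-z test),
* per-SNR paired sign-flip permutation tests with Holm-Bonferroni
  correction,
* the Brown-Forsythe variance-homogeneity test,
* cluster-based permutation testing of TRF differences over channels and
  lags (sign-flip null, cluster-mass statistic, channel adjacency graph).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PsychometricFit",
    "fit_psychometric",
    "logistic_psychometric",
    "bin_snrs",
    "compare_dependent_correlations",
    "paired_permutation_by_snr",
    "holm_bonferroni",
    "brown_forsythe",
    "Cluster",
    "ClusterResult",
    "cluster_permutation",
]


# ---------------------------------------------------------------------------
# Psychometric function
# ---------------------------------------------------------------------------

def logistic_psychometric(snr, alpha, beta, guess=0.0, lapse=0.0):
    """``guess + (1 - guess - lapse) / (1 + exp(-(snr - alpha) / beta))``."""
    from scipy.special import expit

    snr = np.asarray(snr, dtype=float)
    return guess + (1.0 - guess - lapse) * expit((snr - alpha) / beta)


@dataclass
class PsychometricFit:
    """Fitted psychometric parameters.

    ``alpha`` is the SRT (dB SNR, midpoint of the logistic), ``beta`` the
    spread (dB).  The reported slope is the derivative at the midpoint,
    ``100 * (1 - guess - lapse) / (4 * beta)`` in %/dB.
    """

    alpha: float
    beta: float
    guess: float = 0.0
    lapse: float = 0.0
    fit_ok: bool = True
    message: str = ""
    ci: tuple | None = None

    @property
    def slope_pct_per_db(self) -> float:
        return 100.0 * (1.0 - self.guess - self.lapse) / (4.0 * self.beta)

    def predict(self, snr):
        return logistic_psychometric(snr, self.alpha, self.beta,
                                     self.guess, self.lapse)


def _nll_binomial(params, snrs, k, n, fix_rates):
    if fix_rates:
        alpha, beta = params
        guess = lapse = 0.0
    else:
        alpha, beta, guess, lapse = params
    p = logistic_psychometric(snrs, alpha, beta, guess, lapse)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def _sse(params, snrs, scores, fix_rates):
    if fix_rates:
        alpha, beta = params
        guess = lapse = 0.0
    else:
        alpha, beta, guess, lapse = params
    resid = scores - logistic_psychometric(snrs, alpha, beta, guess, lapse)
    return float(resid @ resid)


def fit_psychometric(snrs, scores, fix_rates: bool = True,
                     n_trials=None) -> PsychometricFit:
    """Fit the logistic psychometric function.

    Parameters
    ----------
    snrs, scores : array-like
        SNRs in dB and proportions in [0, 1] (word scores, or tracking
        correlations in neural mode).
    fix_rates : bool
        True pins guess = lapse = 0 (behavioral word scores, two free
        parameters); False frees both rates, which lets the asymptotes
        absorb the floor and ceiling of neural-tracking data.
    n_trials : int or array-like, optional
        Words per SNR.  When given, a binomial maximum-likelihood fit is
        used; otherwise least squares.

    Non-convergence is reported through ``fit_ok=False``, never silently.
    """
    snrs = np.asarray(snrs, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if snrs.shape != scores.shape:
        raise ValueError("snrs and scores must have the same shape")
    n_params = 2 if fix_rates else 4
    if np.unique(snrs).size < n_params:
        raise ValueError(
            f"need >= {n_params} distinct SNRs to fit {n_params} parameters")

    # Moderate starting values: midpoint from interpolation, unit spread.
    order = np.argsort(snrs)
    lo_score, hi_score = scores.min(), scores.max()
    mid = 0.5 * (lo_score + hi_score)
    alpha0 = float(np.interp(mid, scores[order], snrs[order]))
    span = max(np.ptp(snrs), 1.0)
    x0s = [(alpha0, b0) for b0 in (0.5, 1.0, 2.0, span / 4)]

    if n_trials is not None:
        n = np.broadcast_to(np.asarray(n_trials), snrs.shape).astype(float)
        k = scores * n
        obj, args = _nll_binomial, (snrs, k, n, fix_rates)
    else:
        obj, args = _sse, (snrs, scores, fix_rates)

    bounds = [(snrs.min() - 2 * span, snrs.max() + 2 * span), (1e-3, 10 * span)]
    if not fix_rates:
        bounds += [(0.0, 0.5), (0.0, 0.5)]
        x0s = [x0 + (max(lo_score, 0.0), max(1 - hi_score, 0.0))
               for x0 in x0s]

    best = None
    for x0 in x0s:
        res = optimize.minimize(obj, x0, args=args, bounds=bounds,
                                method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    params = best.x
    guess, lapse = (0.0, 0.0) if fix_rates else (params[2], params[3])
    ok = bool(best.success and params[1] > 1.5e-3 and guess + lapse < 1.0)
    return PsychometricFit(alpha=float(params[0]), beta=float(params[1]),
                           guess=float(guess), lapse=float(lapse),
                           fit_ok=ok, message=str(best.message))


# ---------------------------------------------------------------------------
# SNR binning
# ---------------------------------------------------------------------------

def bin_snrs(snr_values, k: int = 7, seed: int = 0):
    """Cluster 1-D SNR values with k-means.

    Returns ``(labels, centers)`` with cluster labels renumbered so centers
    are in ascending order.  Deterministic under ``seed``.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(snr_values, dtype=float).reshape(-1, 1)
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct values")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[km.labels_], km.cluster_centers_.ravel()[order]


# ---------------------------------------------------------------------------
# Dependent correlations
# ---------------------------------------------------------------------------

def compare_dependent_correlations(r_a: float, r_b: float, r_ab: float,
                                   n: int) -> float:
    """Two-sided p for equality of two dependent overlapping correlations.

    ``r_a = cor(x, y)`` and ``r_b = cor(x, z)`` share the variable ``x``;
    ``r_ab = cor(y, z)`` is the correlation between the non-shared
    variables.  Uses Hittner's modification of Dunn and Clark's z with the
    back-transformed average of the two Fisher-z values.
    """
    for r in (r_a, r_b, r_ab):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z_a, z_b = np.arctanh(r_a), np.arctanh(r_b)
    r_mean = np.tanh(0.5 * (z_a + z_b))  # back-transformed average
    num = r_ab * (1 - 2 * r_mean ** 2) - 0.5 * r_mean ** 2 * (
        1 - 2 * r_mean ** 2 - r_ab ** 2)
    cov = num / (1 - r_mean ** 2) ** 2
    z = (z_a - z_b) * np.sqrt((n - 3) / (2.0 * (1 - cov)))
    return float(2 * sstats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Paired permutation tests
# ---------------------------------------------------------------------------

def holm_bonferroni(p_values):
    """Step-down Holm adjustment (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="holm")[1]


def _signflip_pvalue(diff, n_perm, rng, statistic="mean"):
    diff = np.asarray(diff, dtype=float)
    n = diff.size

    def stat(d):
        if statistic == "mean":
            return d.mean(axis=-1)
        sd = d.std(axis=-1, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return d.mean(axis=-1) / (sd / np.sqrt(n))

    obs = stat(diff)
    if 2 ** n <= n_perm:
        bits = np.arange(2 ** n)
        signs = 1 - 2.0 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        null = stat(signs * diff[None, :])
        # exact enumeration: include all sign assignments (identity included)
        return float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = stat(signs * diff[None, :])
    return float((1 + np.sum(np.abs(null) >= abs(obs) - 1e-12))
                 / (1 + n_perm))


def paired_permutation_by_snr(x: dict, y: dict, n_perm: int = 10000,
                              seed: int = 0, statistic: str = "mean") -> dict:
    """Per-SNR-bin paired sign-flip permutation tests, Holm-corrected.

    ``x`` and ``y`` map bin identifiers to equally sized per-subject value
    arrays (paired by position).  The test statistic is the mean paired
    difference (``statistic="t"`` selects the paired t-value instead); the
    null is generated by random sign flips of the differences, or by exact
    enumeration when ``2 ** n_subjects <= n_perm``.  Returns a dict mapping
    each bin to its Holm-adjusted two-sided p-value.
    """
    if set(x) != set(y):
        raise ValueError("x and y must cover the same bins")
    bins = list(x)
    rng = np.random.default_rng(seed)
    raw = []
    for b in bins:
        xa, ya = np.asarray(x[b], float), np.asarray(y[b], float)
        if xa.shape != ya.shape:
            raise ValueError(f"bin {b!r}: unpaired data")
        raw.append(_signflip_pvalue(xa - ya, n_perm, rng, statistic))
    adj = holm_bonferroni(raw)
    return dict(zip(bins, adj.tolist()))


def brown_forsythe(*groups):
    """Brown-Forsythe variance-homogeneity test.

    A Levene-type one-way ANOVA on absolute deviations from the group
    medians.  Degenerate input with zero spread everywhere returns
    (0.0, 1.0) rather than failing.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least two values")
    devs = [np.abs(np.asarray(g, float) - np.median(g)) for g in groups]
    if all(np.ptp(d) == 0 for d in devs) and \
            np.ptp([d.mean() for d in devs]) == 0:
        return 0.0, 1.0
    stat, p = sstats.levene(*groups, center="median")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Cluster-based permutation test over channels x lags
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    channels: list
    lag_range_ms: tuple
    mass: float
    p_value: float
    members: list = field(default_factory=list)  # (channel index, lag index)


@dataclass
class ClusterResult:
    clusters: list
    alpha_level: float
    t_crit: float
    n_perm: int

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c.p_value <= alpha]


def _neighbor_lists(labels, adjacency):
    idx = {lbl: i for i, lbl in enumerate(labels)}
    nbrs = [[] for _ in labels]
    if adjacency:
        for a, conn in adjacency.items():
            if a not in idx:
                continue
            for b in conn:
                if b in idx:
                    nbrs[idx[a]].append(idx[b])
    return nbrs


def _max_cluster_masses(t, supra, nbrs):
    """Cluster supra-threshold cells (adjacent channels at the same lag,
    adjacent lags in the same channel); returns list of (mass, members)."""
    n_ch, n_lag = t.shape
    visited = np.zeros_like(supra, dtype=bool)
    clusters = []
    sign = np.sign(t)
    coords = np.argwhere(supra)
    for c0, l0 in coords:
        if visited[c0, l0]:
            continue
        s = sign[c0, l0]
        stack = [(c0, l0)]
        visited[c0, l0] = True
        members = []
        mass = 0.0
        while stack:
            c, l = stack.pop()
            members.append((c, l))
            mass += t[c, l]
            for l2 in (l - 1, l + 1):
                if 0 <= l2 < n_lag and supra[c, l2] and not visited[c, l2] \
                        and sign[c, l2] == s:
                    visited[c, l2] = True
                    stack.append((c, l2))
            for c2 in nbrs[c]:
                if supra[c2, l] and not visited[c2, l] and sign[c2, l] == s:
                    visited[c2, l] = True
                    stack.append((c2, l))
        clusters.append((mass, members))
    return clusters


def cluster_permutation(trf_a, trf_b, adjacency: dict = None,
                        cluster_alpha: float = 0.05, n_perm: int = 5000,
                        seed: int = 0, labels=None,
                        lag_ms=None) -> ClusterResult:
    """Cluster-based permutation test of paired TRF differences.

    ``trf_a`` and ``trf_b`` are paired per-subject TRF sets: lists of
    :class:`~envtrack.linear_model.ForwardTRF` or arrays of shape
    (n_subjects, n_channels, n_lags).  A paired t-value is computed for
    every (channel, lag) cell; cells with ``|t|`` above the two-sided
    t-quantile at ``cluster_alpha`` are clustered under channel adjacency
    and lag contiguity (same-sign cells only); each cluster's mass is its
    summed t.  The null distribution of the maximum absolute cluster mass
    is built from random subject-level sign flips of the differences, and
    each observed cluster's p-value is the fraction of permutations whose
    maximum mass is at least as large.

    With ``adjacency=None`` or an empty graph, clustering degenerates to
    per-channel runs along the lag axis.
    """
    a, labels, lag_ms = _coerce_trfs(trf_a, labels, lag_ms)
    b, _, _ = _coerce_trfs(trf_b, labels, lag_ms)
    if a.shape != b.shape:
        raise ValueError("TRF sets must have identical shape")
    n_subj = a.shape[0]
    if n_subj < 5:
        raise ValueError("fewer than 5 subjects: permutation null too coarse")
    d = a - b  # (S, C, L)
    n_ch, n_lag = d.shape[1], d.shape[2]
    sumsq = np.sum(d ** 2, axis=0)
    t_crit = float(sstats.t.ppf(1 - cluster_alpha / 2, n_subj - 1))
    nbrs = _neighbor_lists(labels, adjacency or {})

    def t_grid(mean, sumsq):
        var = (sumsq - n_subj * mean ** 2) / (n_subj - 1)
        sd = np.sqrt(np.maximum(var, 0.0))
        sd[sd == 0] = np.inf
        return mean / (sd / np.sqrt(n_subj))

    t_obs = t_grid(d.mean(axis=0), sumsq)
    obs_clusters = _max_cluster_masses(t_obs, np.abs(t_obs) > t_crit, nbrs)

    rng = np.random.default_rng(seed)
    flat = d.reshape(n_subj, -1)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        mean_p = (signs @ flat).reshape(n_ch, n_lag) / n_subj
        t_p = t_grid(mean_p, sumsq)
        perm_clusters = _max_cluster_masses(t_p, np.abs(t_p) > t_crit, nbrs)
        if perm_clusters:
            null_max[i] = max(abs(m) for m, _ in perm_clusters)

    clusters = []
    for mass, members in obs_clusters:
        p = float((1 + np.sum(null_max >= abs(mass) - 1e-12)) / (1 + n_perm))
        chans = sorted({labels[c] for c, _ in members}) if labels else \
            sorted({c for c, _ in members})
        lags = [lag_ms[l] for _, l in members]
        clusters.append(Cluster(channels=chans,
                                lag_range_ms=(float(min(lags)),
                                              float(max(lags))),
                                mass=float(mass), p_value=p,
                                members=members))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(clusters=clusters, alpha_level=cluster_alpha,
                         t_crit=t_crit, n_perm=n_perm)


def _coerce_trfs(trfs, labels, lag_ms):
    from .linear_model import ForwardTRF

    if isinstance(trfs, np.ndarray):
        arr = trfs.astype(float)
        if labels is None:
            labels = [str(i) for i in range(arr.shape[1])]
        if lag_ms is None:
            lag_ms = np.arange(arr.shape[2], dtype=float)
        return arr, list(labels), np.asarray(lag_ms, float)
    if all(isinstance(t, ForwardTRF) for t in trfs):
        arr = np.stack([t.kernel for t in trfs])
        return arr, list(trfs[0].labels), np.asarray(trfs[0].lag_ms, float)
    arr = np.stack([np.asarray(t, float) for t in trfs])
    if labels is None:
        labels = [str(i) for i in range(arr.shape[1])]
    if lag_ms is None:
        lag_ms = np.arange(arr.shape[2], dtype=float)
    return arr, list(labels), np.asarray(lag_ms, float)
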