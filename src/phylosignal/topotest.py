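"""Topology tests on site log-likelihood matrices: RELL bootstrap, KH test,
and the approximately-unbiased (AU) test via multiscale bootstrap.

The AU test resamples site log-likelihoods (RELL) at several replicate sizes
``n' = r * n`` for scale factors ``r`` around 1, records each candidate's
bootstrap proportion ``bp(r)``, and fits the probit model

    Phi^-1(1 - bp(r)) = d * sqrt(r) + c / sqrt(r)

by weighted least squares (weights from the binomial variance of bp through
the delta method). ``d`` estimates the signed distance of the data from the
region where the candidate is optimal and ``c`` the boundary curvature; the
AU p-value is ``1 - Phi(d - c)``. A one-sided KH p-value per candidate comes
from the same scale-1 replicates by centering the replicate log-likelihood
differences against the maximum-likelihood candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .likelihood import SiteLnLMatrix

logger = logging.getLogger(__name__)

DEFAULT_SCALES: tuple[float, ...] = (
    0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4
)
DEFAULT_N_REPS = 10_000


# -- RELL machinery ---------------------------------------------------------

def rell_scores(
    site_lnl: np.ndarray,
    scale_factor: float,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicate log-likelihood sums, shape (n_reps, n_trees).

    Each replicate draws ``round(scale_factor * n_sites)`` sites with
    replacement (multinomial weights) and sums the weighted site lnL of
    every candidate.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    n_sites = site_lnl.shape[1]
    n_draw = max(1, int(round(scale_factor * n_sites)))
    out = np.empty((n_reps, site_lnl.shape[0]))
    chunk = max(1, 4_000_000 // n_draw)  # bound the index buffer
    offsets = np.arange(chunk)[:, None] * n_sites
    for start in range(0, n_reps, chunk):
        c = min(chunk, n_reps - start)
        idx = rng.integers(0, n_sites, size=(c, n_draw))
        flat = np.bincount(
            (offsets[:c] + idx).ravel(), minlength=c * n_sites
        )
        counts = flat.reshape(c, n_sites).astype(float)
        out[start:start + c] = counts @ site_lnl.T
    return out


def _winners(scores: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Argmax per replicate with uniform random tie-breaking."""
    best = scores.max(axis=1, keepdims=True)
    is_max = scores == best
    winners = np.argmax(is_max, axis=1)
    tied = is_max.sum(axis=1) > 1
    for r in np.flatnonzero(tied):
        winners[r] = rng.choice(np.flatnonzero(is_max[r]))
    return winners


def rell_replicates(
    matrix: SiteLnLMatrix,
    scale_factor: float = 1.0,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> dict[str, int]:
    """Winner counts per candidate over RELL replicates at one scale."""
    rng = np.random.default_rng(seed)
    scores = rell_scores(matrix.site_lnl, scale_factor, n_reps, rng)
    winners = _winners(scores, rng)
    counts = np.bincount(winners, minlength=matrix.n_trees)
    return dict(zip(matrix.tree_ids, counts.tolist()))


# -- AU / KH ----------------------------------------------------------------

@dataclass
class AUResult:
    tree_id: str
    total_lnl: float
    p_au: float
    p_kh: float
    bp: dict[float, float] = field(default_factory=dict)
    d_hat: float = np.nan
    c_hat: float = np.nan
    n_replicates_per_scale: int = 0


@dataclass
class ConfidenceSet:
    alpha: float
    members: list[str]
    ml_tree_id: str

    def __contains__(self, tree_id: str) -> bool:
        return tree_id in self.members


def _fit_probit_wls(scales: np.ndarray, bp: np.ndarray,
                    n_reps: int) -> tuple[float, float]:
    """WLS fit of Phi^-1(1-bp) = d*sqrt(r) + c/sqrt(r); returns (d, c)."""
    eps = 1.0 / (2.0 * n_reps)
    bp_c = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp_c)
    w = n_reps * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    return float(coef[0]), float(coef[1])


def _fit_probit(scales: np.ndarray, bp: np.ndarray,
                n_reps: int) -> tuple[float, float]:
    """Fit bp(r) = Phi(-(d*sqrt(r) + c/sqrt(r))) to replicate counts.

    Maximum likelihood on the binomial counts (Newton steps via scipy),
    initialized at the closed-form WLS estimate on the probit scale. The
    likelihood fit is markedly more stable than pure WLS when bootstrap
    proportions sit close to 0.5 at every scale.
    """
    from scipy.optimize import minimize as _minimize

    d0, c0 = _fit_probit_wls(scales, bp, n_reps)
    k = np.round(bp * n_reps)
    sq = np.sqrt(scales)

    def nll(theta):
        eta = theta[0] * sq + theta[1] / sq
        p = np.clip(norm.cdf(-eta), 1e-12, 1.0 - 1e-12)
        return -(k * np.log(p) + (n_reps - k) * np.log1p(-p)).sum()

    res = _minimize(nll, np.array([d0, c0]), method="BFGS")
    d, c = (res.x if res.success or np.isfinite(res.fun) else (d0, c0))
    return float(d), float(c)


def kh_pvalue_normal(row_i: np.ndarray, row_j: np.ndarray) -> float:
    """One-sided KH p-value for tree i against tree j, normal approximation.

    Tests H0: E[lnL_i - lnL_j] = 0 against tree i being worse; small values
    reject tree i.
    """
    diff = row_i - row_j
    n = diff.size
    sd = float(np.sqrt(n * diff.var(ddof=1)))
    if sd == 0:
        return 0.5
    return float(norm.cdf(diff.sum() / sd))


def au_test(
    matrix: SiteLnLMatrix,
    scales=DEFAULT_SCALES,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> list[AUResult]:
    """Approximately-unbiased and KH p-values for every candidate tree."""
    scales = np.asarray(sorted(set(float(s) for s in scales)))
    if (scales <= 0).any():
        raise ValueError("scales must be positive")
    totals = matrix.total_lnl()
    k = matrix.n_trees
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scales) + 1)

    bp_table = np.zeros((len(scales), k))
    scale1_scores = None
    for s_idx, r in enumerate(scales):
        rng = np.random.default_rng(children[s_idx])
        scores = rell_scores(matrix.site_lnl, r, n_reps, rng)
        winners = _winners(scores, rng)
        bp_table[s_idx] = np.bincount(winners, minlength=k) / n_reps
        if np.isclose(r, 1.0):
            scale1_scores = scores
    if scale1_scores is None:
        rng = np.random.default_rng(children[-1])
        scale1_scores = rell_scores(matrix.site_lnl, 1.0, n_reps, rng)

    # KH: each tree against the ML tree (the ML tree against the runner-up)
    ml_idx = int(np.argmax(totals))
    order = np.argsort(totals)[::-1]
    runner_up = int(order[1]) if k > 1 else ml_idx
    p_kh = np.ones(k)
    for i in range(k):
        j = ml_idx if i != ml_idx else runner_up
        if i == j:
            continue
        d_obs = totals[i] - totals[j]
        reps = scale1_scores[:, i] - scale1_scores[:, j]
        p_kh[i] = float(np.mean(reps - reps.mean() <= d_obs))

    # drop scales where every candidate's bp is degenerate
    degenerate = ((bp_table == 0.0) | (bp_table == 1.0)).all(axis=1)
    usable = ~degenerate
    results = []
    for i, tid in enumerate(matrix.tree_ids):
        bp_i = bp_table[:, i]
        if usable.sum() >= 2 and not ((bp_i == 0.0) | (bp_i == 1.0)).all():
            d, c = _fit_probit(scales[usable], bp_i[usable], n_reps)
            p_au = float(1.0 - norm.cdf(d - c))
        else:
            p_au = 1.0 if bp_i.mean() > 0.5 else 0.0
            d = c = np.nan
            logger.warning(
                "degenerate bootstrap proportions for %s; p_au clamped to %g",
                tid, p_au,
            )
        results.append(AUResult(
            tree_id=tid,
            total_lnl=float(totals[i]),
            p_au=min(max(p_au, 0.0), 1.0),
            p_kh=float(p_kh[i]),
            bp=dict(zip(scales.tolist(), bp_i.tolist())),
            d_hat=d,
            c_hat=c,
            n_replicates_per_scale=n_reps,
        ))
    return results


def confidence_set(results: list[AUResult], alpha: float = 0.05) -> ConfidenceSet:
    """Candidates with p_au >= alpha; the ML tree is always a member."""
    if not results:
        raise ValueError("no AU results supplied")
    ml = max(results, key=lambda r: r.total_lnl)
    members = [r.tree_id for r in results if r.p_au >= alpha or r is ml]
    return ConfidenceSet(alpha=alpha, members=members, ml_tree_id=ml.tree_id)


def write_au_table(results: list[AUResult], cset: ConfidenceSet, path) -> None:
    """TSV with one row per candidate: lnL, p_KH, p_AU, membership."""
    lines = ["tree_id\tlnL_total\tp_KH\tp_AU\tin_confidence_set"]
    for r in sorted(results, key=lambda x: -x.total_lnl):
        lines.append(
            f"{r.tree_id}\t{r.total_lnl:.6f}\t{r.p_kh:.6g}\t{r.p_au:.6g}"
            f"\t{int(r.tree_id in cset)}"
        )
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
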