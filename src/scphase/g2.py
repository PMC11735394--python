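"""G2-phase identification from total read counts per clone.

With tagmentation-style library preparation, total read counts scale with
DNA content, so G2 cells yield roughly twice the reads of G0/G1 cells of the
same clone.  The total counts of a clone's non-S cells are deconvolved with
a two-component negative-binomial mixture whose G2 mean is constrained to
exceed both the G0/G1 mean and the mean count of the clone's S-phase cells
(a cell finishing S phase cannot carry less DNA than one inside it).

The estimator is sampling-importance-resampling over (mu, means,
dispersions) under the constraint, followed by constrained EM refinement
from the resampled mode.  A mixture that does not beat the single-component
fit by the BIC margin collapses to mu = 0 (everyone G0/G1).  Per-cell
posteriors use the fitted likelihoods with a uniform class prior; a cell is
G2 when its probability of being G0/G1 falls strictly below the threshold
(0.3 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import nbinom

#: default posterior threshold: G2 iff P(G0/G1) < threshold
G2_THRESHOLD = 0.3
#: minimum non-S cells for a per-clone fit; smaller clones use a pooled fit
MIN_CELLS_PER_FIT = 30


@dataclass
class G2MixtureFit:
    clone_id: object
    mu: float  # G2 fraction
    mean_g1: float
    disp_g1: float
    mean_g2: float
    disp_g2: float
    p_g0g1: np.ndarray  # per-cell posterior of being G0/G1 (uniform prior)
    loglik: float
    single_loglik: float
    flags: dict = field(default_factory=dict)


def _nb_logpmf(x: np.ndarray, mean: float, disp: float) -> np.ndarray:
    """NB log pmf with mean/dispersion parameterisation (var = m + m^2/r)."""
    r = disp
    p = r / (r + mean)
    return nbinom.logpmf(x, r, p)


def _fit_single_nb(x: np.ndarray) -> tuple[float, float, float]:
    """Moment fit of one NB component; returns (mean, dispersion, loglik)."""
    m = float(np.mean(x))
    v = float(np.var(x))
    r = m**2 / max(v - m, m * 1e-3)
    r = float(np.clip(r, 0.5, 1e6))
    return m, r, float(_nb_logpmf(x, m, r).sum())


def _mixture_loglik(x, mu, m1, r1, m2, r2):
    l1 = np.log1p(-mu) + _nb_logpmf(x, m1, r1) if mu < 1 else np.full_like(x, -np.inf, dtype=float)
    l2 = np.log(mu) + _nb_logpmf(x, m2, r2) if mu > 0 else np.full_like(x, -np.inf, dtype=float)
    m = np.maximum(l1, l2)
    return float(np.sum(m + np.log(np.exp(l1 - m) + np.exp(l2 - m))))


def fit_g2_mixture(
    counts_non_s: np.ndarray,
    counts_s: np.ndarray | None = None,
    clone_id: object = None,
    n_draws: int = 4000,
    n_em_iter: int = 50,
    seed: int = 0,
    bic_margin: float | None = None,
) -> G2MixtureFit:
    """Constrained NB mixture fit of a clone's non-S total read counts.

    The importance-sampling stage draws mu uniform on [0, 1], component means
    log-uniform within the data range (ordered) and dispersions log-uniform
    in [2, 2000], rejecting draws whose G2 mean does not exceed the S-cell
    mean; draws are weighted by the data likelihood and the best draw seeds a
    constrained EM refinement.  ``bic_margin`` (default: BIC penalty for the
    3 extra parameters) guards against spurious splits on single-component
    data.
    """
    x = np.asarray(counts_non_s, dtype=float)
    if x.size == 0:
        raise ValueError("no non-S cells to fit")
    rng = np.random.default_rng(seed)
    s_mean = float(np.mean(counts_s)) if counts_s is not None and len(counts_s) else -np.inf
    m_single, r_single, ll_single = _fit_single_nb(x)
    flags: dict = {}
    if x.size < MIN_CELLS_PER_FIT:
        flags["too_few_cells"] = True

    if np.isfinite(s_mean) and s_mean >= x.max():
        warnings.warn("constraint unsatisfiable: S-cell mean exceeds all counts; mu = 0")
        return G2MixtureFit(
            clone_id, 0.0, m_single, r_single, m_single * 2, r_single,
            np.ones(x.size), ll_single, ll_single, {"constraint_unsatisfiable": True},
        )

    lo, hi = x.min() * 0.9 + 1.0, x.max() * 1.1
    mus = rng.uniform(0.0, 1.0, n_draws)
    m_pair = np.exp(rng.uniform(np.log(lo), np.log(hi), (n_draws, 2)))
    m_pair.sort(axis=1)
    disp = np.exp(rng.uniform(np.log(2.0), np.log(2000.0), (n_draws, 2)))
    ok = m_pair[:, 1] > max(s_mean, 0.0)
    weights = np.full(n_draws, -np.inf)
    for i in np.flatnonzero(ok):
        weights[i] = _mixture_loglik(
            x, mus[i], m_pair[i, 0], disp[i, 0], m_pair[i, 1], disp[i, 1]
        )
    best = int(np.argmax(weights))
    starts = [
        (
            float(mus[best]),
            float(m_pair[best, 0]),
            float(disp[best, 0]),
            float(m_pair[best, 1]),
            float(disp[best, 1]),
        ),
        # deterministic quantile start: lower bulk vs top decile
        (
            0.15,
            float(np.median(x[x <= np.quantile(x, 0.7)])),
            r_single,
            float(np.mean(x[x >= np.quantile(x, 0.9)])),
            r_single,
        ),
    ]

    def em(mu, m1, r1, m2, r2):
        # the dispersion is shared between components: both reflect the same
        # library-level sampling mechanism, and a free per-component
        # dispersion lets a wrong split absorb the tail of the other mode
        r = 0.5 * (r1 + r2)
        for _ in range(n_em_iter):
            l1 = np.log(max(1 - mu, 1e-12)) + _nb_logpmf(x, m1, r)
            l2 = np.log(max(mu, 1e-12)) + _nb_logpmf(x, m2, r)
            mx = np.maximum(l1, l2)
            w2 = np.exp(l2 - mx) / (np.exp(l1 - mx) + np.exp(l2 - mx))
            w1 = 1.0 - w2
            mu = float(np.clip(np.mean(w2), 0.0, 1.0))
            if w1.sum() > 1e-9:
                m1 = float(np.sum(w1 * x) / w1.sum())
            if w2.sum() > 1e-9:
                m2 = float(np.sum(w2 * x) / w2.sum())
            v = float(
                (np.sum(w1 * (x - m1) ** 2) + np.sum(w2 * (x - m2) ** 2)) / len(x)
            )
            msq = float((np.sum(w1 * m1**2) + np.sum(w2 * m2**2)) / len(x))
            mbar = float((np.sum(w1 * m1) + np.sum(w2 * m2)) / len(x))
            r = float(np.clip(msq / max(v - mbar, mbar * 1e-3), 0.5, 1e6))
            # enforce ordering and the S-cell constraint by projection
            floor = max(m1 * 1.001, s_mean if np.isfinite(s_mean) else 0.0)
            if m2 < floor:
                m2 = floor
        return mu, m1, r, m2, r

    fits = [em(*s) for s in starts]
    lls = [_mixture_loglik(x, *f) for f in fits]
    mu, m1, r1, m2, r2 = fits[int(np.argmax(lls))]
    ll_mix = float(np.max(lls))

    if bic_margin is None:
        bic_margin = 1.5 * np.log(x.size)  # 3 extra parameters
    if ll_mix - ll_single < bic_margin or mu <= 0.0:
        return G2MixtureFit(
            clone_id, 0.0, m_single, r_single, max(m_single * 2, s_mean), r_single,
            np.ones(x.size), max(ll_mix, ll_single), ll_single,
            {**flags, "collapsed_to_single": True},
        )
    l1 = _nb_logpmf(x, m1, r1)
    l2 = _nb_logpmf(x, m2, r2)
    mx = np.maximum(l1, l2)
    p_g0g1 = np.exp(l1 - mx) / (np.exp(l1 - mx) + np.exp(l2 - mx))
    return G2MixtureFit(
        clone_id, mu, m1, r1, m2, r2, p_g0g1, ll_mix, ll_single, flags
    )


def call_g2_cells(fit: G2MixtureFit, threshold: float = G2_THRESHOLD) -> np.ndarray:
    """Boolean per-cell G2 call: strictly ``p_g0g1 < threshold``."""
    return fit.p_g0g1 < threshold
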