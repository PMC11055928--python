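"""Evaluation statistics: Rand index, replicate-study metrics, and WAIC."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp


def rand_index(c1, c2) -> float:
    """Rand index: the fraction of unordered pairs on which two partitions
    agree (both together, or both apart).  Invariant to relabeling."""
    c1 = np.asarray(c1)
    c2 = np.asarray(c2)
    if c1.shape != c2.shape:
        raise ValueError("label vectors must have equal length")
    n = c1.shape[0]
    if n < 2:
        raise ValueError("need at least two items")
    same1 = c1[:, None] == c1[None, :]
    same2 = c2[:, None] == c2[None, :]
    iu = np.triu_indices(n, k=1)
    agree = (same1[iu] == same2[iu]).sum()
    return float(agree) / iu[0].shape[0]


def replicate_metrics(estimates: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Replicate-averaged bias/spread/error of coefficient estimates.

    ``estimates`` has shape (R, n, p) over replicates, areas, covariates;
    ``truth`` has shape (n, p).  Per covariate k:

        MAB  = mean_s mean_r |est_{s,k,r} - truth_{s,k}|
        MSD  = mean_s  sd_r(est_{s,k,r})          (divisor R - 1)
        MMSE = mean_s mean_r (est_{s,k,r} - truth_{s,k})^2

    With a single replicate MSD is undefined and reported as NaN.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.ndim != 3 or estimates.shape[1:] != truth.shape:
        raise ValueError("estimates must be (R, n, p) matching truth (n, p)")
    R = estimates.shape[0]
    err = estimates - truth[None, :, :]
    mab = np.abs(err).mean(axis=0).mean(axis=0)
    mmse = (err ** 2).mean(axis=0).mean(axis=0)
    if R >= 2:
        msd = estimates.std(axis=0, ddof=1).mean(axis=0)
    else:
        msd = np.full(truth.shape[1], np.nan)
    return pd.DataFrame({"covariate": np.arange(1, truth.shape[1] + 1),
                         "MAB": mab, "MSD": msd, "MMSE": mmse})


def waic(pointwise_loglik: np.ndarray) -> dict:
    """Widely applicable information criterion from a (draws, n) matrix.

    lppd   = sum_i log mean_d exp(ll_{d,i})      (log-space)
    p_waic = sum_i var_d ll_{d,i}                (divisor M - 1)
    WAIC   = -2 (lppd - p_waic)
    """
    ll = np.atleast_2d(np.asarray(pointwise_loglik, dtype=float))
    M = ll.shape[0]
    if M < 2:
        raise ValueError("WAIC needs at least two posterior draws")
    lppd = float((logsumexp(ll, axis=0) - np.log(M)).sum())
    p_waic = float(ll.var(axis=0, ddof=1).sum())
    return {"waic": -2.0 * (lppd - p_waic), "lppd": lppd, "p_waic": p_waic}
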