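"""Exact tail tests on element counts, the adaptive leap threshold, and the
binomial fold.

P-values are carried internally as natural-log values so that deeply
significant tails (far below float underflow) never collapse: the leap
statistic d_k = -log(p_k / p_{k+1}) is computed directly on log p.
Linear-scale returns are floored at the smallest positive subnormal float.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, hypergeom

__all__ = [
    "binomial_tail",
    "binomial_logtail",
    "hypergeometric_tail",
    "hypergeometric_logtail",
    "adaptive_threshold",
    "AdaptiveThresholdResult",
    "binomial_fold",
]

# smallest positive representable float; linear p-values never print as 0
_P_FLOOR = math.ulp(0.0)


def binomial_logtail(k: int, n: int, p: float) -> float:
    """Natural log of the upper binomial tail P(X >= k), X ~ Bin(n, p)."""
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"require 0 <= p <= 1, got p={p}")
    if k == 0:
        return 0.0
    if p == 0.0:
        return -math.inf
    if p == 1.0:
        return 0.0
    xs = np.arange(k, n + 1)
    return float(logsumexp(binom.logpmf(xs, n, p)))


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper binomial tail sum_{x=k}^{n} C(n,x) p^x (1-p)^{n-x}.

    Computed in log space; never returns exactly 0 (floored at the smallest
    positive subnormal) so downstream log transforms stay finite.
    """
    return max(math.exp(binomial_logtail(k, n, p)), _P_FLOOR)


def hypergeometric_logtail(k: int, n: int, K: int, N: int) -> float:
    """Natural log of the upper hypergeometric tail P(X >= k).

    X counts successes in `n` draws without replacement from a population of
    `N` containing `K` successes.
    """
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"require 0 <= n, K <= N, got n={n}, K={K}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    if k == 0:
        return 0.0
    xs = np.arange(k, min(n, K) + 1)
    return float(logsumexp(hypergeom.logpmf(xs, N, K, n)))


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper hypergeometric tail sum_{x=k}^{min(n,K)} C(K,x) C(N-K,n-x) / C(N,n)."""
    return max(math.exp(hypergeometric_logtail(k, n, K, N)), _P_FLOOR)


@dataclass(frozen=True)
class AdaptiveThresholdResult:
    """Outcome of the leap-based per-term significance threshold.

    `names` / `logps` are the inspected top-m entries sorted by ascending
    p-value; `gaps[k]` = log p_{k+2} - log p_{k+1} (the leap after the
    (k+1)-th entry); `leap_index` is the 1-based m maximising the leap;
    `threshold_logp` = log p_m; `kept` holds every input name with
    p <= p_m (not only the inspected top-m).
    """

    names: tuple[str, ...]
    logps: tuple[float, ...]
    gaps: tuple[float, ...]
    leap_index: int
    threshold_logp: float
    kept: frozenset[str]


def adaptive_threshold(
    pvals: Mapping[str, float], top_m: int = 10, *, log: bool = False
) -> AdaptiveThresholdResult:
    """Place a per-term p-value cutoff at the largest leap among the top m.

    Sort p-values ascending, inspect the smallest min(top_m, available);
    compute d_k = -log(p_k / p_{k+1}) for adjacent pairs; the threshold is
    p_m at m = argmax_k d_k (smallest index on ties). Every TF in `pvals`
    with p <= p_m is kept — with a single finite p-value, that lone TF.

    With ``log=True`` the mapping values are natural-log p-values.
    """
    items = []
    for name, p in pvals.items():
        if math.isnan(p):
            continue
        lp = p if log else (math.log(p) if p > 0 else -math.inf)
        items.append((lp, name))
    if not items:
        raise ValueError("adaptive_threshold: no finite p-values")
    items.sort(key=lambda t: (t[0], t[1]))
    m_used = min(top_m, len(items))
    top = items[:m_used]
    logps = tuple(lp for lp, _ in top)
    names = tuple(nm for _, nm in top)
    gaps = tuple(logps[k + 1] - logps[k] for k in range(m_used - 1))
    if gaps:
        leap_index = 1 + max(range(len(gaps)), key=lambda k: (gaps[k], -k))
    else:
        leap_index = 1
    threshold_logp = logps[leap_index - 1]
    kept = frozenset(nm for lp, nm in items if lp <= threshold_logp)
    return AdaptiveThresholdResult(
        names=names,
        logps=logps,
        gaps=gaps,
        leap_index=leap_index,
        threshold_logp=threshold_logp,
        kept=kept,
    )


def binomial_fold(k: int, n: int, background_fraction: float) -> float:
    """Observed rate over background rate: (k/n) / background_fraction."""
    if n <= 0:
        raise ValueError("n must be positive")
    if background_fraction <= 0:
        raise ValueError("background_fraction must be positive")
    return (k / n) / background_fraction
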