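"""Population summaries over the detected sites.

Distribution of the optimum across the network, the paired comparison of
below- versus above-optimum sensitivities, and the fraction of sites where
wetting suppresses ER more strongly than drying does.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .errors import InputError

#: Largest number of nonzero differences for which the signed-rank null is
#: enumerated exactly (no ties allowed on the exact path).
EXACT_LIMIT = 25


def summarize(values) -> dict:
    """Order statistics (min, max, median, n) of a value set."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise InputError("summarize: no finite values")
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "median": float(np.median(x)),
        "n": int(x.size),
    }


def _approx_signed_rank(d: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie and continuity corrections.

    W+ is the sum of ranks of positive differences among the |d| ranks.
    Under the null  E[W+] = n(n+1)/4  and
    Var[W+] = n(n+1)(2n+1)/24 - sum_t (t^3 - t)/48  over tie groups t.
    The continuity correction shrinks |W+ - E| by 1/2.
    """
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts**3 - counts) / 48.0).sum())
    if var <= 0:
        return w_plus, 1.0
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
    return w_plus, float(2.0 * stats.norm.sf(z))


def paired_wilcoxon(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on a - b.

    Zero differences are dropped (the classical convention).  With at most
    :data:`EXACT_LIMIT` nonzero untied differences the null distribution is
    enumerated exactly (scipy's exact path); otherwise a normal
    approximation with tie and continuity corrections is used.  ``method``
    may force ``"exact"`` or ``"approx"``.

    Returns ``(W+, p)`` where W+ is the positive-rank sum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired samples must have equal length")
    d = a - b
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    if method == "auto":
        method = "exact" if (d.size <= EXACT_LIMIT and not has_ties) else "approx"
    if method == "exact":
        if has_ties:
            raise InputError("exact enumeration requires untied |differences|")
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
        return _wplus(d), float(res.pvalue)
    return _approx_signed_rank(d)


def _wplus(d: np.ndarray) -> float:
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def fraction_sen_above_greater(results) -> tuple[int, float]:
    """Count and fraction of detected sites with Sen_above strictly greater
    than Sen_below.  Empty input yields (0, nan)."""
    pairs = [
        (r.sen_below, r.sen_above) for r in results if getattr(r, "detected", True)
    ]
    if not pairs:
        return 0, float("nan")
    count = sum(1 for sb, sa in pairs if sa > sb)
    return count, count / len(pairs)


def network_summary(results) -> dict:
    """JSON-ready population summary over per-site detection results."""
    detected = [r for r in results if r.detected]
    out = {
        "n_sites": len(results),
        "n_detected": len(detected),
    }
    if detected:
        out["smer_opt"] = summarize([r.smer_opt for r in detected])
        out["sen_below"] = summarize([r.sen_below for r in detected])
        out["sen_above"] = summarize([r.sen_above for r in detected])
        stat, p = paired_wilcoxon(
            [r.sen_below for r in detected], [r.sen_above for r in detected]
        )
        out["wilcoxon"] = {"stat": stat, "p": p}
        count, frac = fraction_sen_above_greater(detected)
        out["n_sen_above_greater"] = count
        out["fraction_sen_above_greater"] = frac
    reasons: dict[str, int] = {}
    for r in results:
        if not r.detected:
            reasons[r.reason or "unknown"] = reasons.get(r.reason or "unknown", 0) + 1
    out["not_detected_reasons"] = reasons
    return out
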