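"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's index arithmetic: regions are found
by linear scans over explicit intervals and the rules are applied by direct
case analysis, so agreement with the fast implementations is meaningful.
"""
from __future__ import annotations

import numpy as np


def oracle_assign(onsets, soa, presses):
    """Brute-force press-to-trial assignment.

    Returns (rts, n_discarded): per-trial RT (NaN if none) and the count of
    presses that were not attributed to any trial.
    """
    onsets = list(onsets)
    n = len(onsets)
    rts = [float("nan")] * n
    discarded = 0

    primary = {}   # trial -> list of press times in its window
    gaps = []      # (press time, owning trial) in press order
    for p in sorted(presses):
        region = None
        for i, t in enumerate(onsets):
            if t + 0.7 * soa <= p < t + 1.4 * soa:
                region = ("window", i)
                break
            if t + 1.4 * soa <= p < t + 1.7 * soa:
                region = ("gap", i)
                break
        if region is None:
            discarded += 1
        elif region[0] == "window":
            primary.setdefault(region[1], []).append(p)
        else:
            gaps.append((p, region[1]))

    for i, plist in primary.items():
        rts[i] = min(plist) - onsets[i]
        discarded += len(plist) - 1

    for p, i in gaps:
        if np.isnan(rts[i]):
            rts[i] = p - onsets[i]
        elif i + 1 < n and np.isnan(rts[i + 1]):
            rts[i + 1] = p - onsets[i + 1]
        else:
            discarded += 1

    return np.array(rts), discarded


def mc_bf10_correlation(r, n, n_draws, seed, kappa=1.0):
    """Monte-Carlo Bayes factor: average the likelihood ratio over prior
    draws of rho.  Returns (estimate, standard error)."""
    from scipy import special

    rng = np.random.default_rng(seed)
    a = 1.0 / kappa
    rho = 2 * rng.beta(a, a, n_draws) - 1
    c = (2 * n - 1) / 2
    h0 = special.hyp2f1(0.5, 0.5, c, 0.5)
    lr = np.exp(
        (n - 1) / 2 * np.log1p(-rho**2)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, c, (1 + rho * r) / 2) / h0)
    )
    return float(lr.mean()), float(lr.std(ddof=1) / np.sqrt(n_draws))
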