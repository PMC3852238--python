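"""Independent reference implementations used to pin pipeline semantics.

Each oracle is deliberately naive (exhaustive enumeration, textbook
formulas) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist


def bh_reject(pvals, q):
    """Benjamini-Hochberg by direct definition: find the largest k with
    p_(k) <= q*k/n, reject everything at or below that p-value."""
    pvals = np.asarray(pvals, dtype=float)
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    threshold = 0.0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= q * rank / n:
            threshold = pvals[idx]
    return pvals <= threshold if threshold > 0 else np.zeros(n, dtype=bool)


def classify_presence(m_a, m_b, min_in=3, max_out=1):
    """The presence/absence rule, written as literal prose-to-code."""
    a_has = m_a >= min_in
    b_has = m_b >= min_in
    a_absent = m_a <= max_out
    b_absent = m_b <= max_out
    if a_has and b_absent:
        return "DMC_A"
    if b_has and a_absent:
        return "DMC_B"
    if a_has and b_has:
        return "CMC"
    return "unclassified"


def window_cluster_members(positions, window=250, min_count=3):
    """Union of positions lying in ANY length-``window`` interval that
    contains at least ``min_count`` of them (exhaustive slide)."""
    positions = sorted(positions)
    members = set()
    for start in {p for p in positions} | {p - window + 1 for p in positions}:
        inside = [p for p in positions if start <= p < start + window]
        if len(inside) >= min_count:
            members.update(inside)
    return members


def chi2_textbook(table):
    """Pearson statistic by the Sum (O-E)^2 / E formula, df = 1 for 2x2."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, df))
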