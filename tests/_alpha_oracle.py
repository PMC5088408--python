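"""Brute-force pair-enumeration oracle for the agreement statistics.

Computes alpha exactly as the pairwise-permutation definition reads, with
naive Python loops and no linear algebra: observed disagreement is counted
over all ordered pairs of distinct ratings within each unit; chance
disagreement is counted over all ordered pairs of distinct slots in a
pooled list in which every rating appears once per pairing it participates
in (multiplicity ``m_u - 1``).  Deliberately independent of
``nisslcyto.reliability``.
"""

import itertools


def _pairable_rows(df):
    rows = []
    for _, row in df.iterrows():
        vals = [v for v in row.tolist() if isinstance(v, str)]
        if len(vals) >= 2:
            rows.append(vals)
    return rows


def brute_alpha(df) -> float:
    """Nominal alpha from a units x raters DataFrame (NaN = missing)."""
    rows = _pairable_rows(df)
    n_pairs = 0
    disagreements = 0
    for vals in rows:
        for i in range(len(vals)):
            for j in range(len(vals)):
                if i == j:
                    continue
                n_pairs += 1
                if vals[i] != vals[j]:
                    disagreements += 1
    d_obs = disagreements / n_pairs

    pooled = []
    for vals in rows:
        for v in vals:
            pooled.extend([v] * (len(vals) - 1))
    total = 0
    differing = 0
    for i in range(len(pooled)):
        for j in range(len(pooled)):
            if i == j:
                continue
            total += 1
            if pooled[i] != pooled[j]:
                differing += 1
    d_exp = differing / total
    return 1.0 - d_obs / d_exp


def brute_percent_agreement(df):
    """(mean, sem) of percent agreement over all rater pairs, naive loops."""
    per_pair = []
    for a, b in itertools.combinations(df.columns, 2):
        shared = 0
        equal = 0
        for u in df.index:
            va, vb = df.at[u, a], df.at[u, b]
            if isinstance(va, str) and isinstance(vb, str):
                shared += 1
                if va == vb:
                    equal += 1
        if shared:
            per_pair.append(100.0 * equal / shared)
    mean = sum(per_pair) / len(per_pair)
    if len(per_pair) > 1:
        var = sum((x - mean) ** 2 for x in per_pair) / (len(per_pair) - 1)
        sem = (var / len(per_pair)) ** 0.5
    else:
        sem = 0.0
    return mean, sem
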