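"""Naive brute-force reference implementations used only as test oracles.

Everything here is written as plain loops straight from the definitions, with
no shared code with the package, so agreement is a meaningful check.
"""

import math

import numpy as np


def _sd(v):
    v = list(map(float, v))
    n = len(v)
    m = sum(v) / n
    return math.sqrt(sum((x - m) ** 2 for x in v) / (n - 1))


def delta_ct(x):
    """Mean over partners of the SD of pairwise Cq differences."""
    g, s = x.shape
    out = []
    for i in range(g):
        sds = []
        for k in range(g):
            if k == i:
                continue
            sds.append(_sd([x[i, j] - x[k, j] for j in range(s)]))
        out.append(sum(sds) / len(sds))
    return np.array(out)


def genorm_stepwise(x, genes):
    """Stepwise exclusion: returns (values, exclusion_order) with the same
    lexicographic tie rule the package documents."""
    remaining = list(range(len(genes)))
    values = {}
    order = []
    while len(remaining) > 2:
        sub = x[remaining]
        m = delta_ct(sub) if len(remaining) > 2 else None
        worst = max(m)
        tied = [remaining[j] for j in range(len(remaining)) if m[j] == worst]
        drop = min(tied, key=lambda i: genes[i])
        values[genes[drop]] = float(m[remaining.index(drop)])
        order.append(genes[drop])
        remaining.remove(drop)
    i, k = remaining
    final_m = _sd([x[i, j] - x[k, j] for j in range(x.shape[1])])
    values[genes[i]] = final_m
    values[genes[k]] = final_m
    return values, order


def bestkeeper(x):
    """Per-gene Cq SD, per-sample geometric-mean index, Pearson r vs index."""
    g, s = x.shape
    sd = np.array([_sd(x[i]) for i in range(g)])
    index = np.array([math.prod(x[i, j] for i in range(g)) ** (1.0 / g) for j in range(s)])
    r = np.full(g, np.nan)
    mi = index.mean()
    for i in range(g):
        mg = x[i].mean()
        num = sum((x[i, j] - mg) * (index[j] - mi) for j in range(s))
        dg = math.sqrt(sum((x[i, j] - mg) ** 2 for j in range(s)))
        di = math.sqrt(sum((index[j] - mi) ** 2 for j in range(s)))
        if dg > 0 and di > 0:
            r[i] = num / (dg * di)
    return sd, index, r


def normfinder_ungrouped(x):
    g, s = x.shape
    z = np.array([[x[i, j] - x[:, j].mean() for j in range(s)] for i in range(g)])
    return np.array([_sd(z[i]) for i in range(g)])


def normfinder_grouped(x, conditions):
    g, s = x.shape
    z = np.array([[x[i, j] - x[:, j].mean() for j in range(s)] for i in range(g)])
    labels = list(dict.fromkeys(conditions))
    out = np.zeros(g)
    for i in range(g):
        overall = z[i].mean()
        acc = 0.0
        for lab in labels:
            cols = [j for j in range(s) if conditions[j] == lab]
            zbar = sum(z[i, j] for j in cols) / len(cols)
            d = zbar - overall
            s2 = sum((z[i, j] - zbar) ** 2 for j in cols) / (len(cols) - 1)
            acc += abs(d) + math.sqrt(s2 / len(cols))
        out[i] = acc / len(labels)
    return out


def exhaustive_two_group_p(a, b):
    """Exact permutation p for a two-group one-way ANOVA by enumerating all
    distinct assignments of the pooled values to groups of sizes |a|, |b|."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n_a = len(a)

    def f_stat(ga, gb):
        n, k = len(ga) + len(gb), 2
        grand = (sum(ga) + sum(gb)) / n
        ssb = len(ga) * (np.mean(ga) - grand) ** 2 + len(gb) * (np.mean(gb) - grand) ** 2
        sst = sum((v - grand) ** 2 for v in ga + gb)
        ssw = sst - ssb
        if ssw <= 1e-300:
            return math.inf if ssb > 0 else 0.0
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = f_stat(list(a), list(b))
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if f_stat(ga, gb) >= f_obs:
            count += 1
    return count / total
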