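"""Independent brute-force oracles used by the bootstrap tests.

These deliberately avoid the package's resampling code: the weighted
bootstrap distribution for a tiny sample is enumerated exactly over all
n^n ordered resamples with their multinomial probabilities.
"""

import itertools

import numpy as np


def enumerate_resample_distribution(values, weights):
    """Exact distribution of the resample mean for a tiny weighted sample.

    Returns (atoms, probs): sorted unique resample means and their
    probabilities over all len(values)**len(values) ordered draws.
    """
    values = np.asarray(values, dtype=float)
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    n = values.size
    dist: dict[float, float] = {}
    for combo in itertools.product(range(n), repeat=n):
        idx = list(combo)
        prob = float(np.prod(p[idx]))
        mean = float(values[idx].mean())
        dist[mean] = dist.get(mean, 0.0) + prob
    atoms = np.array(sorted(dist))
    probs = np.array([dist[a] for a in atoms])
    return atoms, probs


def exact_mean_sd(atoms, probs):
    mean = float((atoms * probs).sum())
    var = float(((atoms - mean) ** 2 * probs).sum())
    return mean, np.sqrt(var)


def quantile_bracket(atoms, probs, level, slack):
    """Interval that must contain any consistent empirical quantile.

    ``slack`` is the allowed CDF error (Monte-Carlo standard errors times
    their multiplier).  The bracket spans from the largest atom whose CDF
    stays below level - slack up to the smallest atom whose CDF reaches
    level + slack; an empirical quantile interpolated between order
    statistics must fall inside.
    """
    cdf = np.cumsum(probs)
    lo = atoms[0]
    for a, f in zip(atoms, cdf):
        if f < level - slack:
            lo = a
        else:
            break
    hi = atoms[-1]
    for a, f in zip(atoms, cdf):
        if f >= level + slack:
            hi = a
            break
    return lo, hi
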