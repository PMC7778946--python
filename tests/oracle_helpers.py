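"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they verify: rank scores
are assigned by explicit sorting and tie-averaging over positions, and
geNorm M is computed from all pairwise log-ratio SDs directly.
"""

import itertools
import math

import numpy as np


def position_scores(values, best_is_high):
    """Rank scores by explicit position: n for the best value, 1 for the
    worst, tied values receive the average of their positions."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i], reverse=not best_is_high)
    # order[0] is the worst -> position 1
    scores = [0.0] * n
    pos = 0
    while pos < n:
        tied = [order[pos]]
        while pos + len(tied) < n and values[order[pos + len(tied)]] == values[order[pos]]:
            tied.append(order[pos + len(tied)])
        avg = sum(range(pos + 1, pos + len(tied) + 1)) / len(tied)
        for i in tied:
            scores[i] = avg
        pos += len(tied)
    return scores


def brute_force_sp(mean_rpkm, sd_log2, mfc):
    """Score Product per transcript by explicit position products."""
    s1 = position_scores(list(mean_rpkm), best_is_high=True)
    s2 = position_scores(list(sd_log2), best_is_high=False)
    s3 = position_scores(list(mfc), best_is_high=False)
    sp = [
        float(np.power(np.float64(a) * np.float64(b) * np.float64(c), 1.0 / 3.0))
        for a, b, c in zip(s1, s2, s3)
    ]
    return sp, s1, s2, s3


def brute_force_genorm(log2_expr):
    """geNorm M by direct all-pairs SD of log-ratios (ddof=1)."""
    x = np.asarray(log2_expr, dtype=float)
    m = []
    for j in range(x.shape[0]):
        sds = []
        for k in range(x.shape[0]):
            if k == j:
                continue
            diff = x[j] - x[k]
            mean = diff.mean()
            sds.append(math.sqrt(((diff - mean) ** 2).sum() / (len(diff) - 1)))
        m.append(sum(sds) / len(sds))
    return np.array(m)


def nn_tm_oracle(seq, na_mM=50.0, mg_mM=1.5, oligo_nM=200.0):
    """Independent nearest-neighbor Tm: SantaLucia 2004 unified parameters
    with the Owczarzy 2008 monovalent+magnesium correction."""
    nn = {
        "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
        "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9),
    }
    comp = str.maketrans("ACGT", "TGCA")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        h, s = nn[pair] if pair in nn else nn[pair.translate(comp)[::-1]]
        dh += h
        ds += s
    r_gas = 1.987  # cal / (mol K)
    ct = oligo_nM * 1e-9
    tm_k = dh * 1000.0 / (ds + r_gas * math.log(ct))

    mon = na_mM * 1e-3
    mg = mg_mM * 1e-3
    fgc = (seq.count("G") + seq.count("C")) / len(seq)
    ratio = math.sqrt(mg) / mon
    if ratio < 0.22:
        inv = (
            1 / tm_k
            + (4.29 * fgc - 3.95) * 1e-5 * math.log(mon)
            + 9.40e-6 * math.log(mon) ** 2
        )
    else:
        a, b, c, d = 3.92e-5, -9.11e-6, 6.26e-5, 1.42e-5
        e, f, g = -4.82e-4, 5.25e-4, 8.31e-5
        if ratio < 6.0:
            lnm = math.log(mon)
            a = 3.92e-5 * (0.843 - 0.352 * math.sqrt(mon) * lnm)
            d = 1.42e-5 * (1.279 - 4.03e-3 * lnm - 8.03e-3 * lnm ** 2)
            g = 8.31e-5 * (0.486 - 0.258 * lnm + 5.25e-3 * lnm ** 3)
        lnmg = math.log(mg)
        inv = (
            1 / tm_k
            + a
            + b * lnmg
            + fgc * (c + d * lnmg)
            + (1.0 / (2.0 * (len(seq) - 1))) * (e + f * lnmg + g * lnmg ** 2)
        )
    return 1.0 / inv - 273.15


def random_metric_tables(n_tables, max_n=6, seed=0, with_ties=True):
    """Random candidate metric tables (mean RPKM, SD, MFC), some with ties."""
    rng = np.random.default_rng(seed)
    for i in range(n_tables):
        n = int(rng.integers(1, max_n + 1))
        mean = rng.uniform(30, 300, n)
        sd = rng.uniform(0.01, 0.5, n)
        mfc = rng.uniform(1.0, 2.0, n)
        if with_ties and n >= 2 and i % 3 == 0:
            mean[1] = mean[0]
            if n >= 3 and i % 2 == 0:
                sd[2] = sd[0]
        yield np.round(mean, 2), np.round(sd, 3), np.round(mfc, 3)
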