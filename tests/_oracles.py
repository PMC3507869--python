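"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain Python
loops over the defining formulas, so that agreement with the package is a
genuine cross-check.
"""

from __future__ import annotations

import itertools
import math


def squared_euclidean(u, v) -> float:
    return float(sum((a - b) ** 2 for a, b in zip(u, v)))


def brute_amova(profiles: dict, groups: dict) -> dict:
    """AMOVA components evaluated directly from the defining sums.

    ``profiles`` maps sample id -> sequence of band values; ``groups`` maps
    sample id -> group label.
    """
    samples = list(profiles)
    n = len(samples)
    labels = sorted({groups[s] for s in samples})
    members = {g: [s for s in samples if groups[s] == g] for g in labels}

    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += squared_euclidean(profiles[samples[i]],
                                          profiles[samples[j]])
    ss_total /= n

    ss_within = 0.0
    sswp = {}
    for g in labels:
        mem = members[g]
        s = 0.0
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                s += squared_euclidean(profiles[mem[i]], profiles[mem[j]])
        s /= len(mem)
        sswp[g] = s
        ss_within += s

    ss_among = ss_total - ss_within
    df_among = len(labels) - 1
    df_within = n - len(labels)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - sum(len(members[g]) ** 2 for g in labels) / n) / df_among
    vw = ms_within
    va = (ms_among - vw) / n0
    va_pos = max(va, 0.0)
    phi = va_pos / (va_pos + vw) if (va_pos + vw) > 0 else 0.0
    return {
        "ss_total": ss_total, "ss_within": ss_within, "ss_among": ss_among,
        "df_among": df_among, "df_within": df_within,
        "ms_among": ms_among, "ms_within": ms_within,
        "va": va, "vw": vw, "n0": n0, "phi_pt": phi, "sswp": sswp,
    }


def brute_phi(profiles: dict, groups: dict) -> float:
    return brute_amova(profiles, groups)["phi_pt"]


def exact_permutation_p(profiles: dict, group_sizes: list[int]) -> float:
    """Exact permutation p-value for PhiPT by full label enumeration.

    All assignments of samples to groups of the given sizes are enumerated
    (each distinct ordered label sequence once); the observed grouping is
    the one listing samples in their given order into consecutive groups.
    Ties count as >=, matching the conservative convention.
    """
    samples = list(profiles)
    observed_groups = {}
    pos = 0
    for g, size in enumerate(group_sizes):
        for s in samples[pos:pos + size]:
            observed_groups[s] = g
        pos += size
    observed = brute_phi(profiles, observed_groups)

    count = 0
    total = 0
    for perm in itertools.permutations(samples):
        groups = {}
        pos = 0
        for g, size in enumerate(group_sizes):
            for s in perm[pos:pos + size]:
                groups[s] = g
            pos += size
        total += 1
        if brute_phi(profiles, groups) >= observed - 1e-12:
            count += 1
    return count / total


def pearson_r(xs, ys) -> float:
    """Closed-form Pearson correlation."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs)
                    * sum((y - my) ** 2 for y in ys))
    return num / den
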