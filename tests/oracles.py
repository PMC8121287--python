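"""Independent brute-force oracles used to check the library implementations.

These deliberately re-derive each quantity from first principles with naive
loops and stay independent of the code paths they check.
"""

import math

import numpy as np


def oracle_features(profile, build, baseline=2):
    """Naive per-feature enumeration of all 8 feature observation lists."""
    segs = {}
    for chrom, sub in profile.by_chromosome():
        segs[chrom] = [(int(r.start), int(r.end), int(r.cn)) for r in sub.itertuples()]

    out = {name: [] for name in
           ("BP10MB", "BPArm", "CN", "CNCP", "OsCN", "SS", "NC50", "BoChr")}

    # junction = boundary between consecutive segments; located at left end
    junctions = {c: [(s[i][1], abs(s[i + 1][2] - s[i][2]))
                     for i in range(len(s) - 1)] for c, s in segs.items()}

    for chrom in segs:
        length = build.lengths[chrom]
        w_start = 1
        while w_start <= length:
            w_end = min(w_start + 10_000_000 - 1, length)
            out["BP10MB"].append(
                sum(1 for pos, _ in junctions[chrom] if w_start <= pos <= w_end)
            )
            w_start += 10_000_000

    for chrom in build.chromosomes:
        (p_lo, p_hi), (q_lo, q_hi) = build.arms(chrom)
        js = junctions.get(chrom, [])
        out["BPArm"].append(sum(1 for pos, _ in js if p_lo <= pos <= p_hi))
        out["BPArm"].append(sum(1 for pos, _ in js if q_lo <= pos <= q_hi))

    for chrom in segs:
        for start, end, cn in segs[chrom]:
            out["CN"].append(cn)
            out["SS"].append(math.log10(end - start + 1))
        out["CNCP"].extend(delta for _, delta in junctions[chrom])

    # OsCN: maximal runs of the oscillation indicator; a chromosome whose
    # last indicator is False (or that never oscillates) ends with a 0.
    for chrom in segs:
        cn = [s[2] for s in segs[chrom]]
        if len(cn) < 3:
            continue
        flags = [cn[i] == cn[i - 2] and cn[i] != cn[i - 1] for i in range(2, len(cn))]
        run = 0
        emitted = []
        for f in flags:
            if f:
                run += 1
            elif run > 0:
                emitted.append(run)
                run = 0
        emitted.append(run)
        out["OsCN"].extend(emitted)

    altered = [(chrom, s) for chrom in segs for s in segs[chrom] if s[2] != baseline]
    per_chrom = {}
    for chrom, _ in altered:
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    total = sum(per_chrom.values())
    if total == 0:
        out["NC50"].append(0)
    else:
        counts = sorted(per_chrom.values(), reverse=True)
        acc = 0
        for k, c in enumerate(counts, start=1):
            acc += c
            if acc >= total / 2:
                out["NC50"].append(k)
                break
    out["BoChr"].extend(build.chrom_index(chrom) for chrom, _ in altered)
    return out


def oracle_tally_row(obs, scheme):
    """Per-observation loop tally using scalar classification only."""
    from cnsig import classify_observation

    counts = dict.fromkeys(scheme.labels, 0)
    for feature in scheme.features:
        for value in obs[feature]:
            counts[classify_observation(feature, value, scheme)] += 1
    return counts


def oracle_chromothripsis(profile):
    total = 0
    for _, sub in profile.by_chromosome():
        cn = list(sub["cn"])
        n = sum(1 for i in range(len(cn) - 2) if cn[i:i + 3] == [2, 1, 2])
        total += n * n
    return total


def oracle_tdp(profile, build, min_size=1_000, max_size=2_000_000, baseline=2):
    tds = []
    for row in profile.segments.itertuples():
        size = row.end - row.start + 1
        if row.cn > baseline and min_size <= size <= max_size:
            tds.append((row.chromosome, size))
    total = len(tds)
    if total == 0:
        return 0.0
    genome = sum(build.lengths.values())
    disp = 0.0
    for chrom in build.chromosomes:
        obs = sum(1 for c, _ in tds if c == chrom)
        disp += abs(obs - total * build.lengths[chrom] / genome)
    size_mb = sum(s for _, s in tds) / 1e6
    return total / (disp + 1.0) * size_mb


def grid_search_exposures(W, v, n, step=0.01):
    """Exhaustive simplex grid search for 3-signature exposure fitting."""
    best, best_err = None, np.inf
    fracs = np.arange(0, 1 + step / 2, step)
    for a in fracs:
        for b in fracs:
            if a + b > 1 + 1e-12:
                continue
            x = n * np.array([a, b, 1 - a - b])
            err = np.linalg.norm(W @ x - v)
            if err < best_err:
                best, best_err = x, err
    return best
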