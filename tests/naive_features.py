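"""Naive loop-based reference implementations of the twenty epoch features.

Deliberately written as slow per-sample loops with no shared code path with
the package, to serve as an independent oracle.
"""

import math


def naive_features(samples):
    """samples: sequence of (x, y, z) triples; returns dict of 20 features."""
    xs = [s[0] for s in samples]
    ys = [s[1] for s in samples]
    zs = [s[2] for s in samples]
    n = len(samples)
    out = {}
    for name, vals in (("X", xs), ("Y", ys), ("Z", zs)):
        out[f"MIN_{name}"] = min(vals)
        out[f"MAX_{name}"] = max(vals)
        mean = sum(vals) / n
        out[f"AVG_{name}"] = mean
        out[f"SD_{name}"] = math.sqrt(
            sum((v - mean) ** 2 for v in vals) / (n - 1)
        )
    out["MAG"] = sum(
        math.sqrt(x * x + y * y + z * z) for x, y, z in zip(xs, ys, zs)
    ) / n
    total = 0.0
    for vals in (xs, ys, zs):
        for i in range(n - 1):
            total += abs(vals[i + 1] - vals[i])
    out["MVA"] = total / (n - 1)
    out["SMA"] = sum(abs(x) + abs(y) + abs(z) for x, y, z in zip(xs, ys, zs)) / n
    ent = 0.0
    for x, y, z in zip(xs, ys, zs):
        u = (1.0 + (x + y + z)) ** 2
        if u > 0.0:
            ent += u * math.log(u)
    out["ENT"] = ent / n
    out["ENG"] = sum(x * x + y * y + z * z for x, y, z in zip(xs, ys, zs)) / n
    pit = rol = inc = 0.0
    for x, y, z in zip(xs, ys, zs):
        pit += math.degrees(math.atan2(-x, math.sqrt(y * y + z * z)))
        rol += math.degrees(math.atan2(y, z))
        inc += math.degrees(math.atan2(math.sqrt(x * x + y * y), z))
    out["PIT"] = pit / n
    out["ROL"] = rol / n
    out["INC"] = inc / n
    return out
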