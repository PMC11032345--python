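"""Independent naive-loop oracles for the descriptor formulas.

Deliberately written with plain Python loops and dictionaries, sharing only
the bundled property tables with the implementation, so that agreement is a
meaningful check of the vectorized code paths.
"""

import math

from acprop import aadata
from acprop.aadata import AA_INDEX, AA_ORDER


def composition(seq: str, k: int) -> dict[str, float]:
    n = len(seq)
    counts: dict[str, int] = {}
    for i in range(n - k + 1):
        counts[seq[i:i + k]] = counts.get(seq[i:i + k], 0) + 1
    return {kmer: c / (n - k + 1) for kmer, c in counts.items()}


def moreau_broto(seq: str, prop: str, d: int) -> float:
    p = [aadata.autocorrelation_properties()[prop][AA_INDEX[a]] for a in seq]
    n = len(p)
    return sum(p[i] * p[i + d] for i in range(n - d)) / (n - d)


def moran(seq: str, prop: str, d: int) -> float:
    p = [aadata.autocorrelation_properties()[prop][AA_INDEX[a]] for a in seq]
    n = len(p)
    pbar = sum(p) / n
    ss = sum((x - pbar) ** 2 for x in p)
    if ss <= 1e-12 * n:
        return 0.0
    num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(n - d)) / (n - d)
    return num / (ss / n)


def geary(seq: str, prop: str, d: int) -> float:
    p = [aadata.autocorrelation_properties()[prop][AA_INDEX[a]] for a in seq]
    n = len(p)
    pbar = sum(p) / n
    ss = sum((x - pbar) ** 2 for x in p)
    if ss <= 1e-12 * n:
        return 0.0
    num = sum((p[i] - p[i + d]) ** 2 for i in range(n - d)) / (2 * (n - d))
    return num / (ss / (n - 1))


def ctd_composition(seq: str, prop_key: str, group: int) -> float:
    part = aadata.ctd_partitions()[prop_key]
    members = set(part[f"G{group}"])
    return sum(1 for a in seq if a in members) / len(seq)


def ctd_transition(seq: str, prop_key: str, g: int, h: int) -> float:
    part = aadata.ctd_partitions()[prop_key]
    grp = {}
    for gi in (1, 2, 3):
        for a in part[f"G{gi}"]:
            grp[a] = gi
    count = 0
    for i in range(len(seq) - 1):
        pair = {grp[seq[i]], grp[seq[i + 1]]}
        if pair == {g, h}:
            count += 1
    return count / (len(seq) - 1)


def ctd_distribution(seq: str, prop_key: str, group: int, frac: int) -> float:
    part = aadata.ctd_partitions()[prop_key]
    members = set(part[f"G{group}"])
    pos = [i + 1 for i, a in enumerate(seq) if a in members]
    if not pos:
        return 0.0
    k = 1 if frac == 0 else math.ceil(frac / 100 * len(pos))
    return 100.0 * pos[k - 1] / len(seq)


def conjoint_triad(seq: str) -> dict[str, float]:
    cls_of = {}
    for a in AA_ORDER:
        cls_of[a] = int(aadata.conjoint_triad_classes()[AA_INDEX[a]]) + 1
    counts: dict[str, int] = {}
    for i in range(len(seq) - 2):
        key = f"CT.{cls_of[seq[i]]}{cls_of[seq[i + 1]]}{cls_of[seq[i + 2]]}"
        counts[key] = counts.get(key, 0) + 1
    return {k: c / (len(seq) - 2) for k, c in counts.items()}


def _dmatrix(scheme: str):
    return (aadata.physicochemical_distance_matrix() if scheme == "phys"
            else aadata.grantham_distance_matrix())


def socn(seq: str, scheme: str, d: int) -> float:
    dm = _dmatrix(scheme)
    return sum(float(dm[AA_INDEX[seq[i]], AA_INDEX[seq[i + d]]]) ** 2
               for i in range(len(seq) - d))


def qso(seq: str, scheme: str, nlag: int = 30, weight: float = 0.1) -> dict[str, float]:
    n = len(seq)
    taus = [socn(seq, scheme, d) for d in range(1, nlag + 1)]
    denom = 1.0 + weight * sum(taus)
    out = {}
    for a in AA_ORDER:
        out[f"QSO.{scheme}.{a}"] = (seq.count(a) / n) / denom
    for d, t in enumerate(taus, start=1):
        out[f"QSO.{scheme}.lag{d}"] = weight * t / denom
    return out


def paac(seq: str, lam: int = 30, weight: float = 0.05) -> dict[str, float]:
    props = aadata.paac_properties()
    n = len(seq)

    def theta(d):
        tot = 0.0
        for i in range(n - d):
            a, b = AA_INDEX[seq[i]], AA_INDEX[seq[i + d]]
            tot += sum((float(props[k][b]) - float(props[k][a])) ** 2 for k in range(3)) / 3
        return tot / (n - d)

    thetas = [theta(d) for d in range(1, lam + 1)]
    denom = 1.0 + weight * sum(thetas)
    out = {f"PAAC.{a}": (seq.count(a) / n) / denom for a in AA_ORDER}
    for d, t in enumerate(thetas, start=1):
        out[f"PAAC.lambda{d}"] = weight * t / denom
    return out


def apaac(seq: str, lam: int = 30, weight: float = 0.05) -> dict[str, float]:
    props = aadata.paac_properties()
    n = len(seq)

    def tau(k, d):
        return sum(float(props[k][AA_INDEX[seq[i]]]) * float(props[k][AA_INDEX[seq[i + d]]])
                   for i in range(n - d)) / (n - d)

    tb = [tau(0, d) for d in range(1, lam + 1)]
    tl = [tau(1, d) for d in range(1, lam + 1)]
    denom = 1.0 + weight * (sum(tb) + sum(tl))
    out = {f"APAAC.{a}": (seq.count(a) / n) / denom for a in AA_ORDER}
    for d, t in enumerate(tb, start=1):
        out[f"APAAC.Hb.lambda{d}"] = weight * t / denom
    for d, t in enumerate(tl, start=1):
        out[f"APAAC.Hl.lambda{d}"] = weight * t / denom
    return out
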