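"""Independent reference implementations used only to check the package.

These deliberately re-derive results from first principles (textbook
formulas, exhaustive scans, brute-force enumeration) rather than calling
the code paths they validate.
"""

import numpy as np
from scipy.special import stdtr

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(COMP[b] for b in reversed(seq))


def ttest_oracle(a, b, kind):
    """Textbook two-sided two-sample t-test from the closed-form formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if kind == "welch":
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    p = 2.0 * stdtr(df, -abs(t))
    return t, p


def bh_oracle(p):
    """Benjamini-Hochberg step-up by direct definition.

    q for the i-th smallest p is min over j >= i of p_(j) * n / j, capped
    at 1, reported back in input order.
    """
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    best = 1.0
    for rank in range(n, 0, -1):
        best = min(best, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = best
    q = np.empty(n)
    q[order] = q_sorted
    return q


def pearson_oracle(x, y):
    """Pearson r from the definition (moment form)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def guide_scan_oracle(window, origin=0):
    """Exhaustive position-by-position SpCas9 site scan on both strands.

    Returns a set of (protospacer, pam, strand, cut_pos) tuples: a site is
    any 23-mer whose last two bases are GG (plus strand, cut 17 in) or
    whose first two bases are CC (minus strand, i.e. a CCN...N23 23-mer
    read as protospacer+NGG on the reverse strand, cut 6 in).
    """
    found = set()
    for i in range(len(window) - 22):
        mer = window[i : i + 23]
        if set(mer) - set("ACGT"):
            continue
        if mer[21:23] == "GG":
            found.add((mer[:20], mer[20:23], "+", origin + i + 17))
        if mer[0:2] == "CC":
            found.add((rc(mer[3:23]), rc(mer[0:3]), "-", origin + i + 6))
    return found


def surrogate_score_oracle(protospacer, offset, half_width):
    """The documented placement/GC score, evaluated independently."""
    gc = sum(protospacer.count(b) for b in "GC") / len(protospacer)
    if "TTTT" in protospacer or not (0.25 <= gc <= 0.75):
        return 0.0
    if any(b * 5 in protospacer for b in "ACGT"):
        return 0.0
    return 0.5 * (1 - abs(gc - 0.5) / 0.5) + 0.5 * (1 - abs(offset) / half_width)


def best_pair_oracle(window, origin, pas_pos, strand, hexamer, half_width=150, due_span=30):
    """Brute-force enumeration of every feasible guide pair.

    Feasibility and the objective replicate the documented design rules;
    selection is an explicit scan over the full cross product.
    """
    cands = []
    for proto, pam, gstrand, cut in guide_scan_oracle(window, origin):
        off = cut - pas_pos if strand == "+" else pas_pos - cut
        if abs(off) > half_width:
            continue
        score = surrogate_score_oracle(proto, off, half_width)
        if score <= 0:
            continue
        cands.append((proto, pam, gstrand, cut, off, score))
    if hexamer is not None:
        hx_lo, hx_hi = hexamer
        edge = hx_lo if strand == "+" else hx_hi
        up_limit = edge - pas_pos if strand == "+" else pas_pos - edge
    else:
        up_limit = -20
    ups = [c for c in cands if c[4] <= up_limit]
    downs = [c for c in cands if c[4] >= due_span]
    if not ups or not downs:
        return None
    best, best_key = None, None
    for u in ups:
        for d in downs:
            size = abs(d[3] - u[3])
            if size == 0:
                continue
            key = (-(u[5] + d[5]), size, min(u[3], d[3]), max(u[3], d[3]))
            if best_key is None or key < best_key:
                best, best_key = (u, d), key
    return best
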