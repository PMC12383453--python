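"""Independent brute-force oracles used to verify the package's metrics.

Everything here is deliberately written as plain scalar/loop code (or
rasterization) that shares no implementation with the package, so a bug in
the package cannot hide in its own oracle.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Aperture geometry via 0.1 mm rasterization
# ---------------------------------------------------------------------------

def rasterize_aperture(bank_a, bank_b, widths, jaws, min_gap, step=0.1):
    """Boolean pixel mask of the open aperture (rows = Y, cols = X)."""
    bank_a = np.asarray(bank_a, float)
    bank_b = np.asarray(bank_b, float)
    widths = np.asarray(widths, float)
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    edges -= edges[-1] / 2.0
    x1, x2, y1, y2 = jaws
    x_lo = min(bank_a.min(), x1) - 2.0
    x_hi = max(bank_b.max(), x2) + 2.0
    xs = np.arange(x_lo, x_hi, step) + step / 2.0
    ys = np.arange(edges[0], edges[-1], step) + step / 2.0
    mask = np.zeros((len(ys), len(xs)), dtype=bool)
    for i in range(len(widths)):
        gap = bank_b[i] - bank_a[i]
        pair_lo, pair_hi = edges[i], edges[i + 1]
        if gap <= min_gap:
            continue
        if pair_hi <= y1 or pair_lo >= y2:  # fully jaw-shadowed
            continue
        rows = (ys > max(pair_lo, y1)) & (ys < min(pair_hi, y2))
        cols = (xs > max(bank_a[i], x1)) & (xs < min(bank_b[i], x2))
        mask[np.ix_(rows, cols)] = True
    return mask, step


def raster_area(mask, step):
    return float(mask.sum()) * step * step


def raster_perimeter(mask, step):
    """Count exposed pixel faces; exact for axis-aligned geometry on-grid."""
    padded = np.pad(mask, 1)
    faces = 0
    faces += np.sum(padded[1:, :] != padded[:-1, :])
    faces += np.sum(padded[:, 1:] != padded[:, :-1])
    return float(faces) * step


def raster_side_length(mask, step):
    """Horizontal exposed faces only (leaf sides run along X)."""
    padded = np.pad(mask, 1)
    return float(np.sum(padded[1:, :] != padded[:-1, :])) * step


# ---------------------------------------------------------------------------
# Scalar re-implementations of the per-arc metrics
# ---------------------------------------------------------------------------

def open_pairs(cp, machine):
    """Indices of open pairs of a control point under the closed-pair rule."""
    edges = machine.leaf_boundaries
    x1, x2, y1, y2 = cp.jaws
    out = []
    for i in range(60):
        gap = cp.bank_b[i] - cp.bank_a[i]
        w = min(edges[i + 1], y2) - max(edges[i], y1)
        if gap > machine.min_gap and w > 0:
            out.append(i)
    return out


def segment_times(arc, machine):
    """Per-segment durations by an explicit scalar max-of-constraints loop."""
    times = []
    cps = arc.control_points
    for k in range(len(cps) - 1):
        dmu = (cps[k + 1].cum_weight - cps[k].cum_weight) * arc.total_mu
        dg = cps[k + 1].gantry_angle - cps[k].gantry_angle
        dg = abs((dg + 180.0) % 360.0 - 180.0)
        travel = 0.0
        for i in range(60):
            travel = max(travel, abs(cps[k + 1].bank_a[i] - cps[k].bank_a[i]),
                         abs(cps[k + 1].bank_b[i] - cps[k].bank_b[i]))
        times.append(max(dmu / machine.max_dose_rate * 60.0,
                         dg / machine.max_gantry_speed,
                         travel / (10.0 * machine.max_leaf_speed)))
    return times


def gap_stats(arc, machine, sas_threshold=10.0):
    """Pooled open gaps -> (Q1, median, SAS) by sort-based percentiles."""
    gaps = []
    for cp in arc.control_points:
        for i in open_pairs(cp, machine):
            gaps.append(cp.bank_b[i] - cp.bank_a[i])
    gaps = sorted(gaps)

    def pctl(p):
        # linear interpolation, same convention as numpy default
        h = (len(gaps) - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, len(gaps) - 1)
        return gaps[lo] + (h - lo) * (gaps[hi] - gaps[lo])

    sas = sum(1 for g in gaps if g < sas_threshold) / len(gaps)
    return pctl(0.25), pctl(0.5), sas


def mean_tgi(arc, machine):
    """MU-weighted tongue-and-groove index by explicit loops."""
    cps = arc.control_points
    n = len(cps)
    dmu = [(cps[k + 1].cum_weight - cps[k].cum_weight) * arc.total_mu
           for k in range(n - 1)]
    w_cp = [0.0] * n
    for k in range(n - 1):
        w_cp[k] += dmu[k] / 2.0
        w_cp[k + 1] += dmu[k] / 2.0
    total_w = 0.0
    acc = 0.0
    for k, cp in enumerate(cps):
        op = open_pairs(cp, machine)
        gap_sum = sum(cp.bank_b[i] - cp.bank_a[i] for i in op)
        if gap_sum <= 0:
            continue
        stagger = 0.0
        for i in op:
            if i + 1 in op:
                stagger += (abs(cp.bank_a[i] - cp.bank_a[i + 1])
                            + abs(cp.bank_b[i] - cp.bank_b[i + 1]))
        acc += w_cp[k] * stagger / (2.0 * gap_sum)
        total_w += w_cp[k]
    return acc / total_w


def lt_al(arc, machine):
    """Mean travel of ever-open leaves over arc length, scalar loops."""
    cps = arc.control_points
    ever = set()
    for cp in cps:
        ever.update(open_pairs(cp, machine))
    travels = []
    for i in sorted(ever):
        ta = sum(abs(cps[k + 1].bank_a[i] - cps[k].bank_a[i])
                 for k in range(len(cps) - 1))
        tb = sum(abs(cps[k + 1].bank_b[i] - cps[k].bank_b[i])
                 for k in range(len(cps) - 1))
        travels.extend([ta, tb])
    arc_len = sum(abs((cps[k + 1].gantry_angle - cps[k].gantry_angle + 180)
                      % 360 - 180) for k in range(len(cps) - 1))
    return float(np.mean(travels)) / arc_len


def dynamic_metrics(arc, machine):
    """Scalar loop version of the six dynamics features."""
    cps = arc.control_points
    n_seg = len(cps) - 1
    t = segment_times(arc, machine)
    dmu = [(cps[k + 1].cum_weight - cps[k].cum_weight) * arc.total_mu
           for k in range(n_seg)]
    dg = [abs((cps[k + 1].gantry_angle - cps[k].gantry_angle + 180) % 360 - 180)
          for k in range(n_seg)]
    arc_len = sum(dg)
    dr = [dmu[k] / t[k] * 60.0 for k in range(n_seg)]
    gs = [dg[k] / t[k] for k in range(n_seg)]

    speeds = {}  # (leaf, segment) -> cm/s for in-field observations
    masks = {}
    for k in range(n_seg):
        op = set(open_pairs(cps[k], machine)) | set(open_pairs(cps[k + 1], machine))
        for i in range(60):
            va = abs(cps[k + 1].bank_a[i] - cps[k].bank_a[i]) / t[k] / 10.0
            vb = abs(cps[k + 1].bank_b[i] - cps[k].bank_b[i]) / t[k] / 10.0
            speeds[("A", i, k)] = va
            speeds[("B", i, k)] = vb
            masks[(i, k)] = i in op
    obs = [speeds[(b, i, k)] for (b, i, k) in speeds if masks[(i, k)]]
    mean_speed = float(np.mean(obs)) if obs else 0.0

    num = 0.0
    travel = 0.0
    for bank in ("A", "B"):
        for i in range(60):
            for k in range(n_seg - 1):
                if masks[(i, k)] and masks[(i, k + 1)]:
                    num += abs(speeds[(bank, i, k + 1)] - speeds[(bank, i, k)])
            for k in range(n_seg):
                if masks[(i, k)]:
                    travel += speeds[(bank, i, k)] * t[k] * 10.0
    speed_mod = num / travel if travel > 0 else 0.0

    mean_rr = sum(dmu) / sum(t) * 60.0
    rr_mod = sum(abs(dr[k + 1] - dr[k]) for k in range(n_seg - 1)) / arc_len
    mean_gs = arc_len / sum(t)
    gs_mod = sum(abs(gs[k + 1] - gs[k]) for k in range(n_seg - 1)) / arc_len
    return mean_speed, speed_mod, mean_rr, rr_mod, mean_gs, gs_mod


def mi_total_dense(arc, machine, alpha=1.0, beta=1.0, f_step=0.001):
    """Modulation index with a 10x finer integration grid, scalar loops."""
    cps = arc.control_points
    n_seg = len(cps) - 1
    t = segment_times(arc, machine)
    dmu = [(cps[k + 1].cum_weight - cps[k].cum_weight) * arc.total_mu
           for k in range(n_seg)]
    dg = [abs((cps[k + 1].gantry_angle - cps[k].gantry_angle + 180) % 360 - 180)
          for k in range(n_seg)]
    dr = [dmu[k] / t[k] * 60.0 for k in range(n_seg)]
    gs = [dg[k] / t[k] for k in range(n_seg)]
    w_seg = [1.0] * n_seg
    for k in range(1, n_seg):
        bump = (alpha * abs(dr[k] - dr[k - 1]) / machine.max_dose_rate
                + beta * abs(gs[k] - gs[k - 1]) / machine.max_gantry_speed)
        w_seg[k - 1] += bump / 2.0
        w_seg[k] += bump / 2.0

    v, w = [], []
    for k in range(n_seg):
        op = set(open_pairs(cps[k], machine)) | set(open_pairs(cps[k + 1], machine))
        for i in op:
            for bank in ("bank_a", "bank_b"):
                d = abs(getattr(cps[k + 1], bank)[i] - getattr(cps[k], bank)[i])
                v.append(d / t[k] / 10.0)
                w.append(w_seg[k])
    v, w = np.array(v), np.array(w)
    if v.size == 0:
        return 0.0
    sigma = float(np.std(v))
    if sigma == 0:
        return 0.0
    grid = np.arange(0.0, 2.0 + f_step / 2, f_step)
    z = [float(np.sum(w[v > f * sigma]) / np.sum(w)) for f in grid]
    return float(np.trapezoid(z, grid))


# ---------------------------------------------------------------------------
# Gamma oracle: exhaustive search with independent bilinear interpolation
# ---------------------------------------------------------------------------

def gamma_exhaustive(ref, ev, spacing, dose_diff, dta, radius_factor=3.0,
                     upsample=10, normalization="global"):
    """Gamma map by explicit search over every fine-grid offset."""
    ref = np.asarray(ref, float)
    ev = np.asarray(ev, float)
    n, m = ref.shape
    step = spacing / upsample
    r = radius_factor * dta
    r_px = int(np.floor(r / step))
    offs = [(dy, dx) for dy in range(-r_px, r_px + 1)
            for dx in range(-r_px, r_px + 1)
            if np.hypot(dy, dx) * step <= r + 1e-12]

    def bilinear(y, x):
        if y < 0 or x < 0 or y > n - 1 or x > m - 1:
            return None
        y0, x0 = min(int(y), n - 2), min(int(x), m - 2)
        fy, fx = y - y0, x - x0
        return (ev[y0, x0] * (1 - fy) * (1 - fx) + ev[y0, x0 + 1] * (1 - fy) * fx
                + ev[y0 + 1, x0] * fy * (1 - fx) + ev[y0 + 1, x0 + 1] * fy * fx)

    gmax = float(ref.max())
    out = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(m):
            tol = dose_diff / 100.0 * (gmax if normalization == "global"
                                       else max(ref[i, j], 1e-12 * gmax))
            best = np.inf
            for dy, dx in offs:
                d = bilinear(i + dy / upsample, j + dx / upsample)
                if d is None:
                    continue
                dist = np.hypot(dy, dx) * step
                g2 = ((d - ref[i, j]) / tol) ** 2 + (dist / dta) ** 2
                best = min(best, g2)
            out[i, j] = np.sqrt(best)
    return out


# ---------------------------------------------------------------------------
# Classification oracles
# ---------------------------------------------------------------------------

def ward_agglomeration(dist):
    """Naive O(n^3) Ward agglomeration on a precomputed distance matrix.

    Uses the Lance-Williams recurrence for Ward linkage; returns the merge
    heights and the final partition function (cut at a threshold).
    """
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]
    next_id = n
    merges = []  # (a, b, height, members)

    def get(a, b):
        return d[(min(a, b), max(a, b))]

    while len(active) > 1:
        (a, b), h = min(d.items(), key=lambda kv: kv[1])
        if a not in active or b not in active:
            del d[(a, b)]
            continue
        members = active[a] + active[b]
        merges.append((a, b, h, list(members)))
        na, nb = len(active[a]), len(active[b])
        new = next_id
        next_id += 1
        for c in list(active):
            if c in (a, b):
                continue
            nc = len(active[c])
            dc = np.sqrt(((na + nc) * get(a, c) ** 2 + (nb + nc) * get(b, c) ** 2
                          - nc * h ** 2) / (na + nb + nc))
            d[(min(c, new), max(c, new))] = dc
        for key in [k for k in d if a in k or b in k]:
            del d[key]
        del active[a], active[b]
        active[new] = members
    return merges


def ward_cut(merges, n, threshold):
    """Flat partition (frozenset of frozensets) cutting merges at threshold."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    applied = {}
    next_id = n
    for a, b, h, members in merges:
        if h <= threshold:
            applied[next_id] = members
        next_id += 1
    # union leaves that co-occur in an applied merge
    for members in applied.values():
        first = members[0]
        for m in members[1:]:
            ra, rb = find(first), find(m)
            if ra != rb:
                parent[rb] = ra
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(i)
    return frozenset(frozenset(c) for c in clusters.values())


def auc_pair_counting(scores, labels):
    """AUC as the probability that a positive outscores a negative."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
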