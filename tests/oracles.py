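"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths of the package: fixed-step RK4
instead of adaptive library solvers, cumulative-sum entropy algebra instead
of per-class renormalization, and full enumeration instead of closed-form
null distributions.
"""

import math
from itertools import combinations

import numpy as np


def rk4_path(rhs, y0, t_end, dt, t_eval):
    """Fixed-step RK4 from t=0; returns the state at each requested time."""
    y = np.asarray(y0, dtype=float)
    t = 0.0
    out = []
    it = iter(sorted(t_eval))
    nxt = next(it, None)
    results = {}
    while nxt is not None and nxt <= 1e-12:
        results[nxt] = y.copy()
        nxt = next(it, None)
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        while nxt is not None and nxt <= t + 1e-9:
            results[nxt] = y.copy()
            nxt = next(it, None)
    return [results[tv] for tv in sorted(t_eval)]


def plasma_ode_oracle(rate, vd, kel, t_eval, dt=0.01):
    """Integrates dCp/dt = rate/vd - kel*Cp."""

    def rhs(t, y):
        return np.array([rate / vd - kel * y[0]])

    states = rk4_path(rhs, [0.0], max(t_eval), dt, t_eval)
    return np.array([s[0] for s in states])


def fdg_tissue_oracle(plasma_times, plasma_values, kin, onset, dt=0.01):
    """Two-compartment tissue curve via RK4 with its own logistic schedule."""

    def k3_t(t):
        sf = kin.suppression_factor
        if sf == 1.0:
            return kin.k3
        if kin.transition_tau == 0:
            gate = 1.0 if t < onset else 0.0
        else:
            gate = 1.0 / (1.0 + math.exp(-(onset - t) / kin.transition_tau))
        return kin.k3 * (sf + (1.0 - sf) * gate)

    def rhs(t, y):
        cp = np.interp(t, plasma_times, plasma_values)
        k3 = k3_t(t)
        return np.array([kin.k1 * cp - (kin.k2 + k3) * y[0], k3 * y[0]])

    states = rk4_path(rhs, [0.0, 0.0], plasma_times[-1], dt, plasma_times)
    free_trapped = np.array(states)
    cp = np.asarray(plasma_values)
    return free_trapped[:, 0] + free_trapped[:, 1] + kin.vb * cp


def gd_tissue_oracle(plasma_times, plasma_values, kin, dt=0.01):
    kep = kin.ktrans / kin.ve

    def rhs(t, y):
        return np.array([kep * (np.interp(t, plasma_times, plasma_values) - y[0])])

    states = rk4_path(rhs, [0.0], plasma_times[-1], dt, plasma_times)
    ce = np.array([s[0] for s in states])
    cb = (1.0 - kin.hct) * np.asarray(plasma_values)
    return kin.ve * ce + kin.vp * cb


def renyi_alpha_bruteforce(counts, alpha):
    """Exhaustive argmax of summed class entropies via cumulative-sum algebra.

    Uses H_a(q) = [log(sum h^a) - a*log(P)] / (1 - a) for the class
    distribution q = h/P, and the h*log(h) form of the Shannon limit --
    algebraically equivalent to, but structurally different from, the
    package's renormalize-then-score loop.  Ties break toward the lowest
    level via strict improvement in ascending order.
    """
    h = np.asarray(counts, dtype=float)
    p = h / h.sum()
    cum = np.cumsum(p)
    count_cum = np.cumsum(h)
    best_t, best = None, -np.inf
    for t in range(len(p)):
        # only occupied levels with mass on both sides are distinct partitions
        if h[t] == 0 or not 0 < count_cum[t] < count_cum[-1]:
            continue
        p1, p2 = cum[t], 1.0 - cum[t]
        lo, hi = p[: t + 1], p[t + 1 :]
        if alpha == 1.0:
            lo_nz, hi_nz = lo[lo > 0], hi[hi > 0]
            hb = -np.sum(lo_nz * np.log(lo_nz)) / p1 + math.log(p1)
            hf = -np.sum(hi_nz * np.log(hi_nz)) / p2 + math.log(p2)
        else:
            hb = (math.log(np.sum(lo**alpha)) - alpha * math.log(p1)) / (1 - alpha)
            hf = (math.log(np.sum(hi**alpha)) - alpha * math.log(p2)) / (1 - alpha)
        if hb + hf > best:
            best, best_t = hb + hf, t
    return best_t


def mann_whitney_exact_enumeration(x, y):
    """Exact two-tailed Mann-Whitney p by enumerating all group assignments.

    Returns (U of x, p).  p = min(1, 2*min(P(U <= u), P(U >= u))) over the
    permutation distribution of U for the pooled sample.
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(group1_idx):
        g1 = [pooled[i] for i in group1_idx]
        g2 = [pooled[i] for i in range(n1 + n2) if i not in group1_idx]
        u = 0.0
        for a in g1:
            for b in g2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(tuple(range(n1)))
    us = [u_stat(idx) for idx in combinations(range(n1 + n2), n1)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs + 1e-12) / total
    p_ge = sum(1 for u in us if u >= u_obs - 1e-12) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def cumtrapz_refined(times, values, factor=10):
    """Trapezoid integral after subdividing every segment ``factor``-fold."""
    out = [0.0]
    for i in range(1, len(times)):
        sub_t = np.linspace(times[i - 1], times[i], factor + 1)
        sub_v = np.interp(sub_t, times, values)
        seg = 0.0
        for j in range(1, len(sub_t)):
            seg += 0.5 * (sub_v[j] + sub_v[j - 1]) * (sub_t[j] - sub_t[j - 1])
        out.append(out[-1] + seg)
    return np.array(out)
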