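"""Independent reference implementations used to validate the package.

Everything here is deliberately written the slow, obvious way (explicit
loops, brute-force enumeration, generic optimisation) and shares no code
with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize, stats


def rebin_loop(freqs, power):
    """1 Hz re-binning by an explicit loop over Fourier frequencies
    (round half up)."""
    sums = {f: [] for f in range(1, 41)}
    for fr, po in zip(freqs, power):
        b = int(math.floor(fr + 0.5))
        if 1 <= b <= 40:
            sums[b].append(po)
    return np.array(
        [np.mean(sums[f]) if sums[f] else np.nan for f in range(1, 41)]
    )


def brute_decode(trial, signatures, conditions):
    """Nearest signature by explicit per-cell absolute-difference sums."""
    best, best_d = None, None
    for cond in conditions:
        sig = signatures[cond]
        total, any_cell = 0.0, False
        for idx in np.ndindex(trial.shape):
            tv, sv = trial[idx], sig[idx]
            if np.isfinite(tv) and np.isfinite(sv):
                total += abs(tv - sv)
                any_cell = True
        if not any_cell:
            return None
        if best_d is None or total < best_d:
            best, best_d = cond, total
    return best


def loo_decode_enumerated(psds, labels, conditions):
    """Full leave-one-out decode by explicit fold enumeration."""
    n = len(labels)
    correct, denom = 0, 0
    for t in range(n):
        train = [i for i in range(n) if i != t]
        sigs = {}
        for cond in conditions:
            members = [psds[i] for i in train if labels[i] == cond]
            stack = np.stack(members)
            with np.errstate(invalid="ignore"):
                sigs[cond] = np.nanmean(stack, axis=0)
        decoded = brute_decode(psds[t], sigs, conditions)
        if decoded is None:
            continue
        denom += 1
        correct += decoded == labels[t]
    return correct / denom if denom else np.nan


def flood_fill_components(mask, sensor_adj, freq_step=1):
    """Connected components of True points of a (sensor, freq) mask by BFS."""
    S, F = mask.shape
    seen = np.zeros_like(mask, bool)
    comps = []
    for s0 in range(S):
        for f0 in range(F):
            if not mask[s0, f0] or seen[s0, f0]:
                continue
            comp, queue = [], [(s0, f0)]
            seen[s0, f0] = True
            while queue:
                s, f = queue.pop()
                comp.append((s, f))
                for s2 in range(S):
                    if s2 != s and not sensor_adj[s, s2]:
                        continue
                    for f2 in range(max(0, f - freq_step), min(F, f + freq_step + 1)):
                        if (s2, f2) != (s, f) and mask[s2, f2] and not seen[s2, f2]:
                            seen[s2, f2] = True
                            queue.append((s2, f2))
            comps.append(sorted(comp))
    return comps


def paired_t_formula(a, b):
    """Textbook paired t from the difference scores."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[np.isfinite(d)]
    n = len(d)
    sd = math.sqrt(sum((x - d.mean()) ** 2 for x in d) / (n - 1))
    return d.mean() / (sd / math.sqrt(n))


def signflip_null_enumeration(diffs, sensor_adj, alpha=0.05, freq_step=1):
    """Null distribution of the maximum |cluster mass| over all 2^n sign
    patterns, built entirely from oracle components."""
    n = diffs.shape[0]
    out = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        d = diffs * np.array(signs)[:, None, None]
        S, F = d.shape[1:]
        t_map = np.zeros((S, F))
        p_map = np.ones((S, F))
        for s in range(S):
            for f in range(F):
                t = paired_t_formula(d[:, s, f], np.zeros(n))
                t_map[s, f] = t
                p_map[s, f] = 2 * stats.t.sf(abs(t), n - 1)
        best = 0.0
        for sign in (1, -1):
            mask = (p_map < alpha) & ((t_map > 0) if sign > 0 else (t_map < 0))
            for comp in flood_fill_components(mask, sensor_adj, freq_step):
                mass = abs(sum(t_map[s, f] for s, f in comp))
                best = max(best, mass)
        out.append(best)
    return np.array(out)


def primal_svr_fit(x, y, C=1.0, epsilon=0.1):
    """Linear epsilon-SVR by direct minimisation of the primal objective
    0.5 w^2 + C sum max(0, |w x + b - y| - eps) (convex in (w, b))."""

    def objective(wb):
        w, b = wb
        resid = np.abs(w * x + b - y)
        return 0.5 * w * w + C * np.sum(np.maximum(0.0, resid - epsilon))

    best = None
    for w0, b0 in [(0.0, 0.0), (1.0, 0.0), (-1.0, 0.0), (0.5, 0.5)]:
        res = optimize.minimize(
            objective, [w0, b0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x  # (w, b)


def jzs_bf_nct(t, n_eff, df, r=math.sqrt(2) / 2, grid=200001, span=12.0):
    """JZS BF10 via the noncentral-t route: average the likelihood of t over
    a Cauchy(0, r) prior on the standardised effect, against delta = 0.
    Dense trapezoidal quadrature on a wide symmetric grid.
    """
    delta = np.linspace(-span, span, grid)
    prior = stats.cauchy.pdf(delta, scale=r)
    like = stats.nct.pdf(t, df, delta * math.sqrt(n_eff))
    # the likelihood is negligible outside the grid for moderate t, so the
    # truncated integral matches the full prior integral
    num = np.trapezoid(like * prior, delta)
    return num / stats.t.pdf(t, df)
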