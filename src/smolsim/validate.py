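"""Statistical validation against analytic theory.

The package's accuracy contract is statistical: simulated trajectories are
compared with closed-form or mass-action expectations via Pearson's
chi-squared test, using analytic variances.  Because points along a single
trajectory are correlated, callers should feed the test statistically
independent quantities (per-molecule counts at one time, conditionally
independent increments, or replicate runs); :func:`chi2_report` itself just
implements the Pearson machinery with low-expectation bin merging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp


@dataclass
class ChiSquareReport:
    statistic: float
    dof: int
    pvalue: float
    n_merged: int

    @property
    def text(self) -> str:
        note = (f" ({self.n_merged} low-expectation bins merged)"
                if self.n_merged else "")
        return (f"chi2 = {self.statistic:.4g} on {self.dof} dof, "
                f"p = {self.pvalue:.4g}{note}")


def chi2_report(observed, expected, variance=None, merge_threshold=5.0):
    """Pearson chi-squared of observed vs expected with analytic variances.

    ``variance`` defaults to ``expected`` (Poisson counting).  Adjacent bins
    whose expected count falls below ``merge_threshold`` are merged (summing
    observed, expected and variance), as is standard for low-occupancy bins;
    the number of merges is noted in the report.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    var = exp.copy() if variance is None else np.asarray(variance, dtype=float)
    if obs.shape != exp.shape or obs.shape != var.shape:
        raise ValueError("observed, expected, variance must have equal length")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")

    o_bins, e_bins, v_bins = [], [], []
    acc_o = acc_e = acc_v = 0.0
    n_merged = 0
    for o, e, v in zip(obs, exp, var):
        acc_o += o
        acc_e += e
        acc_v += v
        if acc_e >= merge_threshold:
            o_bins.append(acc_o)
            e_bins.append(acc_e)
            v_bins.append(acc_v)
            acc_o = acc_e = acc_v = 0.0
        else:
            n_merged += 1
    if acc_e > 0 or acc_v > 0:
        if o_bins:
            o_bins[-1] += acc_o
            e_bins[-1] += acc_e
            v_bins[-1] += acc_v
            n_merged += 1
        else:
            o_bins, e_bins, v_bins = [acc_o], [acc_e], [acc_v]
    o_arr = np.array(o_bins)
    e_arr = np.array(e_bins)
    v_arr = np.array(v_bins)
    keep = v_arr > 0
    stat = float(np.sum((o_arr[keep] - e_arr[keep]) ** 2 / v_arr[keep]))
    dof = int(keep.sum())
    p = float(stats.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return ChiSquareReport(stat, dof, p, n_merged)


# ---------------------------------------------------------------------------
# mass-action references
# ---------------------------------------------------------------------------


def michaelis_menten_ode(E0, S0, V, k1, k2, k3, times):
    """Mass-action solution of E + S <-> ES -> E + P.

    Counts (not concentrations); ``k1`` in um^3/s, ``k2``/``k3`` in 1/s.
    Returns an array of shape (len(times), 4) with columns E, S, ES, P.
    """

    def rhs(t, y):
        E, S, ES = y
        v1 = k1 * E * S / V
        return [-v1 + (k2 + k3) * ES, -v1 + k2 * ES, v1 - (k2 + k3) * ES]

    times = np.asarray(times, dtype=float)
    sol = solve_ivp(rhs, (times[0], times[-1]), [E0, S0, 0.0], t_eval=times,
                    rtol=1e-10, atol=1e-8, method="LSODA")
    E, S, ES = sol.y
    P = (S0 - S) - ES
    return np.column_stack([E, S, ES, P])


def bimolecular_decay_ode(A0, B0, V, k, times):
    """Mass-action A + B -> 0: counts over time (exact closed forms)."""
    times = np.asarray(times, dtype=float)
    a0, b0 = A0 / V, B0 / V
    if abs(a0 - b0) < 1e-12 * max(a0, b0):
        a = a0 / (1.0 + k * a0 * times)
        return np.column_stack([a * V, a * V])
    d = b0 - a0
    e = np.exp(-k * d * times)
    a = a0 * d * e / (b0 - a0 * e)
    b = a + d
    return np.column_stack([a * V, b * V])
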