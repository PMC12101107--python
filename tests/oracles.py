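"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle is a direct transcription of the defining formula (or an
exhaustive grid search), deliberately avoiding the library code paths it
checks.
"""

import math

import numpy as np


def t_paired_oracle(day: np.ndarray, night: np.ndarray) -> tuple[float, int]:
    d = np.asarray(night, float) - np.asarray(day, float)
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    return mean / (sd / math.sqrt(n)), n - 1


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym)
                 / math.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2)))


def cv_oracle(values: np.ndarray) -> float:
    v = np.asarray(values, float)
    n = len(v)
    mean = sum(v) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))
    return 100.0 * sd / mean


def acf_oracle(values: np.ndarray, lag: int) -> float:
    x = np.asarray(values, float)
    xm = x - x.mean()
    return float(np.sum(xm[: len(x) - lag] * xm[lag:]) / np.sum(xm ** 2))


def anova_oracle(groups: list[np.ndarray]) -> tuple[float, int, int]:
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def grid_cosinor_oracle(
    t: np.ndarray,
    y: np.ndarray,
    trial_period: float,
    phi_resolution: float = 0.5,
    amp_resolution: float = 1e-3,
) -> tuple[float, float, float]:
    """Exhaustive (M, A, phi) search at the stated resolutions.

    The mesor that minimises the SSR for fixed (A, phi) is the mean of
    ``y - A cos(...)``, so the search is over the (A, phi) plane with M
    eliminated analytically — the same optimum as a 3-d grid, without the
    third loop.  A coarse pass locates the basin, a fine pass resolves it at
    ``phi_resolution`` degrees and ``amp_resolution`` amplitude units.
    Returns (mesor, amplitude, acrophase_deg in (-360, 0]).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    omega = 2.0 * math.pi / trial_period
    a_max = 2.0 * max(np.max(np.abs(y - y.mean())), amp_resolution)

    def ssr_grid(amps: np.ndarray, phis_deg: np.ndarray):
        # model peak at t_peak = -phi*tau/360
        tp = -phis_deg[:, None] * trial_period / 360.0  # (P,1)
        cosmat = np.cos(omega * (t[None, :] - tp))      # (P,n)
        # residual for each (A, phi): y - A*cos - M(A,phi)
        best = None
        for ai, a in enumerate(amps):
            r = y[None, :] - a * cosmat
            r = r - r.mean(axis=1, keepdims=True)
            ssr = np.sum(r * r, axis=1)
            j = int(np.argmin(ssr))
            if best is None or ssr[j] < best[0]:
                best = (float(ssr[j]), float(a), float(phis_deg[j]))
        return best

    coarse_phi = np.arange(-360.0 + 2.0, 0.0 + 1e-9, 2.0)
    coarse_amp = np.linspace(0.0, a_max, 101)
    _, a0, p0 = ssr_grid(coarse_amp, coarse_phi)

    step_a = coarse_amp[1] - coarse_amp[0]
    fine_phi = np.arange(p0 - 4.0, p0 + 4.0 + 1e-9, phi_resolution)
    fine_phi = np.where(fine_phi > 0, fine_phi - 360.0, fine_phi)
    fine_phi = np.where(fine_phi <= -360.0, fine_phi + 360.0, fine_phi)
    fine_amp = np.arange(max(a0 - 1.5 * step_a, 0.0),
                         a0 + 1.5 * step_a, amp_resolution)
    ssr, a1, p1 = ssr_grid(fine_amp, fine_phi)
    cos1 = np.cos(omega * (t + p1 * trial_period / 360.0))
    m1 = float((y - a1 * cos1).mean())
    return m1, a1, p1
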