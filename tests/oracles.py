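"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-derive results with the simplest possible method
(python loops, dense quadrature) and never call the implementation paths
they are used to check.
"""

import numpy as np
from scipy.special import gammaln

from tmtgaze import px_to_deg


def oracle_scanner(samples, params, geom):
    """Sample-by-sample threshold scanner for event boundaries."""
    t = samples["t_ms"].to_numpy(float)
    deg = px_to_deg(samples[["x_px", "y_px"]].to_numpy(float), geom)
    n = len(t)
    speed = [0.0] * n
    for i in range(1, n - 1):
        dt = (t[i + 1] - t[i - 1]) / 1000.0
        dx = deg[i + 1, 0] - deg[i - 1, 0]
        dy = deg[i + 1, 1] - deg[i - 1, 1]
        speed[i] = (dx * dx + dy * dy) ** 0.5 / dt
    if n >= 3:
        speed[0], speed[-1] = speed[1], speed[-2]
    accel = [0.0] * n
    for i in range(1, n - 1):
        accel[i] = (speed[i + 1] - speed[i - 1]) / ((t[i + 1] - t[i - 1]) / 1000.0)
    if n >= 3:
        accel[0], accel[-1] = accel[1], accel[-2]
    labels = [
        speed[i] > params.vel_thresh or abs(accel[i]) > params.acc_thresh
        for i in range(n)
    ]
    events = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            onset = t[start]
            offset = t[i] if i < n else t[-1]
            if offset > onset:
                events.append(("saccade" if labels[start] else "fixation", onset, offset))
            start = i
    return events


def brute_force_bf(table, model, r, response="y", n_nodes=100_000):
    """Dense log-spaced trapezoid over g on [1e-6, 1e6] for the JZS BF."""
    y = table[response].to_numpy(float)
    n = len(y)
    yc = y - y.mean()
    yty = yc @ yc
    if model == "fixed":
        vals = table["instruction"].to_numpy()
        levels = np.unique(vals)
        a = len(levels)
        Z = (vals[:, None] == levels[None, :]).astype(float)
        ev, evec = np.linalg.eigh(np.eye(a) - 1.0 / a)
        X = Z @ evec[:, ev > 0.5]
    else:
        vals = table["subject"].to_numpy()
        levels = np.unique(vals)
        X = (vals[:, None] == levels[None, :]).astype(float)
    Xc = X - X.mean(axis=0)
    gs = np.logspace(-6, 6, n_nodes)
    b = Xc.T @ yc
    XtX = Xc.T @ Xc
    out = np.empty(n_nodes)
    for i, g in enumerate(gs):
        M = np.eye(Xc.shape[1]) + g * XtX
        _, ld = np.linalg.slogdet(M)
        quad = g * (b @ np.linalg.solve(M, b))
        logbf = -0.5 * ld - (n - 1) / 2.0 * np.log(1 - quad / yty)
        logpr = (0.5 * np.log(r**2 / 2) - gammaln(0.5) - 1.5 * np.log(g)
                 - r**2 / (2 * g))
        out[i] = np.exp(logbf + logpr)
    return np.trapezoid(out, gs)


def half_table(rng, beta=0.0, sd_u=1.0, sd_e=1.0, n=12, test_type="A"):
    """Per-test-half long table: n subjects x {accuracy, speed}."""
    import pandas as pd

    subj = np.repeat([f"s{i:02d}" for i in range(n)], 2)
    instr = np.tile(["accuracy", "speed"], n)
    u = np.repeat(rng.normal(0, sd_u, n), 2)
    y = beta * (instr == "speed") + u + rng.normal(0, sd_e, 2 * n)
    return pd.DataFrame(
        {"subject": subj, "test_type": test_type, "instruction": instr, "y": y}
    )
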