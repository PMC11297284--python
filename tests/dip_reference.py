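"""Independent dip-statistic reference used by the test suite.

The reference computes the dip from its definition: for each candidate mode,
the distance to the nearest unimodal CDF is the optimum of a small linear
program (monotonicity, convexity left of the mode, concavity right of it, an
optional atom at the mode, and a +/- d band around the empirical CDF); the
dip is the minimum over modes.  This shares no code or algorithmic structure
with the greatest-convex-minorant iteration in ``phenopop._dip``.

Reference values for the seeded sample set below are frozen in
``tests/data/dip_oracle.json`` so the comparison does not require re-solving
the LPs on every run; ``regenerate()`` rebuilds the file.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
from scipy.optimize import linprog

DATA = pathlib.Path(__file__).parent / "data" / "dip_oracle.json"
N_SAMPLES = 50
BASE_SEED = 7000


def dip_lp(x: np.ndarray) -> float:
    """Dip by direct minimisation over unimodal CDFs (LP per mode)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    v, counts = np.unique(x, return_counts=True)
    u = v.size
    if u == 1:
        return 1.0 / (2.0 * n)
    c = np.cumsum(counts) / n             # F(v_j)
    cl = np.concatenate([[0.0], c[:-1]])  # F(v_j^-)

    best = np.inf
    for m in range(u):
        nv = u + 2          # g_0..g_{u-1}, gL (left limit at mode), d
        iL, iD = u, u + 1
        A, b = [], []

        def row():
            return np.zeros(nv)

        for j in range(u):  # band lower at values: g_j >= c_j - d
            r = row(); r[j] = -1.0; r[iD] = -1.0
            A.append(r); b.append(-c[j])
        for j in range(u):  # band upper at left limits
            r = row()
            r[iL if j == m else j] = 1.0
            r[iD] = -1.0
            A.append(r); b.append(cl[j])
        r = row(); r[m] = 1.0; r[iD] = -1.0   # |F(v_m) - g_m| <= d
        A.append(r); b.append(c[m])
        for j in range(u - 1):                # monotone through the mode atom
            r = row()
            if j + 1 == m:
                r[j] = 1.0; r[iL] = -1.0
            else:
                r[j] = 1.0; r[j + 1] = -1.0
            A.append(r); b.append(0.0)
        r = row(); r[iL] = 1.0; r[m] = -1.0
        A.append(r); b.append(0.0)
        r = row(); r[u - 1] = 1.0
        A.append(r); b.append(1.0)
        r = row(); r[0] = -1.0
        A.append(r); b.append(0.0)

        def gcol(j):
            return iL if j == m else j

        for j in range(1, m):      # convex left of mode: slopes nondecreasing
            d0 = v[j] - v[j - 1]
            d1 = v[j + 1] - v[j]
            r = row()
            r[gcol(j - 1)] += -1.0 / d0
            r[gcol(j)] += 1.0 / d0 + 1.0 / d1
            r[gcol(j + 1)] += -1.0 / d1
            A.append(r); b.append(0.0)
        for j in range(m + 1, u - 1):  # concave right of mode
            d0 = v[j] - v[j - 1]
            d1 = v[j + 1] - v[j]
            r = row()
            r[j - 1] += 1.0 / d0
            r[j] += -1.0 / d0 - 1.0 / d1
            r[j + 1] += 1.0 / d1
            A.append(r); b.append(0.0)

        cvec = np.zeros(nv)
        cvec[iD] = 1.0
        res = linprog(cvec, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(None, None)] * nv, method="highs")
        if not res.success:
            raise RuntimeError(f"dip LP failed at mode {m}: {res.message}")
        best = min(best, res.fun)
    return float(best)


def oracle_sample(i: int) -> np.ndarray:
    """Deterministic sample #i (n <= 200, varied shapes incl. heavy ties)."""
    rng = np.random.default_rng(BASE_SEED + i)
    n = int(rng.integers(10, 201))
    kind = i % 5
    if kind == 0:
        return rng.normal(size=n)
    if kind == 1:
        return rng.uniform(size=n)
    if kind == 2:
        half = n // 2
        return np.concatenate(
            [rng.normal(-2.0, 1.0, half), rng.normal(2.0, 1.0, n - half)]
        )
    if kind == 3:
        return rng.lognormal(1.0, 0.6, size=n)
    return np.round(rng.normal(size=n), 1)


def anchor_cases():
    """Cases with exact published dip values."""
    return [
        ("two_point_50_50", np.array([0.0] * 50 + [1.0] * 50), 0.25),
        ("uniform_grid_50", (np.arange(1, 51) - 0.5) / 50, 1.0 / 100.0),
    ]


def load_frozen() -> dict[str, float]:
    return json.loads(DATA.read_text())


def regenerate() -> None:
    values = {str(i): dip_lp(oracle_sample(i)) for i in range(N_SAMPLES)}
    for name, x, _ in anchor_cases():
        values[name] = dip_lp(x)
    DATA.parent.mkdir(exist_ok=True)
    DATA.write_text(json.dumps(values, indent=1))


if __name__ == "__main__":
    regenerate()
    print(f"wrote {DATA}")
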