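"""Independent oracles shared between module and acceptance tests.

Everything here deliberately re-derives results along a different code path
than the package (explicit loops, closed forms, batched Newton iterations) so
the tests compare two independent routes to the same quantity.
"""

import numpy as np
import pandas as pd
from scipy.special import expit


def brute_force_scores(dosages, af, weights, missing="mean_impute"):
    """Double-loop weighted dosage sum."""
    n, m = dosages.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(m):
            x = dosages[i, j]
            if np.isnan(x):
                x = 2.0 * af[j] if missing == "mean_impute" else 0.0
            out[i] += weights[j] * x
    return out


def brute_force_prune(pvals, chrom, pos, ids, r2, r2_max, window_bp):
    """Greedy clumping from the definition: ascending p, ties by (chrom,pos,id);
    accept iff r2 with every accepted same-chromosome variant in the window
    stays at or below r2_max. ``r2`` is the full pairwise matrix."""
    order = sorted(range(len(pvals)),
                   key=lambda i: (pvals[i], chrom[i], pos[i], ids[i]))
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if chrom[i] == chrom[j] and abs(pos[i] - pos[j]) <= window_bp:
                if r2[i, j] > r2_max:
                    ok = False
        if ok:
            kept.append(i)
    return [ids[i] for i in kept]


def batched_logistic_wald(x, y):
    """Per-replicate logistic Wald z for the slope; x, y are (reps, n).

    Newton–Raphson on (intercept, slope) vectorized across replicates.
    """
    reps, n = x.shape
    a = np.zeros(reps)
    b = np.zeros(reps)
    for _ in range(25):
        eta = a[:, None] + b[:, None] * x
        p = expit(eta)
        w = p * (1.0 - p)
        r = y - p
        g0, g1 = r.sum(1), (r * x).sum(1)
        h00, h01 = w.sum(1), (w * x).sum(1)
        h11 = (w * x * x).sum(1)
        det = h00 * h11 - h01 * h01
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        a, b = a + da, b + db
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-10:
            break
    eta = a[:, None] + b[:, None] * x
    w = expit(eta) * (1.0 - expit(eta))
    h00, h01 = w.sum(1), (w * x).sum(1)
    h11 = (w * x * x).sum(1)
    var_b = h00 / (h00 * h11 - h01 * h01)
    return b / np.sqrt(var_b)


def make_survival_frame(time, event, entry=None, death=None):
    """Minimal cohort frame accepted by the survival-evaluation functions."""
    n = len(time)
    return pd.DataFrame({
        "sample_id": [f"x{i}" for i in range(n)],
        "entry_age": np.zeros(n) if entry is None else np.asarray(entry, float),
        "event_age": np.asarray(time, float),
        "bc_event": np.asarray(event, int),
        "death_event": np.zeros(n, int) if death is None
        else np.asarray(death, int),
        "prevalent": np.zeros(n, int),
    })
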