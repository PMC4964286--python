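"""Synthetic data with the exact generative structure the model assumes.

Stream discipline
-----------------
Both generators consume the same uniform stream: three uniforms per subject
in the order (latent status D, joint scale pair (T1, T2), expert test T3).
``simulate_counts(params, n, seed)`` is defined as the pattern aggregation
of ``simulate_subject_level(params, n, seed)``, so the two agree exactly
under a shared seed, and the aggregated counts are one multinomial(n, p)
draw over the eight cell probabilities.

The (T1, T2) pair is drawn by inverse-CDF over the four-cell conditional
table in fixed order (1,1), (1,0), (0,1), (0,0), making results
reproducible across platforms given the same uniform stream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CrossClassifiedCounts
from .model import ModelParameters, _cond4


def simulate_subject_level(
    params: ModelParameters, n: int, seed: int
) -> pd.DataFrame:
    """Per-subject records (D, T1, T2, T3), including the latent truth.

    D ~ Bernoulli(prevalence); (T1, T2) from the conditional 2x2 table given
    D (which carries the covariance C+ or C-); T3 independently given D.
    """
    params.validate()
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    u = rng.random((n, 3))
    se1, se2, se3 = params.se
    sp1, sp2, sp3 = params.sp

    d = (u[:, 0] < params.prevalence).astype(np.int8)

    # cumulative conditional tables over (1,1),(1,0),(0,1),(0,0)
    cum_pos = np.cumsum(_cond4(se1, se2, params.cov_pos))
    cum_neg = np.cumsum(_cond4(1.0 - sp1, 1.0 - sp2, params.cov_neg))
    idx_pos = np.searchsorted(cum_pos, u[:, 1], side="right")
    idx_neg = np.searchsorted(cum_neg, u[:, 1], side="right")
    idx = np.where(d == 1, idx_pos, idx_neg).clip(max=3)
    t1 = (idx <= 1).astype(np.int8)          # cells (1,1) and (1,0)
    t2 = ((idx == 0) | (idx == 2)).astype(np.int8)

    p3 = np.where(d == 1, se3, 1.0 - sp3)
    t3 = (u[:, 2] < p3).astype(np.int8)

    return pd.DataFrame({"D": d, "T1": t1, "T2": t2, "T3": t3})


def simulate_counts(
    params: ModelParameters, n: int, seed: int
) -> CrossClassifiedCounts:
    """One multinomial draw of n subjects over the 8 cell probabilities.

    Implemented as the aggregation of :func:`simulate_subject_level` under
    the shared stream discipline, so subject-level and count-level draws
    with the same seed are consistent by construction.
    """
    subjects = simulate_subject_level(params, n, seed)
    return aggregate_subjects(subjects)


def aggregate_subjects(subjects: pd.DataFrame) -> CrossClassifiedCounts:
    """Collapse per-subject records into the 8-cell canonical count vector."""
    t1 = subjects["T1"].to_numpy()
    t2 = subjects["T2"].to_numpy()
    t3 = subjects["T3"].to_numpy()
    # canonical index: (1,1,1) -> 0 ... (0,0,0) -> 7
    idx = (1 - t1) * 4 + (1 - t2) * 2 + (1 - t3)
    counts = np.bincount(idx, minlength=8)
    return CrossClassifiedCounts(tuple(int(c) for c in counts))


def empirical_accuracy(subjects: pd.DataFrame) -> dict[str, float]:
    """Truth-known empirical Se/Sp/prevalence from subject-level records.

    Converges to the generating parameters as n grows; used for recovery
    checks against latent-class estimates.
    """
    d = subjects["D"].to_numpy().astype(bool)
    out: dict[str, float] = {"prevalence": float(d.mean())}
    for i, col in enumerate(("T1", "T2", "T3"), start=1):
        t = subjects[col].to_numpy().astype(bool)
        if d.any():
            out[f"Se{i}"] = float(t[d].mean())
        if (~d).any():
            out[f"Sp{i}"] = float((~t[~d]).mean())
    return out
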