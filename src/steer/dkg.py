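"""Differential kinetic gene (DKG) analysis between two cell groups.

A gene is a DKG when at least one kinetic rate (α, β, γ) differs
significantly between groups (two-sided rank-sum test, Benjamini–Hochberg
adjusted within each rate across genes).  DKGs are classified by the number
of significant rates — SDR (one), DDR (two), TDR (three) — and α/γ DDR pairs
are split into synchronous shifts (expression-reinforcing: ↑α with ↓γ or
vice versa) and asynchronous ones.  A DEG test (same procedure on spliced
expression) runs alongside for overlap statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm
from statsmodels.stats.multitest import multipletests

RATES = ("alpha", "beta", "gamma")


def _rank_tests(matrix: np.ndarray, mask1: np.ndarray, mask2: np.ndarray):
    """Per-column two-sided rank-sum p-values and median differences."""
    g = matrix.shape[1]
    pvals = np.ones(g)
    delta = np.zeros(g)
    x1, x2 = matrix[mask1], matrix[mask2]
    for j in range(g):
        a, b = x1[:, j], x2[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[j] = 1.0
        else:
            pvals[j] = mannwhitneyu(a, b, alternative="two-sided").pvalue
        delta[j] = np.median(b) - np.median(a)
    return pvals, delta


def test_kinetic_rates(
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    S: np.ndarray,
    groups: np.ndarray,
    gene_names=None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Rate-wise and expression-wise differential tests between two groups.

    ``groups`` is a per-cell binary labeling (exactly two distinct values,
    each with ≥ 3 cells).  Returns one row per gene with p/q-values, effect
    directions (sign of median difference, group2 − group1), the DKG
    category, the SDR rate, the DDR sync/async call, and the DEG flag.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("groups must contain exactly two labels")
    mask1, mask2 = groups == uniq[0], groups == uniq[1]
    if mask1.sum() < 3 or mask2.sum() < 3:
        raise ValueError("each group needs at least 3 cells")

    mats = {"alpha": alpha, "beta": beta, "gamma": gamma, "deg": S}
    g = np.asarray(alpha).shape[1]
    if gene_names is None:
        gene_names = np.array([f"gene_{j}" for j in range(g)])
    out = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    for name, mat in mats.items():
        p, d = _rank_tests(np.asarray(mat, dtype=float), mask1, mask2)
        q = multipletests(p, method="fdr_bh")[1]
        out[f"p_{name}"] = p
        out[f"q_{name}"] = q
        out[f"dir_{name}"] = np.sign(d)
    out["sig_alpha"] = out["q_alpha"] < q_threshold
    out["sig_beta"] = out["q_beta"] < q_threshold
    out["sig_gamma"] = out["q_gamma"] < q_threshold
    out["is_deg"] = out["q_deg"] < q_threshold
    return classify_dkg(out)


def classify_dkg(result: pd.DataFrame) -> pd.DataFrame:
    """Assign DKG category (none/SDR/DDR/TDR), SDR rate, and DDR sync/async.

    Synchronous DDR: the two shifted rates reinforce the same steady-state
    expression change.  α counts +1·sign(Δα), γ counts −1·sign(Δγ), β counts
    0 (since s_ss = α/γ); pairs involving β are therefore asynchronous by
    convention.
    """
    result = result.copy()
    n_sig = (
        result["sig_alpha"].astype(int)
        + result["sig_beta"].astype(int)
        + result["sig_gamma"].astype(int)
    )
    result["n_sig_rates"] = n_sig
    result["category"] = np.select(
        [n_sig == 1, n_sig == 2, n_sig == 3], ["SDR", "DDR", "TDR"], default="none"
    )

    sdr_rate = []
    for _, row in result.iterrows():
        if row["category"] == "SDR":
            for r in RATES:
                if row[f"sig_{r}"]:
                    sdr_rate.append(r)
                    break
        else:
            sdr_rate.append("n/a")
    result["sdr_rate"] = sdr_rate

    sync = []
    for _, row in result.iterrows():
        if row["category"] != "DDR":
            sync.append("n/a")
        elif row["sig_alpha"] and row["sig_gamma"]:
            sync.append(
                "sync" if np.sign(row["dir_alpha"]) == -np.sign(row["dir_gamma"])
                else "async"
            )
        else:
            sync.append("async")  # β-involving pairs: β neutral for s_ss
    result["ddr_sync"] = sync
    return result


def overlap_stats(deg_set, dkg_set, universe):
    """Counts and integer percentages for DEG/DKG overlap.

    Percentages are rounded half-away-from-zero; empty sets give None.
    """
    deg_set, dkg_set, universe = set(deg_set), set(dkg_set), set(universe)
    if not deg_set <= universe or not dkg_set <= universe:
        raise ValueError("sets must lie within the universe")
    overlap = deg_set & dkg_set

    def pct(part, whole):
        if whole == 0:
            return None
        return int(np.floor(100.0 * part / whole + 0.5))

    return {
        "n_deg": len(deg_set),
        "n_dkg": len(dkg_set),
        "n_overlap": len(overlap),
        "pct_of_deg": pct(len(overlap), len(deg_set)),
        "pct_of_dkg": pct(len(overlap), len(dkg_set)),
    }


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int):
    """Pooled two-proportion z-test, two-tailed.

    Returns ``(z, p)``; ``(nan, nan)`` when the pooled proportion is 0 or 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if x1 > n1 or x2 > n2 or x1 < 0 or x2 < 0:
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return float("nan"), float("nan")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2 * norm.sf(abs(z)))


def time_pattern_classify(
    expression: np.ndarray,
    t: np.ndarray,
    n_bins: int = 5,
    tolerance: float = 0.1,
) -> str:
    """Classify a gene's trend along latent time.

    Bin means along t (equal-count bins); ``tolerance`` is the minimum
    range, as a fraction of the mean absolute level (floor 1e-8), for a
    pattern to count as non-Flat.  Growth/Recession are monotone trends;
    Peak/Trough need an interior extremum exceeding both endpoints.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    from .velocity_analysis import bin_series

    means = bin_series(np.asarray(expression, dtype=float), np.asarray(t), n_bins)
    scale = max(np.abs(means).mean(), 1e-8)
    tol = tolerance * scale
    if np.ptp(means) <= tol:
        return "Flat"
    diffs = np.diff(means)
    if np.all(diffs >= -tol / n_bins):
        return "Growth"
    if np.all(diffs <= tol / n_bins):
        return "Recession"
    interior = means[1:-1]
    if interior.max() >= means[0] + tol and interior.max() >= means[-1] + tol:
        return "Peak"
    if interior.min() <= means[0] - tol and interior.min() <= means[-1] - tol:
        return "Trough"
    return "Flat"
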