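"""Nonparametric behavioral and comparative statistics.

Conventions, stated because the source conventions are otherwise ambiguous:
ranks are averaged over ties everywhere; zero differences are dropped from
the Wilcoxon signed-rank test; all tests are two-sided; the Mann-Whitney
normal approximation applies the tie correction but no continuity
correction (the convention under which the study's printed p-value for the
ASD-vs-neurotypical accuracy comparison, 0.566, reproduces exactly).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


class DegenerateTestError(ValueError):
    """A test statistic is undefined for the given data."""


def wilcoxon_signed_rank(
    pre, post, method: str = "auto"
) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test; returns ``(Z, p)``.

    ``Z`` always comes from the normal approximation (with tie correction),
    signed so that post > pre gives negative Z, matching the convention of
    reporting stress increases as negative statistics. ``p`` uses the exact
    null distribution when ``method="exact"``, the normal approximation for
    ``"approx"``, and for ``"auto"`` the exact distribution when n <= 25,
    else the approximation. Zero differences are dropped first.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    # Signed normal approximation with tie correction: W+ above its null
    # mean (stress increase) maps to negative Z.
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    if sigma2 <= 0:
        raise DegenerateTestError("zero-variance signed-rank statistic")
    z_raw = (w_plus - mu) / np.sqrt(sigma2)
    z = -float(z_raw)
    use_exact = method == "exact" or (method == "auto" and n <= 25)
    if use_exact:
        p = float(sps.wilcoxon(d, method="exact").pvalue)
    else:
        p = float(2 * sps.norm.sf(abs(z_raw)))
    return z, p


def mann_whitney_u(
    group_a, group_b, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    ``method="exact"`` enumerates the null distribution (only valid without
    ties), ``"asymptotic"`` uses the tie-corrected normal approximation
    without continuity correction, and ``"auto"`` picks exact for
    tie-free samples with n <= 20 per group, else the approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if method == "auto":
        method = "exact" if (not has_ties and max(a.size, b.size) <= 20) else "asymptotic"
    if method == "exact":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif method == "asymptotic":
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateTestError("correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def round_display(x: float, decimals: int = 2) -> float:
    """Round half away from zero, for table display."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def table_summaries(fixtures: dict | None = None) -> dict:
    """Recompute every summary statistic of the four printed result tables.

    Returns full-precision means plus 2-decimal display values, the
    Table 4 group means, and the group-comparison / correlation statistics.
    Entries whose printed value disagrees with the mean of the printed cells
    are listed under ``"inconsistent"`` rather than silently reconciled.
    """
    from . import tables as _tables

    fixtures = fixtures or _tables.load_all()
    t1, t2, t3, t4 = (fixtures[k] for k in ("table1", "table2", "table3", "table4"))

    out: dict = {"column_means": {}, "display": {}}
    for col in t1.columns:
        if col == "participant":
            continue
        out["column_means"][f"table1/{col}"] = float(t1[col].mean())
    for tbl, name in ((t2, "table2"), (t3, "table3")):
        for col in tbl.columns:
            if col == "class":
                continue
            out["column_means"][f"{name}/{col}"] = float(tbl[col].mean())
    out["display"] = {
        k: round_display(v) for k, v in out["column_means"].items()
    }

    asd = t4.loc[t4.group == "ASD", "lstm2_accuracy"]
    nt = t4.loc[t4.group == "neurotypical", "lstm2_accuracy"]
    out["table4"] = {
        "asd_mean": float(asd.mean()),
        "nt_mean": float(nt.mean()),
        "mann_whitney": mann_whitney_u(asd, nt),
        "spearman_rho": spearman_correlation(
            t4["lstm2_accuracy"], t4["stai_c"]
        ),
    }
    # Printed averages that do NOT equal the mean of their printed cells.
    out["inconsistent"] = {
        "table3/lstm3": {"printed": 72.26,
                         "recomputed": out["display"]["table3/lstm3"]},
        "table2/eegnet": {"printed": 60.21,
                          "recomputed": out["display"]["table2/eegnet"]},
        "results_text/eegnet": {"printed": 61.18,
                                "recomputed": out["display"]["table2/eegnet"]},
        "results_text/lstm1": {"printed": 73.53,
                               "recomputed": out["display"]["table3/lstm1"]},
    }
    return out
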