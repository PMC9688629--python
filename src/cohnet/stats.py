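"""Statistical inference for the connectivity pipeline.

Three families of procedures:

* Nonparametric permutation tests for group differences in network
  measures: the observed mean difference is compared against an
  empirical null built by randomly reallocating all values into two
  groups (default 30,000 permutations); the 95th percentile of the null
  is the one-tailed critical value. Nodal comparisons are Bonferroni
  corrected.
* Edge-wise two-sample t-tests with maximal-statistic permutation
  correction (default 5,000 randomizations): each permutation relabels
  whole subjects and records the maximum |t| over all edges, and the
  95th percentile of that maximum is the familywise-corrected
  threshold.
* Classical behavioral analysis: randomized-block (participant +
  exertion level) ANOVA on cell means, Tukey HSD pairwise comparisons
  with simultaneous confidence intervals and a compact letter display,
  and %MVC normalization of forces.

Reference constants at the bottom hold the published behavioral summary
statistics of the motivating isometric arm-exertion study (level means,
ANOVA sums of squares); they are inputs for deterministic reproduction
of that study's behavioral tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import BehavioralRecord, behavior_to_frame


# ---------------------------------------------------------------------------
# Permutation test for group mean differences
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null_quantile_95: float
    p_value: float
    n_permutations: int
    seed: int | None
    tail: str                           # "one" | "two"
    exhaustive: bool = False
    p_upper: float = float("nan")       # P(null >= observed)
    p_lower: float = float("nan")       # P(null <= observed)


def permutation_mean_difference(values_a, values_b, n_perm: int = 30000,
                                tail: str = "one",
                                seed: int = 0) -> PermutationResult:
    """Permutation test for mean(a) - mean(b) by pooled relabeling.

    The pooled values are reallocated into two groups of the original
    sizes. When the number of distinct reallocations C(n_a+n_b, n_a) is
    at most ``n_perm`` the null is enumerated exhaustively (exact p);
    otherwise ``n_perm`` seeded random reallocations are drawn and the
    add-one rule p = (b+1)/(n_perm+1) is used, so p > 0 always.

    One-tailed tests use the fixed upper tail (H1: mean(a) > mean(b)),
    with the null's 95th percentile as the critical value -- group order
    therefore encodes the hypothesized direction. Both one-sided
    p-values are always reported (``p_upper``, ``p_lower``); choosing a
    tail from the observed sign after the fact would double the type-I
    error. Two-tailed: |null| >= |observed|.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = float(a.mean() - b.mean())

    n_total = math.comb(n, na)
    exhaustive = n_total <= n_perm
    if exhaustive:
        total = pooled.sum()
        null = np.empty(n_total)
        for k, idx in enumerate(itertools.combinations(range(n), na)):
            sa = pooled[list(idx)].sum()
            null[k] = sa / na - (total - sa) / (n - na)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        # vectorized reallocation: argsort of uniforms = random permutation
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        perm_a = pooled[order[:, :na]]
        total = pooled.sum()
        sa = perm_a.sum(axis=1)
        null = sa / na - (total - sa) / (n - na)

    tol = 1e-12 * max(1.0, float(np.abs(pooled).max(initial=0.0)))
    n_eff = n_total if exhaustive else n_perm

    def _p(count):
        return count / n_total if exhaustive else (count + 1) / (n_perm + 1)

    p_upper = _p(int(np.sum(null >= observed - tol)))
    p_lower = _p(int(np.sum(null <= observed + tol)))
    if tail == "two":
        p = _p(int(np.sum(np.abs(null) >= abs(observed) - tol)))
        crit = float(np.percentile(np.abs(null), 95))
    else:
        p = p_upper
        crit = float(np.percentile(null, 95))
    return PermutationResult(observed, crit, float(p), n_eff,
                             None if exhaustive else seed, tail,
                             exhaustive=exhaustive,
                             p_upper=float(p_upper), p_lower=float(p_lower))


# ---------------------------------------------------------------------------
# Edge-wise maximal-statistic test
# ---------------------------------------------------------------------------

@dataclass
class EdgeComparisonResult:
    t_map: np.ndarray                   # (n, n) symmetric observed t
    max_null: np.ndarray                # (n_perm,) max |t| per permutation
    corrected_threshold: float          # 95th percentile of max_null
    significant_edges: list             # [(i, j, sign)], sign in {+1, -1}
    corrected_p: np.ndarray             # (n, n) FWER-corrected p per edge
    n_permutations: int
    seed: int


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance independent-sample t, vectorized over columns."""
    nx_, ny = x.shape[0], y.shape[0]
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx = x.var(axis=0, ddof=1)
    vy = y.var(axis=0, ddof=1)
    sp2 = ((nx_ - 1) * vx + (ny - 1) * vy) / (nx_ + ny - 2)
    denom = np.sqrt(sp2 * (1.0 / nx_ + 1.0 / ny))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mx - my) / np.where(denom > 0, denom, 1.0),
                     0.0)
    return t


def maximal_statistic_edge_test(group_a, group_b, n_perm: int = 5000,
                                seed: int = 0,
                                alpha: float = 0.05) -> EdgeComparisonResult:
    """Edge-wise independent-sample t-tests, familywise corrected by the
    permutation distribution of the maximal statistic.

    ``group_a`` and ``group_b`` are collections of symmetric matrices
    (one per subject). Each permutation relabels whole subjects, the
    maximum |t| over the upper-triangle edges is recorded, and edges
    with |t_observed| above the (1-alpha) quantile of that maximum are
    significant, signed by the direction of the observed difference
    (a > b positive).
    """
    a = np.stack([m.C if hasattr(m, "C") else np.asarray(m, float)
                  for m in group_a])
    b = np.stack([m.C if hasattr(m, "C") else np.asarray(m, float)
                  for m in group_b])
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("matrix dimensions differ between groups")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 matrices per group for a t-test")
    n = a.shape[1]
    iu, ju = np.triu_indices(n, 1)
    xa = a[:, iu, ju]
    xb = b[:, iu, ju]
    pooled = np.vstack([xa, xb])
    na, nb = xa.shape[0], xb.shape[0]

    t_obs = _two_sample_t(xa, xb)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    max_null = np.empty(n_perm)
    idx = np.arange(na + nb)
    for k in range(n_perm):
        rng.shuffle(idx)
        t_perm = _two_sample_t(pooled[idx[:na]], pooled[idx[na:]])
        max_null[k] = np.abs(t_perm).max()
    threshold = float(np.percentile(max_null, 100 * (1 - alpha)))

    abs_t = np.abs(t_obs)
    p_corr_flat = (np.sum(max_null[None, :] >= abs_t[:, None], axis=1) + 1) \
        / (n_perm + 1)
    sig = abs_t > threshold
    significant = [(int(i), int(j), 1 if t > 0 else -1)
                   for i, j, t, s in zip(iu, ju, t_obs, sig) if s]

    t_map = np.zeros((n, n))
    t_map[iu, ju] = t_obs
    t_map += t_map.T
    p_map = np.ones((n, n))
    p_map[iu, ju] = p_corr_flat
    p_map = np.minimum(p_map, p_map.T)
    np.fill_diagonal(p_map, 1.0)
    return EdgeComparisonResult(t_map, max_null, threshold, significant,
                                p_map, n_perm, seed)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p); m defaults to the number of p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mm = len(p) if m is None else m
    if mm < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, mm * p)


# ---------------------------------------------------------------------------
# Behavioral ANOVA (randomized block) and Tukey HSD
# ---------------------------------------------------------------------------

def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if records and isinstance(records[0], BehavioralRecord):
        return behavior_to_frame(records)
    return pd.DataFrame(records)


def cell_means(records, response: str = "force_N",
               levels: tuple | None = None) -> pd.DataFrame:
    """Subject x level table of trial-averaged responses (one obs/cell)."""
    df = _records_to_frame(records)
    col = {"force": "force_N", "rppc": "rppc"}.get(response, response)
    table = df.pivot_table(index="subject", columns="level", values=col,
                           aggfunc="mean")
    if levels is not None:
        table = table[list(levels)]
    if table.isna().any().any():
        raise ValueError("missing subject x level cells: design must be "
                         "balanced and complete")
    return table


def anova_randomized_block(records, response: str = "force_N",
                           levels: tuple | None = None) -> pd.DataFrame:
    """Two-way additive ANOVA: participant (block) + treatment (level).

    Trial-level responses are first averaged to one value per subject x
    level cell, so with 12 subjects and 5 levels the degrees of freedom
    are 11 (participant), 4 (level), 44 (error), 59 (total). Both
    factors are tested against the error mean square.
    """
    table = cell_means(records, response, levels)
    y = table.to_numpy(dtype=float)
    n_s, n_l = y.shape
    if n_s < 2 or n_l < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    grand = y.mean()
    ss_block = n_l * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_treat = n_s * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_error = ss_total - ss_block - ss_treat
    df_block, df_treat = n_s - 1, n_l - 1
    df_error = df_block * df_treat
    ms_block = ss_block / df_block
    ms_treat = ss_treat / df_treat
    ms_error = ss_error / df_error
    if ms_error > 0:
        f_block = ms_block / ms_error
        f_treat = ms_treat / ms_error
        p_block = float(sps.f.sf(f_block, df_block, df_error))
        p_treat = float(sps.f.sf(f_treat, df_treat, df_error))
    else:
        f_block = f_treat = np.inf
        p_block = p_treat = 0.0
    return pd.DataFrame(
        {
            "source": ["participant", "level", "error", "total"],
            "df": [df_block, df_treat, df_error, n_s * n_l - 1],
            "ss": [ss_block, ss_treat, ss_error, ss_total],
            "ms": [ms_block, ms_treat, ms_error, np.nan],
            "F": [f_block, f_treat, np.nan, np.nan],
            "p": [p_block, p_treat, np.nan, np.nan],
        }
    )


def f_from_mean_squares(ms_effect: float, ms_error: float,
                        df_effect: int, df_error: int) -> tuple[float, float]:
    """F ratio and p-value from published mean squares (deterministic
    reproduction of an ANOVA table from its printed components)."""
    if ms_error <= 0:
        raise ValueError("ms_error must be > 0")
    f = ms_effect / ms_error
    return float(f), float(sps.f.sf(f, df_effect, df_error))


@dataclass
class TukeyResult:
    table: pd.DataFrame                 # pair, diff, se, ci_lo, ci_hi, t, p_adj
    grouping_letters: dict              # level -> letters string
    q_critical: float
    se: float
    df_error: int


def _compact_letter_display(levels, not_different) -> dict:
    """Letters such that two levels share a letter iff they are not
    significantly different; built from maximal cliques of the
    non-significance graph, ordered by the first level they contain."""
    cliques = []
    # Bron-Kerbosch is overkill for k <= ~10 levels: enumerate subsets
    k = len(levels)
    for size in range(k, 0, -1):
        for subset in itertools.combinations(range(k), size):
            if all(not_different[i][j] for i, j in
                   itertools.combinations(subset, 2)):
                if not any(set(subset) <= set(c) for c in cliques):
                    cliques.append(subset)
    cliques.sort(key=lambda c: c[0])
    letters = {lv: "" for lv in levels}
    for letter, clique in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", cliques):
        for i in clique:
            letters[levels[i]] += letter
    return letters


def tukey_hsd(level_means: dict, mse: float, df_error: int,
              n_per_group: int, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD simultaneous pairwise comparisons in a balanced design.

    For each unordered level pair: difference of level means, common
    SE = sqrt(2 * mse / n), T = difference / SE, simultaneous CI =
    difference +/- q(1-alpha, k, df_error)/sqrt(2) * SE, and adjusted p
    from the studentized-range distribution. ``level_means`` may be a
    mapping level -> mean or a subject x level cell-mean table (whose
    column means are used).
    """
    if isinstance(level_means, pd.DataFrame):
        means = level_means.mean(axis=0).to_dict()
    else:
        means = dict(level_means)
    if mse <= 0:
        raise ValueError("mse must be > 0")
    if df_error <= 0:
        raise ValueError("df_error must be > 0")
    levels = list(means)
    k = len(levels)
    se = math.sqrt(2.0 * mse / n_per_group)
    q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df_error))
    half = q_crit / math.sqrt(2.0) * se
    rows = []
    not_diff = [[True] * k for _ in range(k)]
    for (i, la), (j, lb) in itertools.combinations(enumerate(levels), 2):
        diff = means[la] - means[lb]
        t = diff / se
        p_adj = float(sps.studentized_range.sf(abs(t) * math.sqrt(2.0),
                                               k, df_error))
        sig = p_adj < alpha
        not_diff[i][j] = not_diff[j][i] = not sig
        rows.append({"pair": f"{la}-{lb}", "level_a": la, "level_b": lb,
                     "diff": diff, "se": se, "ci_lo": diff - half,
                     "ci_hi": diff + half, "t": t, "p_adj": p_adj,
                     "significant": sig})
    order = sorted(range(k), key=lambda i: -means[levels[i]])
    letters = _compact_letter_display([levels[i] for i in order],
                                      [[not_diff[a][b] for b in order]
                                       for a in order])
    return TukeyResult(pd.DataFrame(rows), letters, q_crit, se, df_error)


def percent_mvc(force: float, mvc: float) -> float:
    """Force as a percentage of maximum voluntary contraction."""
    if mvc <= 0:
        raise ValueError("mvc must be > 0")
    return 100.0 * force / mvc


# ---------------------------------------------------------------------------
# Group comparison of network metric tables
# ---------------------------------------------------------------------------

def compare_network_metrics(metric_table: pd.DataFrame,
                            level_pair: tuple[str, str],
                            n_perm: int = 30000, seed: int = 0,
                            tail: str = "one",
                            alpha: float = 0.05,
                            bonferroni_m: int | None = None) -> pd.DataFrame:
    """Permutation comparison of two exertion levels for every
    (band, metric, sparsity[, node]) cell of a tidy metric table.

    Expects columns subject, level, band, sparsity, metric, value and
    optionally node. When a node column is present the comparison is
    nodal and Bonferroni correction is applied with m = ``bonferroni_m``
    (default: the number of nodes).
    """
    if metric_table.empty:
        raise ValueError("empty metric table")
    lv_a, lv_b = level_pair
    df = metric_table[metric_table["level"].isin(level_pair)]
    nodal = "node" in df.columns and df["node"].notna().any()
    keys = ["band", "metric", "sparsity"] + (["node"] if nodal else [])
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(10 ** 6)
    for gi, (key, grp) in enumerate(df.groupby(keys, sort=True)):
        va = grp.loc[grp["level"] == lv_a, "value"].to_numpy()
        vb = grp.loc[grp["level"] == lv_b, "value"].to_numpy()
        if va.size == 0 or vb.size == 0:
            continue
        res = permutation_mean_difference(va, vb, n_perm=n_perm, tail=tail,
                                          seed=int(seeds[gi] % (2 ** 31)))
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(pair=f"{lv_a}-{lv_b}", observed=res.observed,
                   crit95=res.null_quantile_95, p=res.p_value,
                   n_perm=res.n_permutations)
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no overlapping level data to compare")
    if nodal:
        m = bonferroni_m if bonferroni_m is not None \
            else out["node"].nunique()
        out["p_adj"] = bonferroni_adjust(out["p"].to_numpy(), m)
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# Published behavioral summary statistics (reference inputs)
# ---------------------------------------------------------------------------

#: Level means of isometric arm force (N) as published (descriptives).
REFERENCE_FORCE_MEANS = {
    "extremely_light": 8.04,
    "light": 13.61,
    "somewhat_hard": 34.58,
    "hard": 41.83,
    "extremely_hard": 67.35,
}

#: Level means of perceived comfort as used in the published Tukey
#: comparison (these differ slightly from the descriptive table).
REFERENCE_RPPC_CELL_MEANS = {
    "extremely_light": 8.23,
    "light": 7.750,
    "somewhat_hard": 5.729,
    "hard": 5.375,
    "extremely_hard": 4.583,
}

#: Published randomized-block ANOVA components for force (N):
#: sums of squares and degrees of freedom.
REFERENCE_FORCE_ANOVA = {
    "ss_participant": 11374.0, "df_participant": 11,
    "ss_level": 27108.0, "df_level": 4,
    "ss_error": 11236.0, "df_error": 44,
    "ms_participant": 1034.0, "ms_level": 6777.085, "ms_error": 255.4,
}

#: Published randomized-block ANOVA components for perceived comfort.
REFERENCE_RPPC_ANOVA = {
    "ss_participant": 61.71, "df_participant": 11,
    "ss_level": 119.36, "df_level": 4,
    "ss_error": 32.64, "df_error": 44,
    "ms_participant": 5.60, "ms_level": 29.84, "ms_error": 0.7417,
}
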