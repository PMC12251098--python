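"""Bespoke statistics: cluster-based permutation tests, percentage-bend
correlation, JZS Bayes factors, and a thin assembly layer for standard tests.

The cluster test controls family-wise error over time (1D) or time-frequency
(2D) grids for paired designs: pointwise paired t statistics are thresholded
at the two-tailed critical value, contiguous supra-threshold runs (1D) or
4-connected components (2D) form clusters scored by their summed-t mass, and
the null distribution of the maximum |mass| is built by random within-
participant sign flips.  The percentage-bend correlation winsorises
standardized deviations from the median before correlating, making it robust
to marginal outliers.  JZS Bayes factors integrate the scaled-Cauchy prior on
effect size by numerical quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, ndimage
from scipy import stats as sps


@dataclass
class Cluster:
    mask: np.ndarray          # boolean over the input grid
    mass: float               # summed t within the cluster
    p: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    t_crit: float
    n_permutations: int
    alpha_cluster: float

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        out = np.zeros_like(self.t_obs, dtype=bool)
        for cl in self.clusters:
            if cl.p < alpha:
                out |= cl.mask
        return out


_ROW_STRUCTURE = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])


def _max_masses_rows(t_rows: np.ndarray, t_crit: float) -> np.ndarray:
    """Max |cluster mass| per row of a (n_rows, n_points) t array (1D clusters)."""
    n_rows = t_rows.shape[0]
    out = np.zeros(n_rows)
    for sign in (1.0, -1.0):
        above = sign * t_rows > t_crit
        labels, n_lab = ndimage.label(above, structure=_ROW_STRUCTURE)
        if n_lab == 0:
            continue
        flat = labels.ravel()
        masses = np.abs(np.bincount(flat, weights=t_rows.ravel(), minlength=n_lab + 1))
        first = np.unique(flat, return_index=True)
        for lab, pos in zip(*first):
            if lab == 0:
                continue
            row = pos // t_rows.shape[1]
            if masses[lab] > out[row]:
                out[row] = masses[lab]
    return out


def _clusters_nd(t: np.ndarray, t_crit: float) -> list[tuple[np.ndarray, float]]:
    """(mask, mass) for positive and negative clusters; 4-connectivity in 2D."""
    structure = ndimage.generate_binary_structure(t.ndim, 1)
    out = []
    for sign in (1.0, -1.0):
        labels, n_lab = ndimage.label(sign * t > t_crit, structure=structure)
        for lab in range(1, n_lab + 1):
            mask = labels == lab
            out.append((mask, float(t[mask].sum())))
    return out


def cluster_permutation_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterTestResult:
    """Paired cluster-based permutation test on (participants x grid) arrays.

    ``data_a``/``data_b`` may be (n, T) for 1D or (n, F, T) for 2D grids.
    Cluster p-values use the (b+1)/(m+1) correction.
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must share a shape")
    n = a.shape[0]
    if n < 6:
        raise ValueError("need at least 6 participants")
    d = a - b
    grid_shape = d.shape[1:]
    d2 = d.reshape(n, -1)

    mean = d2.mean(axis=0)
    sd = d2.std(axis=0, ddof=1)
    t_obs = np.divide(mean, sd / np.sqrt(n), out=np.zeros_like(mean), where=sd > 0)
    t_crit = float(sps.t.ppf(1.0 - alpha_cluster / 2.0, n - 1))

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    # Sign flips change the mean but not the per-point sum of squares.
    ss = (d2**2).sum(axis=0)
    m_null = signs @ d2 / n
    var_null = np.maximum(ss - n * m_null**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(var_null > 0, m_null / np.sqrt(var_null / n), 0.0)

    if len(grid_shape) == 1:
        null_max = _max_masses_rows(t_null, t_crit)
    else:
        null_max = np.zeros(n_perm)
        for i in range(n_perm):
            cl = _clusters_nd(t_null[i].reshape(grid_shape), t_crit)
            if cl:
                null_max[i] = max(abs(m) for _, m in cl)

    clusters = []
    for mask, mass in _clusters_nd(t_obs.reshape(grid_shape), t_crit):
        p = (np.sum(null_max >= abs(mass)) + 1.0) / (n_perm + 1.0)
        clusters.append(Cluster(mask=mask, mass=mass, p=float(p)))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterTestResult(
        clusters=clusters,
        t_obs=t_obs.reshape(grid_shape),
        t_crit=t_crit,
        n_permutations=n_perm,
        alpha_cluster=alpha_cluster,
    )


def _bend_scores(x: np.ndarray, beta: float) -> np.ndarray:
    dev = x - np.median(x)
    m = int(np.ceil((1.0 - beta) * len(x)))
    omega = np.sort(np.abs(dev))[m - 1]
    if omega == 0:
        raise ValueError("zero bend scale (constant variable)")
    return np.clip(dev / omega, -1.0, 1.0)


def percentage_bend_correlation(
    x: np.ndarray,
    y: np.ndarray,
    beta: float = 0.2,
    p_method: str = "permutation",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Robust correlation via winsorised deviations from the median.

    Deviations are standardized by the ceil((1-beta)n)-th smallest absolute
    deviation, passed through psi(u) = clip(u, -1, 1), and correlated with
    Pearson's formula.  With ``beta=0`` this reduces to Pearson on
    median-centered data.  The p-value is two-sided, by permutation of one
    variable's order (default) or by the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    a = _bend_scores(x, beta)
    b = _bend_scores(y, beta)
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        raise ValueError("zero bend scale (constant variable)")
    rho = float(np.sum(a * b) / denom)

    n = len(x)
    if p_method == "t_approx":
        r = min(max(rho, -1 + 1e-15), 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        sa = np.sum(a**2)
        for _ in range(n_perm):
            bp = b[rng.permutation(n)]
            r_null = np.sum(a * bp) / np.sqrt(sa * np.sum(bp**2))
            if abs(r_null) >= abs(rho):
                count += 1
        p = (count + 1.0) / (n_perm + 1.0)
    else:
        raise ValueError("p_method must be 'permutation' or 't_approx'")
    return rho, float(p)


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    tail: str
    r_scale: float
    t_statistic: float
    n: int


def jzs_bayes_factor(
    diffs: np.ndarray, tail: str = "two_sided", r_scale: float = np.sqrt(2) / 2
) -> BayesFactorResult:
    """One-sample JZS Bayes factor BF10 by quadrature over the Cauchy prior.

    The marginal likelihood under H1 integrates the noncentral-t likelihood of
    the observed t statistic against a Cauchy(0, r) prior on the standardized
    effect size; one-sided versions ('plus'/'minus') truncate the prior to the
    stated direction.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2 or not np.all(np.isfinite(d)):
        raise ValueError("need >= 2 finite paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    nu = n - 1

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, nu, np.sqrt(n) * delta) * sps.cauchy.pdf(delta, scale=r_scale)

    if tail == "two_sided":
        m1, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    elif tail == "plus":
        m1, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        m1 *= 2.0  # renormalise the truncated Cauchy prior
    elif tail == "minus":
        m1, _ = integrate.quad(integrand, -np.inf, 0.0, limit=200)
        m1 *= 2.0
    else:
        raise ValueError("tail must be 'two_sided', 'plus', or 'minus'")
    m0 = sps.t.pdf(t, nu)
    return BayesFactorResult(bf10=float(m1 / m0), tail=tail, r_scale=r_scale,
                             t_statistic=float(t), n=n)


def run_condition_tests(cells: pd.DataFrame, dv: str = "value") -> pd.DataFrame:
    """Assemble the standard per-metric tests for a (side x contingency) layout.

    ``cells`` needs columns participant_id, side, contingency, and the dv; each
    participant must contribute all four cells (balanced design).  Returns a
    tidy table with Wilcoxon signed-rank contrasts per side, a contrast of the
    per-side modulations, and a 2x2 repeated-measures ANOVA labeled as
    'Side', 'Reward contingency', and 'Side x Reward contingency'.
    """
    needed = {"participant_id", "side", "contingency", dv}
    if not needed <= set(cells.columns):
        raise ValueError(f"cells must carry columns {sorted(needed)}")
    wide = cells.pivot_table(
        index="participant_id", columns=["side", "contingency"], values=dv
    )
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("unbalanced design: every participant needs all four cells")
    conts = sorted(cells["contingency"].unique())
    from rewardsdt.behavior import CONTINGENCIES

    for sess, pair in CONTINGENCIES.items():
        if set(conts) == set(pair):
            c1, c2 = pair
            break
    else:
        raise ValueError(f"unrecognised contingency labels {conts}")

    rows = []
    deltas = {}
    for side in ("FX", "VR"):
        a = wide[(side, c1)].to_numpy()
        b = wide[(side, c2)].to_numpy()
        deltas[side] = a - b
        if np.allclose(a, b):
            stat, p = np.nan, 1.0
        else:
            stat, p = sps.wilcoxon(a, b)
        rows.append({"test": "signed_rank", "contrast": f"{c1} vs {c2} ({side})",
                     "statistic": stat, "p": p})
    dd = deltas["VR"] - deltas["FX"]
    if np.allclose(dd, 0):
        stat, p = np.nan, 1.0
    else:
        stat, p = sps.wilcoxon(dd)
    rows.append({"test": "signed_rank", "contrast": "modulation VR vs FX",
                 "statistic": stat, "p": p})

    import pingouin as pg

    aov = pg.rm_anova(
        data=cells, dv=dv, within=["side", "contingency"], subject="participant_id",
        detailed=True,
    )
    label_map = {
        "side": "Side",
        "contingency": "Reward contingency",
        "side * contingency": "Side x Reward contingency",
    }
    for _, r in aov.iterrows():
        src = str(r["Source"]).lower()
        if src in label_map:
            p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
            rows.append({"test": "rm_anova", "contrast": label_map[src],
                         "statistic": float(r["F"]), "p": float(r[p_col]),
                         "dof": (int(r["ddof1"]), int(r["ddof2"]))})
    return pd.DataFrame(rows)
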