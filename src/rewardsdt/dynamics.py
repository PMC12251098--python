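"""Switch-locked dynamics and the conserved-attentional-resource test.

A "switch trial" is the first VR-probed trial of a mini-block whose delivered
payoff differs from what the same response type would have earned under the
previous contingency — the earliest trial on which the observer could have
inferred, from feedback, that the VR-side contingency switched.  Metrics
(d', c, alpha power, RT, microsaccade rate) are evaluated in 9-trial windows
centered on a grid of offsets from 2 trials before to 14 trials after the
switch, averaged across switches of the same transition type.  If a metric
reflects a resource conserved across hemifields, its de-meaned (VR, FX) window
values (x_i, y_i) should satisfy x + y = 0; fit quality is the symmetric

    R^2 = 1 - sum (x_i + y_i)^2 / sum (x_i^2 + y_i^2)

which is 1 iff the points lie on the line exactly and can be negative.  R^2 is
compared across sessions with a label-shuffling permutation test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rewardsdt.behavior import estimate_sdt, tabulate_contingency, NoTrialsError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwitchEvent:
    block_idx: int
    trial_idx: int          # global trial index (position in the session)
    miniblock_idx: int
    transition: tuple[str, str]  # (previous contingency, new contingency)


@dataclass
class SwitchLockedSeries:
    """Per-offset metric values around switches, per (transition, side)."""

    offsets: np.ndarray
    values: dict[tuple[tuple[str, str], str], np.ndarray]
    counts: dict[tuple[tuple[str, str], str], np.ndarray]
    width: int = 9


@dataclass
class ConservedResourceFit:
    r_squared: float
    residuals: np.ndarray
    n_points: int
    permutation_p: float | None = None


def find_switch_trials(trials: pd.DataFrame, payoffs: dict) -> list[SwitchEvent]:
    """Identify the informative feedback trial of each mini-block transition.

    ``payoffs`` is the schedule's (side, response_type, contingency, valence)
    -> INR matrix.  Mini-blocks with no informative VR-probed trial yield no
    event (logged).
    """
    needed = {"miniblock_idx", "payoff", "probe_side", "response", "block_idx"}
    if not needed <= set(trials.columns):
        raise ValueError(f"trials must carry columns {sorted(needed)}")
    trials = trials.reset_index(drop=True)
    mb_arr = trials["miniblock_idx"].to_numpy()
    block_arr = trials["block_idx"].to_numpy()
    cont_arr = trials["contingency"].to_numpy()
    val_arr = trials["block_valence"].to_numpy()
    probe_vr = (trials["probe_side"] == "VR").to_numpy()
    responded = (trials["response"] != "none").to_numpy()
    yes = (trials["response"] == "yes").to_numpy()
    change_vr = trials["change_vr"].to_numpy()
    resp_type = np.where(change_vr, np.where(yes, "H", "M"), np.where(yes, "FA", "CR"))

    events: list[SwitchEvent] = []
    # first trial index of every mini-block, in order
    mb_starts = np.flatnonzero(np.concatenate(([True], mb_arr[1:] != mb_arr[:-1])))
    for s_prev, s_cur in zip(mb_starts[:-1], mb_starts[1:]):
        if block_arr[s_prev] != block_arr[s_cur]:
            continue  # block boundary, not a within-block transition
        prev_cont, cont = cont_arr[s_prev], cont_arr[s_cur]
        if prev_cont == cont:
            continue
        end = (
            mb_starts[mb_starts > s_cur][0]
            if (mb_starts > s_cur).any() else len(trials)
        )
        found = None
        for i in range(s_cur, end):
            if block_arr[i] != block_arr[s_cur]:
                break
            if not (probe_vr[i] and responded[i]):
                continue
            rt = resp_type[i]
            if payoffs[("VR", rt, cont, val_arr[i])] != payoffs[("VR", rt, prev_cont, val_arr[i])]:
                found = SwitchEvent(
                    block_idx=int(block_arr[i]),
                    trial_idx=int(i),
                    miniblock_idx=int(mb_arr[i]),
                    transition=(str(prev_cont), str(cont)),
                )
                break
        if found is None:
            logger.debug("mini-block %s: no informative switch trial", mb_arr[s_cur])
        else:
            events.append(found)
    return events


def sdt_metric(parameter: str = "d_prime"):
    """Metric function for switch-locked series: pooled SDT parameter on a side."""

    def fn(sub: pd.DataFrame, side: str) -> float | None:
        probed = sub.loc[(sub["probe_side"] == side) & (sub["response"] != "none")]
        if len(probed) == 0:
            return None
        change = np.where(side == "VR", probed["change_vr"], probed["change_fx"])
        yes = (probed["response"] == "yes").to_numpy()
        from rewardsdt.behavior import ContingencyCounts

        counts = ContingencyCounts(
            n_hit=int((change & yes).sum()),
            n_miss=int((change & ~yes).sum()),
            n_fa=int((~change & yes).sum()),
            n_cr=int((~change & ~yes).sum()),
        )
        if counts.n_change == 0 or counts.n_nochange == 0:
            return None
        return getattr(estimate_sdt(counts), parameter)

    return fn


def rt_metric(sub: pd.DataFrame, side: str) -> float | None:
    """Mean correct-response RT on a side, for switch-locked series."""
    probed = sub.loc[(sub["probe_side"] == side) & (sub["response"] != "none")]
    if len(probed) == 0:
        return None
    change = np.where(side == "VR", probed["change_vr"], probed["change_fx"])
    correct = (probed["response"] == "yes").to_numpy() == change
    rts = probed.loc[correct, "rt_ms"].dropna()
    return float(rts.mean()) if len(rts) else None


def switch_locked_series(
    trials: pd.DataFrame,
    switches: list[SwitchEvent],
    metric_fn,
    width: int = 9,
    shift: int = 2,
    offsets: tuple[int, int] = (-2, 14),
    normalize_by_session_mean: bool = False,
) -> SwitchLockedSeries:
    """Metric in sliding windows around each switch, averaged per transition type.

    Windows of ``width`` trials are centered on each offset of the grid
    ``range(offsets[0], offsets[1] + 1, shift)`` and truncated at the block
    edges (truncation is reflected in the counts).  With the flag set, values
    are divided by the session-wide metric (per side) to control scale across
    participants — the normalization used for neural/motoric metrics.
    """
    grid = np.arange(offsets[0], offsets[1] + 1, shift)
    half = width // 2
    session_mean = {}
    if normalize_by_session_mean:
        for side in ("FX", "VR"):
            session_mean[side] = metric_fn(trials, side)

    acc: dict[tuple[tuple[str, str], str], list[np.ndarray]] = {}
    trials = trials.reset_index(drop=True)
    block_bounds = {}
    for b, g in trials.groupby("block_idx", sort=True):
        block_bounds[b] = (int(g.index[0]), int(g.index[-1]))

    for sw in switches:
        lo_b, hi_b = block_bounds[sw.block_idx]
        for side in ("FX", "VR"):
            vals = np.full(len(grid), np.nan)
            ns = np.zeros(len(grid), dtype=int)
            for j, off in enumerate(grid):
                lo = max(lo_b, sw.trial_idx + off - half)
                hi = min(hi_b, sw.trial_idx + off + half)
                if hi < lo:
                    continue
                sub = trials.iloc[lo : hi + 1]
                v = metric_fn(sub, side)
                if v is None:
                    continue
                if normalize_by_session_mean:
                    sm = session_mean[side]
                    if sm in (None, 0):
                        continue
                    v = v / sm
                vals[j] = v
                ns[j] = hi - lo + 1
            key = (sw.transition, side)
            acc.setdefault(key, []).append((vals, ns))

    values, counts = {}, {}
    for key, pairs in acc.items():
        stack = np.vstack([p[0] for p in pairs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            values[key] = np.nanmean(stack, axis=0)
        counts[key] = np.vstack([p[1] for p in pairs]).sum(axis=0)
    return SwitchLockedSeries(offsets=grid, values=values, counts=counts, width=width)


def sdt_switch_series(
    trials: pd.DataFrame,
    switches: list[SwitchEvent],
    parameter: str = "d_prime",
    width: int = 9,
    shift: int = 2,
    offsets: tuple[int, int] = (-2, 14),
) -> SwitchLockedSeries:
    """Vectorised switch-locked series for the SDT parameters.

    Equivalent to :func:`switch_locked_series` with an SDT metric function, but
    computes window contingency counts from cumulative sums, which makes the
    replicate-heavy conserved-resource analyses tractable.
    """
    if parameter not in ("d_prime", "criterion"):
        raise ValueError("parameter must be 'd_prime' or 'criterion'")
    from scipy.stats import norm

    trials = trials.reset_index(drop=True)
    grid = np.arange(offsets[0], offsets[1] + 1, shift)
    half = width // 2
    probe_vr = (trials["probe_side"] == "VR").to_numpy()
    responded = (trials["response"] != "none").to_numpy()
    yes = (trials["response"] == "yes").to_numpy()
    change = np.where(probe_vr, trials["change_vr"].to_numpy(), trials["change_fx"].to_numpy())
    block = trials["block_idx"].to_numpy()
    block_bounds = {}
    for b in np.unique(block):
        w = np.flatnonzero(block == b)
        block_bounds[b] = (int(w[0]), int(w[-1]))

    # cumulative counts per side: hit, miss, fa, cr
    cums = {}
    for side, smask in (("FX", ~probe_vr), ("VR", probe_vr)):
        base = smask & responded
        cells = np.stack(
            [
                base & change & yes,
                base & change & ~yes,
                base & ~change & yes,
                base & ~change & ~yes,
            ]
        ).astype(np.int64)
        cums[side] = np.concatenate(
            [np.zeros((4, 1), dtype=np.int64), np.cumsum(cells, axis=1)], axis=1
        )

    # Pool window contingency counts across all switches of a transition type
    # before the probit: single-switch 9-trial windows are too sparse for a
    # stable d'/c estimate (and their extreme-rate corrections would bias the
    # two sides' traces in a spuriously coupled way).
    pooled: dict[tuple[tuple[str, str], str], np.ndarray] = {}
    nwin: dict[tuple[tuple[str, str], str], np.ndarray] = {}
    for sw in switches:
        lo_b, hi_b = block_bounds[sw.block_idx]
        los = np.clip(sw.trial_idx + grid - half, lo_b, hi_b + 1)
        his = np.clip(sw.trial_idx + grid + half, lo_b - 1, hi_b)
        for side in ("FX", "VR"):
            cs = cums[side]
            counts = cs[:, his + 1] - cs[:, los]  # (4, n_offsets)
            key = (sw.transition, side)
            pooled[key] = pooled.get(key, 0) + counts
            nwin[key] = nwin.get(key, 0) + np.maximum(his - los + 1, 0)

    values, counts_out = {}, {}
    for key, counts in pooled.items():
        h, m, fa, cr = counts
        nc = h + m
        nn = fa + cr
        valid = (nc > 0) & (nn > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            hr = h / np.maximum(nc, 1)
            far = fa / np.maximum(nn, 1)
            hr = np.where(hr == 0, 1 / (2 * np.maximum(nc, 1)), hr)
            hr = np.where(hr == 1, 1 - 1 / (2 * np.maximum(nc, 1)), hr)
            far = np.where(far == 0, 1 / (2 * np.maximum(nn, 1)), far)
            far = np.where(far == 1, 1 - 1 / (2 * np.maximum(nn, 1)), far)
            zh, zf = norm.ppf(hr), norm.ppf(far)
            vals = zh - zf if parameter == "d_prime" else -0.5 * (zh + zf)
        values[key] = np.where(valid, vals, np.nan)
        counts_out[key] = nwin[key]
    return SwitchLockedSeries(offsets=grid, values=values, counts=counts_out, width=width)


def average_series(series_list: list[SwitchLockedSeries]) -> SwitchLockedSeries:
    """Average switch-locked series across participants (keys must agree)."""
    keys = set().union(*(s.values.keys() for s in series_list))
    offsets = series_list[0].offsets
    values, counts = {}, {}
    for key in keys:
        stack = np.vstack([s.values[key] for s in series_list if key in s.values])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values[key] = np.nanmean(stack, axis=0)
        counts[key] = np.vstack([s.counts[key] for s in series_list if key in s.counts]).sum(axis=0)
    return SwitchLockedSeries(
        offsets=offsets, values=values, counts=counts, width=series_list[0].width
    )


def series_points(series: SwitchLockedSeries) -> tuple[np.ndarray, np.ndarray]:
    """Paired (x = VR, y = FX) window values pooled across transition types."""
    xs, ys = [], []
    transitions = sorted({t for (t, _) in series.values})
    for tr in transitions:
        x = series.values.get((tr, "VR"))
        y = series.values.get((tr, "FX"))
        if x is None or y is None:
            continue
        ok = ~(np.isnan(x) | np.isnan(y))
        xs.append(x[ok])
        ys.append(y[ok])
    if not xs:
        raise ValueError("series contains no paired FX/VR values")
    return np.concatenate(xs), np.concatenate(ys)


def conserved_resource_r2(
    x: np.ndarray, y: np.ndarray, symmetric: bool = True
) -> ConservedResourceFit:
    """Fit de-meaned paired points to the line x + y = 0.

    The symmetric residual treats both sides identically; the asymmetric
    variant (``symmetric=False``) scores y against -x relative to the variance
    of y, for sensitivity analysis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired points")
    x = x - x.mean()
    y = y - y.mean()
    total = np.sum(x**2 + y**2) if symmetric else np.sum(y**2)
    if total == 0:
        raise ValueError("zero total variation: R^2 undefined")
    resid = x + y
    r2 = 1.0 - np.sum(resid**2) / total
    return ConservedResourceFit(r_squared=float(r2), residuals=resid, n_points=len(x))


def r2_permutation_test(
    points_a: tuple[np.ndarray, np.ndarray],
    points_b: tuple[np.ndarray, np.ndarray],
    n_perm: int = 1000,
    seed: int | None = None,
    symmetric: bool = True,
) -> dict:
    """One-sided test of R^2(a) > R^2(b) by shuffling session labels per pair.

    Each (x, y) pair keeps its identity but is randomly reassigned between the
    two sessions (labels shuffled 50/50 per index), and the R^2 difference is
    recomputed, giving the null for the observed difference.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    xa, ya = map(np.asarray, points_a)
    xb, yb = map(np.asarray, points_b)
    if len(xa) != len(xb):
        raise ValueError("series must contribute the same number of pairs")
    rng = np.random.default_rng(seed)
    obs = (
        conserved_resource_r2(xa, ya, symmetric).r_squared
        - conserved_resource_r2(xb, yb, symmetric).r_squared
    )
    null = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.random(len(xa)) < 0.5
        x1 = np.where(swap, xb, xa)
        y1 = np.where(swap, yb, ya)
        x2 = np.where(swap, xa, xb)
        y2 = np.where(swap, ya, yb)
        null[i] = (
            conserved_resource_r2(x1, y1, symmetric).r_squared
            - conserved_resource_r2(x2, y2, symmetric).r_squared
        )
    p = (np.sum(null >= obs) + 1.0) / (n_perm + 1.0)
    return {"observed_diff": float(obs), "p": float(p), "null": null}
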