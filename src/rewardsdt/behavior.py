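"""Domain types and signal-detection-theoretic estimation for the change-detection task.

Trials live in a tidy :class:`pandas.DataFrame` with one row per trial and the
column schema of :data:`TRIAL_COLUMNS` (this is also the on-disk CSV schema).
Behavioural analysis reduces trials to 2x2 stimulus-response contingency tables
per (side x reward contingency) cell, estimates equal-variance SDT parameters

    d' = Phi^-1(HR) - Phi^-1(FAR)
    c  = -0.5 [Phi^-1(HR) + Phi^-1(FAR)]

and summarises reward-contingency effects as modulation indices
``delta = value(c1) - value(c2)`` with the contingency order fixed per session
type: (VR_gt_FX, VR_lt_FX) for space-specific sessions and
(liberal, conservative) for choice-specific sessions.  Lower c means a more
liberal (Yes-biased) observer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Canonical trial-table column order (also the CSV schema; UTF-8, header required).
TRIAL_COLUMNS = [
    "participant_id",
    "session_type",
    "block_idx",
    "block_valence",
    "miniblock_idx",
    "contingency",
    "fx_side",
    "probe_side",
    "change_fx",
    "change_vr",
    "response",
    "rt_ms",
    "payoff",
]

SESSION_TYPES = ("space_specific", "choice_specific")
#: Reward-contingency labels, per session type, in fixed modulation order (c1, c2).
CONTINGENCIES = {
    "space_specific": ("VR_gt_FX", "VR_lt_FX"),
    "choice_specific": ("liberal", "conservative"),
}
SIDES = ("FX", "VR")
VALENCES = ("gain", "loss")


class NoTrialsError(ValueError):
    """Raised when a (side, contingency, valence) filter selects no trials."""


def contingency_pair(session_type: str) -> tuple[str, str]:
    """Return the (c1, c2) contingency ordering used for modulation indices."""
    try:
        return CONTINGENCIES[session_type]
    except KeyError:
        raise ValueError(f"unknown session_type {session_type!r}") from None


@dataclass(frozen=True)
class ContingencyCounts:
    """Cells of a 2x2 stimulus-response contingency table."""

    n_hit: int
    n_miss: int
    n_fa: int
    n_cr: int

    def __post_init__(self) -> None:
        for name in ("n_hit", "n_miss", "n_fa", "n_cr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_change(self) -> int:
        return self.n_hit + self.n_miss

    @property
    def n_nochange(self) -> int:
        return self.n_fa + self.n_cr

    @property
    def hit_rate(self) -> float:
        return self.n_hit / self.n_change

    @property
    def fa_rate(self) -> float:
        return self.n_fa / self.n_nochange

    def __add__(self, other: "ContingencyCounts") -> "ContingencyCounts":
        return ContingencyCounts(
            self.n_hit + other.n_hit,
            self.n_miss + other.n_miss,
            self.n_fa + other.n_fa,
            self.n_cr + other.n_cr,
        )


@dataclass(frozen=True)
class SDTParams:
    """Equal-variance SDT parameters: sensitivity d' and criterion c."""

    d_prime: float
    criterion: float
    corrected: bool = False  # True when an extreme-rate (0/1) correction was applied


@dataclass(frozen=True)
class MetricValue:
    """A scalar metric value tagged with the side and metric it was computed on."""

    value: float
    side: str
    metric: str


@dataclass(frozen=True)
class ModulationIndex:
    """Reward-contingency modulation of a metric: delta = value(c1) - value(c2)."""

    side: str
    metric: str
    delta: float


def validate_trials(trials: pd.DataFrame) -> None:
    """Validate trial-table schema and the task's structural invariants.

    Raises ``ValueError`` with a message naming every violated constraint.
    """
    problems: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if not trials["session_type"].isin(SESSION_TYPES).all():
        problems.append("session_type outside {space_specific, choice_specific}")
    if not trials["fx_side"].isin(("left", "right")).all():
        problems.append("fx_side outside {left, right}")
    if not trials["probe_side"].isin(SIDES).all():
        problems.append("probe_side outside {FX, VR}")
    if not trials["response"].isin(("yes", "no", "none")).all():
        problems.append("response outside {yes, no, none}")
    if not trials["block_valence"].isin(VALENCES).all():
        problems.append("block_valence outside {gain, loss}")
    for sess in SESSION_TYPES:
        sel = trials["session_type"] == sess
        if sel.any() and not trials.loc[sel, "contingency"].isin(CONTINGENCIES[sess]).all():
            problems.append(f"contingency labels inconsistent with {sess} session")
    none_resp = trials["response"] == "none"
    if trials.loc[none_resp, "rt_ms"].notna().any():
        problems.append("rt_ms present on response='none' trials")
    # No-response trials carry the fixed abstention penalty regardless of valence;
    # the gain/loss payoff-sign invariant applies to responded trials only.
    responded = ~none_resp
    gain = responded & (trials["block_valence"] == "gain")
    loss = responded & (trials["block_valence"] == "loss")
    if (trials.loc[gain, "payoff"] < 0).any():
        problems.append("negative payoff in gain block")
    if (trials.loc[loss, "payoff"] > 0).any():
        problems.append("positive payoff in loss block")
    if problems:
        raise ValueError("invalid trial table: " + "; ".join(problems))


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV (schema :data:`TRIAL_COLUMNS`) and validate it."""
    trials = pd.read_csv(
        path,
        dtype={"participant_id": str},
        true_values=["True", "true", "TRUE"],
        false_values=["False", "false", "FALSE"],
    )
    trials["change_fx"] = trials["change_fx"].astype(bool)
    trials["change_vr"] = trials["change_vr"].astype(bool)
    validate_trials(trials)
    return trials


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials)
    trials.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)


def _probed_change(trials: pd.DataFrame) -> pd.Series:
    """Whether the grating on the probed side changed, per trial."""
    return np.where(trials["probe_side"] == "VR", trials["change_vr"], trials["change_fx"])


def tabulate_contingency(
    trials: pd.DataFrame,
    side: str,
    contingency: str,
    valence_filter: str = "pooled",
) -> ContingencyCounts:
    """Summarise trials probed on ``side`` under ``contingency`` into a 2x2 table.

    Classification on the probed side: change & yes -> hit, change & no -> miss,
    no-change & yes -> false alarm, no-change & no -> correct rejection.  Trials
    with no response are excluded.  ``valence_filter`` restricts to gain or loss
    blocks; the default pools both (the headline analysis path).
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    if valence_filter not in ("gain", "loss", "pooled"):
        raise ValueError(f"valence_filter must be gain/loss/pooled, got {valence_filter!r}")
    if len(trials) == 0:
        raise NoTrialsError("empty trial table")
    sess = trials["session_type"].iloc[0]
    if contingency not in CONTINGENCIES.get(sess, ()):
        raise ValueError(f"contingency {contingency!r} invalid for session {sess!r}")

    sel = (
        (trials["probe_side"] == side)
        & (trials["contingency"] == contingency)
        & (trials["response"] != "none")
    )
    if valence_filter != "pooled":
        sel &= trials["block_valence"] == valence_filter
    sub = trials.loc[sel]
    if len(sub) == 0:
        raise NoTrialsError(
            f"no trials for side={side}, contingency={contingency}, "
            f"valence={valence_filter}"
        )
    change = pd.Series(_probed_change(sub), index=sub.index)
    yes = sub["response"] == "yes"
    return ContingencyCounts(
        n_hit=int((change & yes).sum()),
        n_miss=int((change & ~yes).sum()),
        n_fa=int((~change & yes).sum()),
        n_cr=int((~change & ~yes).sum()),
    )


def estimate_sdt(counts: ContingencyCounts) -> SDTParams:
    """Estimate (d', c) from a contingency table.

    Extreme rates of 0 or 1 are replaced by 1/(2N) and 1 - 1/(2N) of the
    respective row total before the probit transform (logged when applied), so
    the estimates stay finite.
    """
    if counts.n_change == 0 or counts.n_nochange == 0:
        raise ValueError("both rows of the contingency table must have trials")
    corrected = False

    def _rate(k: int, n: int) -> float:
        nonlocal corrected
        r = k / n
        if r == 0.0:
            corrected = True
            return 1.0 / (2 * n)
        if r == 1.0:
            corrected = True
            return 1.0 - 1.0 / (2 * n)
        return r

    hr = _rate(counts.n_hit, counts.n_change)
    far = _rate(counts.n_fa, counts.n_nochange)
    if corrected:
        logger.debug(
            "extreme-rate correction applied (counts: H=%d M=%d FA=%d CR=%d)",
            counts.n_hit, counts.n_miss, counts.n_fa, counts.n_cr,
        )
    z_hr = norm.ppf(hr)
    z_far = norm.ppf(far)
    return SDTParams(
        d_prime=float(z_hr - z_far),
        criterion=float(-0.5 * (z_hr + z_far)),
        corrected=corrected,
    )


def modulation_index(value_c1, value_c2, side: str | None = None, metric: str | None = None) -> ModulationIndex:
    """Modulation index delta = value(c1) - value(c2) for a metric on one side.

    Accepts plain floats (with ``side``/``metric`` given explicitly) or two
    :class:`MetricValue` objects, whose side/metric tags must agree.
    """
    if isinstance(value_c1, MetricValue) or isinstance(value_c2, MetricValue):
        if not (isinstance(value_c1, MetricValue) and isinstance(value_c2, MetricValue)):
            raise ValueError("mix of tagged and untagged metric values")
        if value_c1.side != value_c2.side or value_c1.metric != value_c2.metric:
            raise ValueError(
                f"mismatched side/metric: ({value_c1.side}, {value_c1.metric}) vs "
                f"({value_c2.side}, {value_c2.metric})"
            )
        side, metric = value_c1.side, value_c1.metric
        value_c1, value_c2 = value_c1.value, value_c2.value
    if side is None or metric is None:
        raise ValueError("side and metric are required for untagged values")
    return ModulationIndex(side=side, metric=metric, delta=float(value_c1) - float(value_c2))


def sdt_by_cell(
    trials: pd.DataFrame, valence_filter: str = "pooled"
) -> dict[tuple[str, str], SDTParams]:
    """Estimate SDT parameters for every (side x contingency) cell of a session."""
    sess = trials["session_type"].iloc[0]
    out = {}
    for side in SIDES:
        for cont in CONTINGENCIES[sess]:
            out[(side, cont)] = estimate_sdt(
                tabulate_contingency(trials, side, cont, valence_filter)
            )
    return out


def sdt_modulations(
    trials: pd.DataFrame, valence_filter: str = "pooled"
) -> dict[str, ModulationIndex]:
    """Delta-d' and Delta-c per side, with the session's fixed contingency order."""
    sess = trials["session_type"].iloc[0]
    c1, c2 = contingency_pair(sess)
    cells = sdt_by_cell(trials, valence_filter)
    out = {}
    for side in SIDES:
        out[f"d_prime_{side}"] = modulation_index(
            cells[(side, c1)].d_prime, cells[(side, c2)].d_prime, side, "d_prime"
        )
        out[f"criterion_{side}"] = modulation_index(
            cells[(side, c1)].criterion, cells[(side, c2)].criterion, side, "criterion"
        )
    return out


def _high_bias_response(contingency: str) -> str:
    """The response choice carrying higher reward (or lower penalty) expectation."""
    return {"liberal": "yes", "conservative": "no"}[contingency]


def rt_summaries(trials: pd.DataFrame, side: str, contingency: str) -> dict:
    """Median/mean RT for correct responses in a cell, plus the choice-bias RT effect.

    RTs are measured from probe onset; correct responses are hits and correct
    rejections on the probed side.  ``delta_rt_by_choice_bias`` (high-bias minus
    low-bias choice RT, averaged across the two choice-specific contingencies on
    the VR side) is reported for choice-specific sessions when ``side == 'VR'``,
    else ``None``.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    sess = trials["session_type"].iloc[0]
    sel = (
        (trials["probe_side"] == side)
        & (trials["contingency"] == contingency)
        & (trials["response"] != "none")
    )
    sub = trials.loc[sel]
    change = pd.Series(_probed_change(sub), index=sub.index)
    correct = (change & (sub["response"] == "yes")) | (~change & (sub["response"] == "no"))
    rts = sub.loc[correct, "rt_ms"].dropna()
    if len(rts) == 0:
        logger.info("no correct trials for side=%s contingency=%s", side, contingency)
        median_rt = mean_rt = None
    else:
        median_rt = float(rts.median())
        mean_rt = float(rts.mean())

    delta = None
    if sess == "choice_specific" and side == "VR":
        delta = delta_rt_by_choice_bias(trials)
    return {"median_rt": median_rt, "mean_rt": mean_rt, "delta_rt_by_choice_bias": delta}


def delta_rt_by_choice_bias(trials: pd.DataFrame) -> float | None:
    """deltaRT = RT(high-bias choice) - RT(low-bias choice) on the VR side.

    Computed per choice-specific contingency from all responded VR-probed trials
    and averaged across the two contingencies; the high-bias choice is Yes under
    the liberal and No under the conservative contingency.
    """
    deltas = []
    for cont in CONTINGENCIES["choice_specific"]:
        sub = trials.loc[
            (trials["probe_side"] == "VR")
            & (trials["contingency"] == cont)
            & (trials["response"] != "none")
        ]
        bh = sub.loc[sub["response"] == _high_bias_response(cont), "rt_ms"].dropna()
        bl = sub.loc[sub["response"] != _high_bias_response(cont), "rt_ms"].dropna()
        if len(bh) and len(bl):
            deltas.append(float(bh.mean() - bl.mean()))
    if not deltas:
        logger.info("deltaRT undefined: no trials in one of the choice-bias cells")
        return None
    return float(np.mean(deltas))
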