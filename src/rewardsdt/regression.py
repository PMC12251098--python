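"""Linear models linking marker modulations to psychophysical modulations.

Two ordinary-least-squares models predict the per-(participant x side)
psychophysical modulation (delta-d' in space-specific sessions, delta-c in
choice-specific sessions) from marker modulations:

    Model I  (neural):  delta ~ dN2pc + dP300 + dAlphaPre + dAlphaPost
    Model II (motoric): delta ~ dRT + dMSC

with n = 2 sides x participants rows.  Inference uses an F-test against the
intercept-only model, jackknife (leave-one-participant-out) standard errors,
a side-label permutation test per coefficient, and condition indices of the
column-scaled design for multicollinearity.  Out-of-sample performance is the
percentage-bend correlation between observed and leave-one-participant-out
predicted modulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from rewardsdt.stats import percentage_bend_correlation

logger = logging.getLogger(__name__)

MODEL_PREDICTORS = {
    "I": ["d_n2pc", "d_p300", "d_alpha_pre", "d_alpha_post"],
    "II": ["d_rt", "d_msc"],
}
RESPONSE_COLUMN = "response"


@dataclass
class MarkerRegressionFit:
    model: str
    predictors: list[str]
    intercept: float
    betas: dict[str, float]
    jackknife_sem: dict[str, float]
    r_squared: float
    f_statistic: float
    f_dof: tuple[int, int]
    f_pvalue: float
    condition_indices: np.ndarray
    permutation_p: dict[str, float] = field(default_factory=dict)
    n_rows: int = 0


def _design(table: pd.DataFrame, model: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    preds = MODEL_PREDICTORS[model]
    missing = [c for c in preds + [RESPONSE_COLUMN] if c not in table.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    if table[preds + [RESPONSE_COLUMN]].isna().any().any():
        raise ValueError("marker table has missing cells in fitted rows")
    X = sm.add_constant(table[preds].to_numpy(), has_constant="add")
    y = table[RESPONSE_COLUMN].to_numpy()
    return X, y, preds


def condition_indices(X: np.ndarray) -> np.ndarray:
    """Condition indices of the column-scaled design (unit column lengths)."""
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero design column")
    s = np.linalg.svd(X / norms, compute_uv=False)
    with np.errstate(divide="ignore"):
        return s.max() / s


def fit_marker_model(table: pd.DataFrame, model: str = "I") -> MarkerRegressionFit:
    """Fit Model I or II by OLS with full diagnostic output.

    Raises on rank-deficient designs, naming exactly collinear column pairs
    when they can be identified.
    """
    X, y, preds = _design(table, model)
    if len(y) <= X.shape[1]:
        raise ValueError("need more rows than predictors + intercept")
    ci = condition_indices(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cols = ["intercept"] + preds
        dupes = []
        Xs = X / np.linalg.norm(X, axis=0)
        corr = Xs.T @ Xs
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if abs(corr[i, j]) > 1.0 - 1e-10:
                    dupes.append((cols[i], cols[j]))
        raise ValueError(f"rank-deficient design; collinear columns: {dupes or 'unidentified'}")

    res = sm.OLS(y, X).fit()

    # jackknife s.e.m. by leave-one-participant-out refits
    if "participant_id" not in table.columns:
        raise ValueError("marker table must carry participant_id")
    parts = table["participant_id"].to_numpy()
    uniq = pd.unique(parts)
    jack = np.empty((len(uniq), X.shape[1]))
    for i, p in enumerate(uniq):
        keep = parts != p
        jack[i] = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
    n_j = len(uniq)
    sem = np.sqrt((n_j - 1) / n_j * ((jack - jack.mean(axis=0)) ** 2).sum(axis=0))

    return MarkerRegressionFit(
        model=model,
        predictors=preds,
        intercept=float(res.params[0]),
        betas={p: float(b) for p, b in zip(preds, res.params[1:])},
        jackknife_sem={p: float(s) for p, s in zip(preds, sem[1:])},
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_dof=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue),
        condition_indices=ci,
        n_rows=len(y),
    )


def beta_permutation_test(
    table: pd.DataFrame, model: str = "I", n_perm: int = 100_000, seed: int | None = None,
    direction: str = "observed",
) -> dict[str, float]:
    """One-sided permutation p per coefficient by shuffling FX/VR response labels.

    The null reassigns each participant's pair of response values between their
    FX and VR rows at random, refitting the model each time (vectorised via the
    fixed design pseudoinverse).  By default the test is one-sided in the
    direction of the observed coefficient; pass ``direction='positive'`` or
    ``'negative'`` for a fixed a-priori direction.  P-values carry the
    (b+1)/(m+1) correction.
    """
    X, y, preds = _design(table, model)
    parts = table["participant_id"].to_numpy()
    sides = table["side"].to_numpy()
    uniq = pd.unique(parts)
    # row index of (participant, FX) and (participant, VR)
    idx_fx = np.array([np.flatnonzero((parts == p) & (sides == "FX"))[0] for p in uniq])
    idx_vr = np.array([np.flatnonzero((parts == p) & (sides == "VR"))[0] for p in uniq])

    rng = np.random.default_rng(seed)
    pinv = np.linalg.pinv(X)
    obs = pinv @ y

    Y = np.tile(y[:, None], (1, n_perm))
    swap = rng.random((len(uniq), n_perm)) < 0.5
    for k, (i, j) in enumerate(zip(idx_fx, idx_vr)):
        s = swap[k]
        Y[i, s], Y[j, s] = y[j], y[i]
    null = pinv @ Y  # (k+1, n_perm)

    if direction not in ("observed", "positive", "negative"):
        raise ValueError("direction must be 'observed', 'positive', or 'negative'")
    out = {}
    for c, name in enumerate(["intercept"] + preds):
        b = obs[c]
        if direction == "positive" or (direction == "observed" and b >= 0):
            p = (np.sum(null[c] >= b) + 1.0) / (n_perm + 1.0)
        else:
            p = (np.sum(null[c] <= b) + 1.0) / (n_perm + 1.0)
        if name != "intercept":
            out[name] = float(p)
    return out


def loo_predict(
    table: pd.DataFrame, model: str = "I", unit: str = "participant",
    pb_beta: float = 0.2, seed: int | None = 0,
) -> dict:
    """Leave-one-out predictions and robust observed-vs-predicted correlation.

    The held-out unit is the participant (both that participant's rows are
    dropped from the training fold and predicted from their own predictors);
    ``unit='row'`` holds out single rows instead.  Returns the predictions
    aligned to the table plus the percentage-bend correlation.
    """
    X, y, preds = _design(table, model)
    if unit not in ("participant", "row"):
        raise ValueError("unit must be 'participant' or 'row'")
    parts = table["participant_id"].to_numpy()
    folds = pd.unique(parts) if unit == "participant" else np.arange(len(y))
    if (unit == "participant" and len(folds) < 3) or (unit == "row" and len(folds) < 4):
        raise ValueError("need at least 3 participants for leave-one-out prediction")

    pred = np.full(len(y), np.nan)
    for f in folds:
        hold = (parts == f) if unit == "participant" else (np.arange(len(y)) == f)
        Xtr, ytr = X[~hold], y[~hold]
        if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
            logger.info("fold %s skipped: rank-deficient training design", f)
            continue
        beta = np.linalg.lstsq(Xtr, ytr, rcond=None)[0]
        pred[hold] = X[hold] @ beta

    ok = ~np.isnan(pred)
    rho, p = percentage_bend_correlation(
        y[ok], pred[ok], beta=pb_beta, seed=seed
    )
    return {
        "predicted": pred,
        "observed": y,
        "rho": float(rho),
        "p": float(p),
        "n_folds_used": int(ok.sum()),
    }
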