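"""Pre-registered exclusion rules at trial, measure, and participant level.

Rules and their scopes:

* ``same_button`` — one left/right button pressed on >= 75% of 'unseen'
  (double-denied) trials: participant excluded from all analyses.
* ``all_negative`` — every detection response "no" under one experimental
  condition (e.g. active TMS): participant excluded from all analyses.
* ``illogical_rate`` — illogical response patterns on > 2.5% of trials:
  participant excluded from all analyses.
* ``chance_pcu`` — sham 'unseen' accuracy not above chance by a one-tailed
  z-test at alpha 0.05: participant excluded from PcU analyses only.
* ``chauvenet`` — Chauvenet's criterion applied per analysis vector: the
  point is removed from that vector only.
* ``blink`` — trial removed when a TMS-induced blink coincides with the
  stimulus (pupil shift > 1 deg followed by a transitory < 1 s signal
  loss).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from unseen.trials import is_illogical

SAME_BUTTON_THRESHOLD = 0.75
ILLOGICAL_THRESHOLD = 0.025


def same_button_rate(trials: pd.DataFrame) -> tuple[float, bool]:
    """Largest one-button share on 'unseen' trials and the exclusion flag.

    'Unseen' trials are those with "no" to both detection questions,
    regardless of stimulus.  Excluded when the dominant direction response
    covers 75% or more of them.  With zero unseen trials returns
    (NaN, False): nothing to assess, flagged upstream.
    """
    unseen = trials.loc[
        (trials["resp_arrow"] == "no") & (trials["resp_something"] == "no")
    ]
    if len(unseen) == 0:
        return math.nan, False
    share = unseen["resp_direction"].value_counts(normalize=True).max()
    return float(share), bool(share >= SAME_BUTTON_THRESHOLD)


def all_negative(trials: pd.DataFrame, condition: pd.Series | None = None) -> bool:
    """True iff every detection response is "no" within the condition subset.

    ``condition`` is a boolean mask (default: all trials).  An empty subset
    returns False — there is nothing to condemn the participant on.
    """
    sub = trials if condition is None else trials.loc[condition]
    if len(sub) == 0:
        return False
    return bool((sub["resp_arrow"] == "no").all() & (sub["resp_something"] == "no").all())


def illogical_rate(trials: pd.DataFrame) -> tuple[float, bool]:
    """Illogical-response rate and the exclusion flag (rate strictly > 2.5%)."""
    if len(trials) == 0:
        return math.nan, False
    rate = float(is_illogical(trials).mean())
    return rate, bool(rate > ILLOGICAL_THRESHOLD)


def chance_test_pcu(
    pcu_value: float, n_trials: int, alpha: float = 0.05
) -> tuple[float, bool]:
    """One-tailed z-test of 'unseen' accuracy against chance (0.5).

    z = (PcU - 0.5) / sqrt(0.25 / n), the null binomial SD.  Retention
    requires one-tailed p < alpha; otherwise the participant is excluded
    from PcU analyses only.
    """
    if n_trials < 1:
        return math.nan, True
    z = (pcu_value - 0.5) / math.sqrt(0.25 / n_trials)
    p_one = norm.sf(z)
    return z, bool(p_one >= alpha)


def chauvenet(
    values: np.ndarray | pd.Series | list,
    mode: str = "exceedance",
) -> np.ndarray:
    """Chauvenet's criterion: indices of points to drop from one vector.

    A normal distribution is fitted to the full vector (sample mean, sample
    SD including the candidate point); a point is excluded when its
    likelihood times the number of points falls below 0.5.  Single pass.

    ``mode='exceedance'`` (default, the classical criterion) takes
    likelihood as the two-tailed exceedance probability of the point;
    ``mode='density'`` takes the normal density at the point, offered for
    sensitivity analysis.  A zero-SD vector yields no exclusions.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        return np.array([], dtype=int)
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.array([], dtype=int)
    z = (x - mean) / sd
    if mode == "exceedance":
        likelihood = 2.0 * norm.sf(np.abs(z))
    elif mode == "density":
        likelihood = norm.pdf(z) / sd
    else:
        raise ValueError(f"unknown chauvenet mode {mode!r}")
    return np.flatnonzero(likelihood * n < 0.5)


def blink_filter(
    trials: pd.DataFrame, pupil_events: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Remove trials contaminated by a stimulus-coincident blink.

    With ``pupil_events`` (same length/index as ``trials``; columns
    ``shift_deg``, ``loss_s``, ``coincident``) a blink is a pupil-position
    shift > 1 degree followed by a transitory (0 < loss < 1 s) signal loss
    coincident with stimulus presentation.  Without it the precomputed
    ``blink`` flag is honoured.
    """
    if pupil_events is None:
        return trials.loc[~trials["blink"].astype(bool)]
    blink = (
        (pupil_events["shift_deg"] > 1.0)
        & (pupil_events["loss_s"] > 0.0)
        & (pupil_events["loss_s"] < 1.0)
        & pupil_events["coincident"].astype(bool)
    )
    return trials.loc[~blink.to_numpy()]


def participant_screen(trials: pd.DataFrame) -> pd.DataFrame:
    """Apply the participant-level rules to every participant.

    Returns an ExclusionReport-shaped frame with one row per (participant,
    rule) firing plus informational rows for degenerate inputs; columns:
    participant_id, rule, scope, detail, excluded.
    """
    records = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        share, sb_excl = same_button_rate(sub)
        if math.isnan(share):
            records.append(
                dict(
                    participant_id=pid,
                    rule="same_button",
                    scope="participant_all",
                    detail="no unseen trials; rule not assessable",
                    excluded=False,
                )
            )
        elif sb_excl:
            records.append(
                dict(
                    participant_id=pid,
                    rule="same_button",
                    scope="participant_all",
                    detail=f"dominant unseen direction share {share:.3f} >= 0.75",
                    excluded=True,
                )
            )
        for mode in ("active", "sham"):
            if all_negative(sub, sub["tms_mode"] == mode):
                records.append(
                    dict(
                        participant_id=pid,
                        rule="all_negative",
                        scope="participant_all",
                        detail=f"all detection responses negative under {mode} TMS",
                        excluded=True,
                    )
                )
        rate, il_excl = illogical_rate(sub)
        if il_excl:
            records.append(
                dict(
                    participant_id=pid,
                    rule="illogical_rate",
                    scope="participant_all",
                    detail=f"illogical rate {rate:.4f} > 0.025",
                    excluded=True,
                )
            )
    return pd.DataFrame.from_records(
        records, columns=["participant_id", "rule", "scope", "detail", "excluded"]
    )
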