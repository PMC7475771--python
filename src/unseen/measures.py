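"""Non-parametric signal detection measures and trial classification.

Conscious detection is quantified with the non-parametric sensitivity
measure Pr = hit rate - false-alarm rate and its criterion companion
Br = FA rate / (1 - Pr), computed from a bespoke allocation of response
patterns to SDT classes.  The primary allocation (scheme ``PrC``) reflects
participants' reported strategy of detecting the *arrow*: a non-arrow
acknowledged as "something" but denied as an arrow counts as a correct
rejection, not a hit.  Single-question variants (``PrA``, ``PrS``) score
the arrow question against arrow-present signal and the something question
against any-stimulus signal, with stimulus-absent trials supplying false
alarms for both.

Two further measures are computed directly from trial subsets:

* ``PcU`` — 'unseen' capacity: left/right accuracy restricted to arrow
  trials on which the participant answered "no" to both detection
  questions.
* ``PCm`` — detection without identification: both detection questions
  answered "yes" but the direction judgement wrong, over all arrow trials.

No smoothing constants are ever added to hit or false-alarm rates; empty
denominators yield an undefined flag instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from unseen.trials import ARROW_STIMULI, TMS_MODES, TMS_TIMES, is_illogical

HIT, MISS, FA, CR = "HIT", "MISS", "FA", "CR"
UNCLASSIFIED, ILLOGICAL = "UNCLASSIFIED", "ILLOGICAL"

SCHEMES = ("PrC", "PrA", "PrS")
MEASURES = ("PrC", "BrC", "PrA", "BrA", "PrS", "BrS", "PcU", "PCm", "dprime", "c")

# Primary allocation: (stimulus kind, something?, arrow?) -> class.  The
# seven defined rows; everything else (other than illogical) is left
# unclassified under the literal reading.
_TABLE_PRC = {
    ("arrow", "yes", "yes"): HIT,
    ("arrow", "no", "no"): MISS,
    ("non_arrow", "yes", "yes"): FA,
    ("non_arrow", "yes", "no"): CR,
    ("absent", "yes", "yes"): FA,
    ("absent", "yes", "no"): FA,
    ("absent", "no", "no"): CR,
}
# Permissive completion of the two absent rows, for sensitivity analysis.
_TABLE_PRC_PERMISSIVE = {
    ("arrow", "yes", "no"): MISS,
    ("non_arrow", "no", "no"): CR,
}


def _stim_kind(stimulus: str) -> str:
    return "arrow" if stimulus in ARROW_STIMULI else stimulus


def classify_trial(
    stimulus: str,
    resp_something: str,
    resp_arrow: str,
    scheme: str = "PrC",
    strict_table1: bool = True,
) -> str:
    """Classify one trial into an SDT class under the given scheme.

    Total over the enum domains: every combination maps to exactly one of
    HIT/MISS/FA/CR/UNCLASSIFIED/ILLOGICAL.  The illogical pattern (arrow
    "yes", something "no") is ILLOGICAL under every scheme.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if resp_arrow == "yes" and resp_something == "no":
        return ILLOGICAL
    kind = _stim_kind(stimulus)
    if scheme == "PrC":
        table = dict(_TABLE_PRC)
        if not strict_table1:
            table.update(_TABLE_PRC_PERMISSIVE)
        return table.get((kind, resp_something, resp_arrow), UNCLASSIFIED)
    if scheme == "PrA":
        # Arrow question alone: arrow stimuli are signal, absent supplies
        # false alarms; non-arrow trials carry no truth value here.
        if kind == "arrow":
            return HIT if resp_arrow == "yes" else MISS
        if kind == "absent":
            return FA if resp_arrow == "yes" else CR
        return UNCLASSIFIED
    # PrS: something question alone; arrow and non-arrow are both signal.
    if kind in ("arrow", "non_arrow"):
        return HIT if resp_something == "yes" else MISS
    return FA if resp_something == "yes" else CR


def classify_frame(
    df: pd.DataFrame, scheme: str = "PrC", strict_table1: bool = True
) -> pd.Series:
    """Vectorized :func:`classify_trial` over a trial table."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    kind = np.where(df["stimulus"].isin(ARROW_STIMULI), "arrow", df["stimulus"])
    s_yes = (df["resp_something"] == "yes").to_numpy()
    a_yes = (df["resp_arrow"] == "yes").to_numpy()
    out = np.full(len(df), UNCLASSIFIED, dtype=object)
    if scheme == "PrC":
        table = dict(_TABLE_PRC)
        if not strict_table1:
            table.update(_TABLE_PRC_PERMISSIVE)
        for (k, s, a), label in table.items():
            mask = (kind == k) & (s_yes == (s == "yes")) & (a_yes == (a == "yes"))
            out[mask] = label
    elif scheme == "PrA":
        arrow = kind == "arrow"
        absent = kind == "absent"
        out[arrow & a_yes] = HIT
        out[arrow & ~a_yes] = MISS
        out[absent & a_yes] = FA
        out[absent & ~a_yes] = CR
    else:
        signal = (kind == "arrow") | (kind == "non_arrow")
        absent = kind == "absent"
        out[signal & s_yes] = HIT
        out[signal & ~s_yes] = MISS
        out[absent & s_yes] = FA
        out[absent & ~s_yes] = CR
    out[a_yes & ~s_yes] = ILLOGICAL
    return pd.Series(out, index=df.index, name="sdt_class")


@dataclass(frozen=True)
class SdtCounts:
    """Hit/miss/FA/CR tallies for one analysis cell under one scheme."""

    hits: int
    misses: int
    fas: int
    crs: int
    unclassified: int = 0
    scheme: str = "PrC"

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.fas, self.crs, self.unclassified) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_classified(self) -> int:
        return self.hits + self.misses + self.fas + self.crs


def sdt_counts(
    df: pd.DataFrame, scheme: str = "PrC", strict_table1: bool = True
) -> SdtCounts:
    """Tally SDT classes over a trial subset (one analysis cell)."""
    labels = classify_frame(df, scheme, strict_table1)
    c = labels.value_counts()
    return SdtCounts(
        hits=int(c.get(HIT, 0)),
        misses=int(c.get(MISS, 0)),
        fas=int(c.get(FA, 0)),
        crs=int(c.get(CR, 0)),
        unclassified=int(c.get(UNCLASSIFIED, 0)),
        scheme=scheme,
    )


def rates(counts: SdtCounts) -> tuple[float, float]:
    """Raw (hit rate, false-alarm rate); NaN where the denominator is empty."""
    n_sig = counts.hits + counts.misses
    n_noise = counts.fas + counts.crs
    hr = counts.hits / n_sig if n_sig > 0 else math.nan
    far = counts.fas / n_noise if n_noise > 0 else math.nan
    return hr, far


def pr(hit_rate: float, fa_rate: float) -> float:
    """Non-parametric sensitivity: hit rate minus false-alarm rate."""
    return hit_rate - fa_rate


def br(fa_rate: float, pr_value: float) -> float:
    """Non-parametric criterion: FA rate / (1 - Pr); NaN at Pr = 1."""
    denom = 1 - pr_value  # int literal: exact under rational inputs
    if denom == 0 or math.isnan(denom) or math.isnan(fa_rate):
        return math.nan
    return fa_rate / denom


def _correct_direction(df: pd.DataFrame) -> pd.Series:
    truth = df["stimulus"].map({"arrow_left": "left", "arrow_right": "right"})
    return df["resp_direction"] == truth


def pcu(df: pd.DataFrame) -> tuple[float, int]:
    """'Unseen' capacity of one cell: (proportion correct, n).

    Left/right accuracy over arrow-present trials on which both detection
    questions were answered "no".  Returns (NaN, 0) when no trial
    qualifies.
    """
    qualifying = (
        df["stimulus"].isin(ARROW_STIMULI)
        & (df["resp_arrow"] == "no")
        & (df["resp_something"] == "no")
    )
    sub = df.loc[qualifying]
    n = len(sub)
    if n == 0:
        return math.nan, 0
    return float(_correct_direction(sub).mean()), n


def default_pcm_numerator(df: pd.DataFrame) -> pd.Series:
    """Acknowledged awareness (both questions "yes") with a wrong direction."""
    return (
        df["stimulus"].isin(ARROW_STIMULI)
        & (df["resp_arrow"] == "yes")
        & (df["resp_something"] == "yes")
        & ~_correct_direction(df)
    )


def default_pcm_denominator(df: pd.DataFrame) -> pd.Series:
    """All arrow-present trials."""
    return df["stimulus"].isin(ARROW_STIMULI)


def pcm(
    df: pd.DataFrame,
    numerator: Callable[[pd.DataFrame], pd.Series] = default_pcm_numerator,
    denominator: Callable[[pd.DataFrame], pd.Series] = default_pcm_denominator,
) -> tuple[float, int]:
    """Detection-without-identification rate of one cell: (value, n).

    The numerator/denominator predicates are hooks so alternative variants
    can be scored without changing the default.  Returns (NaN, 0) when the
    denominator is empty.
    """
    den = denominator(df)
    n = int(den.sum())
    if n == 0:
        return math.nan, 0
    num = int((numerator(df) & den).sum())
    return num / n, n


def dprime_c(counts: SdtCounts, clamp: bool = True) -> tuple[float, float]:
    """Parametric d' and c from the same tallies (supplementary comparison).

    Extreme rates are clamped to [1/(2N), 1 - 1/(2N)] per cell (N the
    cell's signal or noise count) so both statistics stay finite; the
    non-parametric measures need no such correction.
    """
    hr, far = rates(counts)
    if math.isnan(hr) or math.isnan(far):
        return math.nan, math.nan
    if clamp:
        n_sig = counts.hits + counts.misses
        n_noise = counts.fas + counts.crs
        hr = min(max(hr, 1 / (2 * n_sig)), 1 - 1 / (2 * n_sig))
        far = min(max(far, 1 / (2 * n_noise)), 1 - 1 / (2 * n_noise))
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return zh - zf, -0.5 * (zh + zf)


_CELL_KEYS = ["participant_id", "tms_mode", "tms_time"]


def _scheme_counts(trials: pd.DataFrame, scheme: str, strict: bool) -> pd.DataFrame:
    """Per-cell HIT/MISS/FA/CR counts for one allocation scheme."""
    labels = classify_frame(trials, scheme, strict)
    ct = pd.crosstab([trials[k] for k in _CELL_KEYS], labels)
    for col in (HIT, MISS, FA, CR):
        if col not in ct.columns:
            ct[col] = 0
    return ct


def _pr_br_frames(ct: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Vectorized (Pr, Br, n_classified) per cell from a count frame."""
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = ct[HIT] / (ct[HIT] + ct[MISS]).replace(0, np.nan)
        far = ct[FA] / (ct[FA] + ct[CR]).replace(0, np.nan)
        prv = hr - far
        brv = far / (1.0 - prv).replace(0, np.nan)
    n = ct[HIT] + ct[MISS] + ct[FA] + ct[CR]
    return prv, brv, n


def measure_table(
    trials: pd.DataFrame,
    measures: Iterable[str] = ("PrC", "BrC", "PcU", "PCm"),
    strict_table1: bool = True,
) -> pd.DataFrame:
    """Tidy measure table: one row per participant x mode x time x measure.

    Columns: participant_id, tms_mode, tms_time, measure, value, n,
    defined.  Trials flagged for exclusion (blinks, excluded participants)
    must be removed upstream; illogical trials are dropped here from all
    denominators — they feed only the illogical-rate exclusion rule.
    """
    measures = list(measures)
    unknown = [m for m in measures if m not in MEASURES]
    if unknown:
        raise ValueError(f"unknown measure(s) {unknown}")
    trials = trials.loc[~is_illogical(trials)]

    parts: dict[str, pd.DataFrame] = {}

    def emit(name: str, value: pd.Series, n: pd.Series) -> None:
        parts[name] = pd.DataFrame({"value": value.astype(float), "n": n.astype(int)})

    schemes_needed = {m: "Pr" + m[2] for m in measures if m[:2] in ("Pr", "Br")}
    if "dprime" in measures or "c" in measures:
        schemes_needed["dprime_c"] = "PrC"
    counts: dict[str, pd.DataFrame] = {}
    for scheme in set(schemes_needed.values()):
        counts[scheme] = _scheme_counts(trials, scheme, strict_table1)
    for m in measures:
        if m[:2] in ("Pr", "Br"):
            ct = counts[schemes_needed[m]]
            prv, brv, n = _pr_br_frames(ct)
            emit(m, prv if m.startswith("Pr") else brv, n)
    if "PcU" in measures:
        qual = (
            trials["stimulus"].isin(ARROW_STIMULI)
            & (trials["resp_arrow"] == "no")
            & (trials["resp_something"] == "no")
        )
        correct = _correct_direction(trials) & qual
        g = trials.assign(q=qual, ok=correct).groupby(_CELL_KEYS, sort=True)[["q", "ok"]].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            emit("PcU", g["ok"] / g["q"].replace(0, np.nan), g["q"])
    if "PCm" in measures:
        den = trials["stimulus"].isin(ARROW_STIMULI)
        num = default_pcm_numerator(trials)
        g = trials.assign(den=den, num=num & den).groupby(_CELL_KEYS, sort=True)[
            ["den", "num"]
        ].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            emit("PCm", g["num"] / g["den"].replace(0, np.nan), g["den"])
    if "dprime" in measures or "c" in measures:
        ct = counts["PrC"]
        n_sig = (ct[HIT] + ct[MISS]).astype(float)
        n_noise = (ct[FA] + ct[CR]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            hr = (ct[HIT] / n_sig.replace(0, np.nan)).clip(
                1 / (2 * n_sig), 1 - 1 / (2 * n_sig)
            )
            far = (ct[FA] / n_noise.replace(0, np.nan)).clip(
                1 / (2 * n_noise), 1 - 1 / (2 * n_noise)
            )
        zh, zf = norm.ppf(hr), norm.ppf(far)
        n = (n_sig + n_noise).astype(int)
        if "dprime" in measures:
            emit("dprime", pd.Series(zh - zf, index=ct.index), n)
        if "c" in measures:
            emit("c", pd.Series(-0.5 * (zh + zf), index=ct.index), n)

    records = []
    for m in measures:
        block = parts[m].reset_index()
        block.insert(3, "measure", m)
        records.append(block)
    out = pd.concat(records, ignore_index=True)
    out["defined"] = out["value"].notna()
    out["tms_mode"] = pd.Categorical(out["tms_mode"], TMS_MODES)
    out["tms_time"] = pd.Categorical(out["tms_time"], TMS_TIMES)
    return out.sort_values(_CELL_KEYS, kind="stable", ignore_index=True)
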