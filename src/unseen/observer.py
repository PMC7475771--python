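"""Generative observer emulating a participant in the masking task.

A single-channel equal-variance Gaussian detection model drives both
yes/no questions: each trial draws evidence e ~ N(strength, 1) and the
participant answers "something?" when e exceeds a liberal criterion and
"arrow?" when e exceeds a stricter one (the ordering guarantees that,
absent lapses, no illogical response pattern can occur).  An independent
left/right channel with its own sensitivity d_dir produces the direction
response, correct with probability Phi(d_dir / sqrt(2)) — the simplest
structure that realizes above-chance 'unseen' discrimination.  This is a
data-shape emulator, not a model of cortical processing.

Active TMS adds condition-specific offsets: a (non-positive) evidence
suppression on stimulus-present trials, a shift of both criteria
(negative = more liberal reporting), and a (non-positive) suppression of
direction sensitivity.  Rare lapses flip each response independently and
are the sole source of illogical patterns.

Defaults emulate the study conditions: threshold-level detection
(sham PrC ~ 0.5, maintained per participant by the same calibration loop
the task used, solving the psychometric function for PrC = 0.5),
above-chance 'unseen' discrimination (~0.65 under the 110 ms pulse, with
wide individual spread so the above-chance screening rule excludes a
realistic fraction of participants), detection suppression by the 110 ms
pulse alone, extra sensitivity suppression from early (30/70 ms) pulses,
and criterion relaxation from late (150/190 ms) pulses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from unseen.inference import AnalysisConfig, run_report
from unseen.trials import ARROW_STIMULI, DesignSpec, TMS_TIMES, generate_design


@dataclass(frozen=True)
class TmsEffect:
    """Additive effect of one active-TMS condition on the observer.

    d_signal (<= 0) shifts the evidence mean on stimulus-present trials;
    d_criteria shifts both report criteria (negative = more "yes");
    d_direction (<= 0) shifts the left/right channel sensitivity.
    """

    d_signal: float = 0.0
    d_criteria: float = 0.0
    d_direction: float = 0.0

    def __post_init__(self) -> None:
        if self.d_signal > 0 or self.d_direction > 0:
            raise ValueError("TMS suppression terms must be <= 0")


ZERO_EFFECT = TmsEffect()

#: Default active-TMS effects (all conditions include the 110 ms pulse).
DEFAULT_TMS_EFFECTS: dict[str, TmsEffect] = {
    "BIP_only": TmsEffect(d_signal=-0.26, d_criteria=0.0, d_direction=-0.33),
    "E30_BIP": TmsEffect(d_signal=-0.40, d_criteria=0.0, d_direction=-0.50),
    "E70_BIP": TmsEffect(d_signal=-0.35, d_criteria=0.0, d_direction=-0.40),
    "BIP_L150": TmsEffect(d_signal=-0.27, d_criteria=-0.16, d_direction=-0.28),
    "BIP_L190": TmsEffect(d_signal=-0.26, d_criteria=-0.18, d_direction=-0.24),
}


@dataclass(frozen=True)
class ObserverParams:
    """One participant's generative parameters (evidence-SD units)."""

    signal_strength: float = 2.0
    nonarrow_strength: float = 0.6
    criterion_something: float = 1.0
    criterion_arrow: float = 1.6
    direction_sensitivity: float = 0.91
    lapse_rate: float = 0.005
    tms_effects: Mapping[str, TmsEffect] = field(
        default_factory=lambda: dict(DEFAULT_TMS_EFFECTS)
    )

    def __post_init__(self) -> None:
        if self.criterion_arrow < self.criterion_something:
            raise ValueError(
                "criterion_arrow must be >= criterion_something "
                "(the arrow question reflects a higher level of awareness)"
            )
        if not 0 <= self.lapse_rate <= 0.05:
            raise ValueError("lapse_rate must be in [0, 0.05]")
        if self.signal_strength < 0 or self.nonarrow_strength < 0:
            raise ValueError("stimulus strengths must be >= 0")
        if self.direction_sensitivity < 0:
            raise ValueError("direction_sensitivity must be >= 0")
        unknown = set(self.tms_effects) - set(TMS_TIMES)
        if unknown:
            raise ValueError(f"unknown TMS time(s) in effects: {sorted(unknown)}")

    def effect(self, tms_mode: str, tms_time: str) -> TmsEffect:
        if tms_mode == "sham":
            return ZERO_EFFECT
        return self.tms_effects.get(tms_time, ZERO_EFFECT)


def _pattern_probs(p_low: float, p_mid: float, p_high: float, lapse: float) -> dict:
    """P(something, arrow response pattern) given evidence-region masses.

    Regions: low (below both criteria, base pattern no/no), mid (between,
    base yes/no), high (above both, base yes/yes).  Each response flips
    independently with the lapse rate.
    """
    lam = lapse
    keep = 1.0 - lam
    out = {}
    for s in ("yes", "no"):
        for a in ("yes", "no"):
            p = 0.0
            for region, (bs, ba) in (
                (p_low, ("no", "no")),
                (p_mid, ("yes", "no")),
                (p_high, ("yes", "yes")),
            ):
                ps = keep if s == bs else lam
                pa = keep if a == ba else lam
                p += region * ps * pa
            out[(s, a)] = p
    return out


def _regions(mu: float, c_s: float, c_a: float) -> tuple[float, float, float]:
    low = norm.cdf(c_s - mu)
    high = norm.sf(c_a - mu)
    return low, 1.0 - low - high, high


def expected_prc(params: ObserverParams, tms_time: str | None = None) -> float:
    """Closed-form expected PrC of a cell (sham, or one active condition).

    Expected class probabilities follow from the Gaussian evidence regions
    and lapse mixing; HR and FAR use the primary allocation with arrow,
    non-arrow and absent trials in their design ratio 2:1:1.
    """
    eff = ZERO_EFFECT if tms_time is None else params.tms_effects.get(tms_time, ZERO_EFFECT)
    c_s = params.criterion_something + eff.d_criteria
    c_a = params.criterion_arrow + eff.d_criteria
    mu_arrow = max(params.signal_strength + eff.d_signal, 0.0)
    mu_na = max(params.nonarrow_strength + eff.d_signal, 0.0)
    lam = params.lapse_rate

    arrow = _pattern_probs(*_regions(mu_arrow, c_s, c_a), lam)
    na = _pattern_probs(*_regions(mu_na, c_s, c_a), lam)
    absent = _pattern_probs(*_regions(0.0, c_s, c_a), lam)

    p_hit = arrow[("yes", "yes")]
    p_miss = arrow[("no", "no")]
    hr = p_hit / (p_hit + p_miss)
    # Noise side: non-arrow FA = yes/yes, CR = yes/no; absent FA = yes/yes
    # or yes/no, CR = no/no.  Equal trial counts for non-arrow and absent.
    p_fa = na[("yes", "yes")] + absent[("yes", "yes")] + absent[("yes", "no")]
    p_cr = na[("yes", "no")] + absent[("no", "no")]
    far = p_fa / (p_fa + p_cr)
    return hr - far


def expected_pcu(params: ObserverParams, tms_time: str | None = None) -> float:
    """Expected 'unseen' accuracy: lapse-mixed Phi(d_dir / sqrt(2))."""
    eff = ZERO_EFFECT if tms_time is None else params.tms_effects.get(tms_time, ZERO_EFFECT)
    d = max(params.direction_sensitivity + eff.d_direction, 0.0)
    p = norm.cdf(d / math.sqrt(2.0))
    return (1 - params.lapse_rate) * p + params.lapse_rate * (1 - p)


def simulate_responses(
    design: pd.DataFrame, params: ObserverParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill the response columns of a design scaffold (vectorized)."""
    df = design.copy()
    n = len(df)
    stim = df["stimulus"].to_numpy()
    active = (df["tms_mode"] == "active").to_numpy()
    time = df["tms_time"].to_numpy()

    d_signal = np.zeros(n)
    d_crit = np.zeros(n)
    d_dir = np.zeros(n)
    for t, eff in params.tms_effects.items():
        mask = active & (time == t)
        d_signal[mask] = eff.d_signal
        d_crit[mask] = eff.d_criteria
        d_dir[mask] = eff.d_direction

    strength = np.where(
        np.isin(stim, ARROW_STIMULI),
        params.signal_strength,
        np.where(stim == "non_arrow", params.nonarrow_strength, 0.0),
    )
    present = strength > 0
    strength = np.where(present, np.maximum(strength + d_signal, 0.0), 0.0)

    e = rng.normal(strength, 1.0)
    c_s = params.criterion_something + d_crit
    c_a = params.criterion_arrow + d_crit
    something = e > c_s
    arrow = e > c_a

    d_eff = np.maximum(params.direction_sensitivity + d_dir, 0.0)
    p_correct = norm.cdf(d_eff / math.sqrt(2.0))
    correct = rng.random(n) < p_correct
    truth_right = stim == "arrow_right"
    # Non-arrow/absent trials have no truth value: a fair guess.
    guess_right = rng.random(n) < 0.5
    is_arrow = np.isin(stim, ARROW_STIMULI)
    resp_right = np.where(is_arrow, truth_right == correct, guess_right)

    if params.lapse_rate > 0:
        flip = rng.random((n, 3)) < params.lapse_rate
        arrow = arrow ^ flip[:, 0]
        something = something ^ flip[:, 1]
        resp_right = resp_right ^ flip[:, 2]

    df["resp_arrow"] = np.where(arrow, "yes", "no")
    df["resp_something"] = np.where(something, "yes", "no")
    df["resp_direction"] = np.where(resp_right, "right", "left")
    return df


def calibrate_signal(
    params: ObserverParams,
    target_prc: float = 0.5,
    tol: float = 0.001,
    max_strength: float = 12.0,
) -> float:
    """Solve the observer's psychometric function for a sham PrC target.

    Monotone bisection on ``signal_strength`` against the closed-form
    sham PrC, mirroring the luminance-calibration loop of the task.
    Raises ValueError when the target is outside the attainable range.
    """
    lo, hi = 0.0, max_strength
    f = lambda mu: expected_prc(replace(params, signal_strength=mu))
    if not f(lo) - tol <= target_prc <= f(hi) + tol:
        raise ValueError(
            f"target PrC {target_prc} outside attainable range "
            f"[{f(lo):.3f}, {f(hi):.3f}]"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if abs(f(mid) - target_prc) < tol:
            return mid
        if f(mid) < target_prc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class CohortSpec:
    """Population from which participants' parameters are drawn.

    Individual differences: criteria and direction sensitivity jitter with
    the given SDs; each participant's TMS effects are the population means
    scaled by a participant factor ~ N(1, effect_scale_sd) truncated at 0;
    each participant's signal strength is calibrated to the sham PrC
    target, as in the task's luminance calibration.
    """

    base: ObserverParams = field(default_factory=ObserverParams)
    criterion_sd: float = 0.12
    criterion_gap_min: float = 0.2
    direction_sd: float = 0.5
    lapse_max: float = 0.01
    effect_scale_sd: float = 0.4
    target_prc: float = 0.5

    def draw(self, rng: np.random.Generator) -> ObserverParams:
        c_s = self.base.criterion_something + rng.normal(0, self.criterion_sd)
        gap = max(
            self.base.criterion_arrow - self.base.criterion_something
            + rng.normal(0, self.criterion_sd),
            self.criterion_gap_min,
        )
        d_dir = max(self.base.direction_sensitivity + rng.normal(0, self.direction_sd), 0.0)
        lapse = float(rng.uniform(0.0, self.lapse_max))
        scale = max(rng.normal(1.0, self.effect_scale_sd), 0.0)
        effects = {
            t: TmsEffect(eff.d_signal * scale, eff.d_criteria * scale,
                         eff.d_direction * scale)
            for t, eff in self.base.tms_effects.items()
        }
        p = ObserverParams(
            signal_strength=self.base.signal_strength,
            nonarrow_strength=self.base.nonarrow_strength,
            criterion_something=c_s,
            criterion_arrow=c_s + gap,
            direction_sensitivity=d_dir,
            lapse_rate=lapse,
            tms_effects=effects,
        )
        return replace(p, signal_strength=calibrate_signal(p, self.target_prc))


def null_cohort_spec() -> CohortSpec:
    """A cohort whose TMS does nothing (for false-positive calibration)."""
    base = ObserverParams(tms_effects={t: ZERO_EFFECT for t in TMS_TIMES})
    return CohortSpec(base=base)


def recovery_cohort_spec(
    early_d_signal: float = -0.3,
    early_d_direction: float = -0.3,
    late_d_criteria: float = -0.3,
) -> CohortSpec:
    """The parameter-recovery scenario: a clean temporal dissociation.

    Early pulses suppress sensitivity (evidence mean and direction
    channel); late pulses relax the report criteria; the 110 ms pulse
    alone does nothing.  Recovering this pattern means the pipeline's
    early-vs-late contrasts come out negative for PrC and PcU and
    late-dominant (negative early-minus-late) for BrC.
    """
    effects = {t: ZERO_EFFECT for t in TMS_TIMES}
    early = TmsEffect(early_d_signal, 0.0, early_d_direction)
    effects["E30_BIP"] = early
    effects["E70_BIP"] = early
    late = TmsEffect(0.0, late_d_criteria, 0.0)
    effects["BIP_L150"] = late
    effects["BIP_L190"] = late
    return CohortSpec(base=ObserverParams(tms_effects=effects))


def simulate_cohort(
    n_participants: int,
    cohort: CohortSpec | None = None,
    design: DesignSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full cohort: parameter draws, design, responses.

    Deterministic under ``seed``.  The design spec's own participant count
    is overridden by ``n_participants``.
    """
    cohort = cohort or CohortSpec()
    design = design or DesignSpec()
    rng = np.random.default_rng(seed)
    spec = DesignSpec(
        n_participants=n_participants,
        blocks_active=design.blocks_active,
        blocks_sham=design.blocks_sham,
        trials_per_block=design.trials_per_block,
        reps_per_condition=design.reps_per_condition,
        seed=int(rng.integers(2**31 - 1)),
    )
    scaffold = generate_design(spec)
    frames = []
    for pid, block in scaffold.groupby("participant_id", sort=True):
        params = cohort.draw(rng)
        frames.append(simulate_responses(block, params, rng))
    return pd.concat(frames, ignore_index=True)


def recovery_experiment(
    cohort: CohortSpec,
    n_cohorts: int = 100,
    n_participants: int = 40,
    design: DesignSpec | None = None,
    measures: tuple = ("PrC", "PcU", "BrC"),
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeatedly simulate cohorts and run the pipeline's contrasts.

    Returns one row per cohort x measure with the early-vs-late contrast
    mean, t, p and sign, from which sign-recovery and false-positive rates
    are summarized.  Bayes factors are skipped here for speed; the
    frequentist gate carries the decisions.
    """
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig(measures=tuple(measures), alpha=alpha, compute_bayes=False)
    rows = []
    for c in range(n_cohorts):
        trials = simulate_cohort(
            n_participants, cohort, design, seed=int(rng.integers(2**31 - 1))
        )
        bundle = run_report(trials, cfg)
        for _, r in bundle.report.iterrows():
            rows.append(dict(
                cohort=c, measure=r["measure"], mean=r["mean"], t=r["t"],
                p=r["p"], n=r["n"], negative=bool(r["mean"] < 0),
                significant=bool(r["p"] < alpha),
            ))
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame) -> pd.DataFrame:
    """Per-measure sign-recovery and rejection rates over cohorts."""
    return results.groupby("measure", sort=True).agg(
        n_cohorts=("cohort", "count"),
        frac_negative=("negative", "mean"),
        frac_significant=("significant", "mean"),
        mean_contrast=("mean", "mean"),
    ).reset_index()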