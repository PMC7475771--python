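"""Sham normalization, temporal contrasts, frequentist tests, and the report.

Every inference is carried by a per-participant *contrast vector*.  The
unit analysis normalizes each active-TMS cell against its sham baseline
(active minus sham), then contrasts the early TMS conditions (extra pulse
at 30/70 ms, probing the feed-forward sweep) against the late ones
(150/190 ms, probing recurrent processing):

    mean(delta_E30, delta_E70) - mean(delta_L150, delta_L190)

The sign convention is early-minus-late throughout.  ``run_report`` wires
the pre-registered order of operations — blink filter, participant-level
exclusions, measure computation, the PcU chance rule, per-vector
Chauvenet outlier removal, t-tests and the three Bayes-factor families in
both prior directions — into a single report bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from unseen import bayes
from unseen.bayes import BayesFactorError, LikelihoodSummary
from unseen.exclusions import (
    blink_filter,
    chance_test_pcu,
    chauvenet,
    participant_screen,
)
from unseen.measures import measure_table, pcu
from unseen.trials import EARLY_TIMES, LATE_TIMES, TMS_TIMES

REPORT_MEASURES = ("PcU", "PrC", "PCm", "BrC", "PrA", "BrA", "PrS", "BrS")


@dataclass
class ContrastVector:
    """Per-participant values of one named contrast; the unit of inference."""

    name: str
    values: pd.Series  # indexed by participant_id
    excluded_outliers: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def df(self) -> int:
        return len(self.values) - 1

    def drop_outliers(self, mode: str = "exceedance") -> "ContrastVector":
        """Return a copy with Chauvenet-flagged points removed."""
        idx = chauvenet(self.values.to_numpy(), mode=mode)
        dropped = list(self.values.index[idx])
        kept = self.values.drop(index=dropped)
        return ContrastVector(
            self.name,
            kept,
            excluded_outliers=self.excluded_outliers + dropped,
            provenance={**self.provenance, "chauvenet": mode},
        )


@dataclass(frozen=True)
class TestResult:
    """One-sample/paired t-test summary matching the report column census."""

    t: float
    df: int
    p: float
    mean: float
    ci95: tuple[float, float]
    cohens_d: float
    n: int
    degenerate: bool = False  # zero-variance vector


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable switches of the analysis pipeline (defaults = primary path)."""

    measures: tuple = REPORT_MEASURES
    alpha: float = 0.05
    likelihood: str = "t"  # BF likelihood: "t" or "normal"
    prior_scale_as_variance: bool = False
    chauvenet_mode: str = "exceedance"
    strict_table1: bool = True
    strict_contrast_members: bool = False  # drop participant if any member undefined
    fine_pair: tuple = ("E30_BIP", "BIP_L190")
    prc_uniform_range: float = 0.5  # PrC spans threshold 0.5 down to 0
    compute_bayes: bool = True  # skipping leaves the frequentist gate only

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        for key in ("measures", "fine_pair"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def sham_normalize(cells: pd.DataFrame) -> pd.DataFrame:
    """Active-minus-sham delta per participant x TMS time x measure.

    Input is a tidy measure table; output columns: participant_id,
    tms_time, measure, delta, defined.  A delta is undefined when either
    member cell is undefined.
    """
    wide = cells.pivot_table(
        index=["participant_id", "tms_time", "measure"],
        columns="tms_mode",
        values="value",
        aggfunc="first",
        observed=True,
    ).reset_index()
    for mode in ("active", "sham"):
        if mode not in wide.columns:
            wide[mode] = math.nan
    wide["delta"] = wide["active"] - wide["sham"]
    wide["defined"] = wide["delta"].notna()
    return wide[["participant_id", "tms_time", "measure", "delta", "defined"]]


def _phase_mean(
    delta: pd.DataFrame, measure: str, times: Iterable[str], strict: bool
) -> pd.Series:
    sub = delta.loc[(delta["measure"] == measure) & delta["tms_time"].isin(list(times))]
    grouped = sub.groupby("participant_id")["delta"]
    out = grouped.mean()  # nan-aware: undefined members are skipped
    if strict:
        out[grouped.apply(lambda s: s.isna().any())] = math.nan
    return out


def early_late_contrast(
    delta: pd.DataFrame, measure: str, strict: bool = False
) -> ContrastVector:
    """Early-minus-late contrast vector for one measure.

    Per participant: mean of the early deltas (E30, E70) minus mean of the
    late deltas (L150, L190).  Undefined member cells are skipped
    (``strict=True`` drops the participant instead); participants with an
    entirely undefined side are dropped and recorded in provenance.
    """
    early = _phase_mean(delta, measure, EARLY_TIMES, strict)
    late = _phase_mean(delta, measure, LATE_TIMES, strict)
    vec = (early - late).dropna()
    dropped = sorted(set(early.index.union(late.index)) - set(vec.index))
    return ContrastVector(
        f"{measure} early_vs_late",
        vec,
        provenance={"sign": "early_minus_late", "dropped_undefined": dropped},
    )


def fine_contrast(
    delta: pd.DataFrame, measure: str, time_a: str, time_b: str
) -> ContrastVector:
    """Single-time contrast delta(time_a) - delta(time_b) per participant."""
    for t in (time_a, time_b):
        if t not in TMS_TIMES:
            raise ValueError(f"unknown TMS time {t!r}")
    a = _phase_mean(delta, measure, [time_a], strict=False)
    b = _phase_mean(delta, measure, [time_b], strict=False)
    vec = (a - b).dropna()
    return ContrastVector(
        f"{measure} {time_a}_vs_{time_b}",
        vec,
        provenance={"sign": f"{time_a}_minus_{time_b}"},
    )


def one_sample_t(values, null: float = 0.0) -> TestResult:
    """Classical one-sample t-test with 95% CI and Cohen's d = mean/SD."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = x.size
    if n < 2:
        return TestResult(math.nan, n - 1, math.nan, float(np.mean(x)) if n else math.nan,
                          (math.nan, math.nan), math.nan, n, degenerate=True)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd <= 1e-12 * max(abs(mean), 1.0):  # constant up to rounding
        # Constant vector: t is infinite in the sign of the shift.
        sign = math.copysign(1.0, mean - null) if mean != null else 0.0
        tval = sign * math.inf if mean != null else 0.0
        return TestResult(tval, df, 0.0 if mean != null else 1.0, mean,
                          (mean, mean), math.inf * sign if mean != null else 0.0,
                          n, degenerate=True)
    sem = sd / math.sqrt(n)
    tval = (mean - null) / sem
    p = 2.0 * stats.t.sf(abs(tval), df)
    half = stats.t.ppf(0.975, df) * sem
    return TestResult(tval, df, p, mean, (mean - half, mean + half), (mean - null) / sd, n)


def paired_t(a, b) -> TestResult:
    """Paired t-test; exactly one_sample_t(a - b, 0) on aligned pairs."""
    a = pd.Series(a).astype(float)
    b = pd.Series(b).astype(float)
    diff = (a - b).dropna()
    return one_sample_t(diff)


def within_subject_se(cells: pd.DataFrame, measure: str) -> pd.Series:
    """Within-subject SE per (mode, time) condition, Cousineau-Morey style.

    Each participant's condition profile is centred on the grand mean
    (removing between-subject offsets); per-condition SEs of the centred
    data are scaled by sqrt(k/(k-1)) over the k conditions.  Participants
    with any undefined cell are dropped; with a single condition the SE is
    undefined.
    """
    sub = cells.loc[cells["measure"] == measure]
    wide = sub.pivot_table(
        index="participant_id", columns=["tms_mode", "tms_time"], values="value",
        aggfunc="first", observed=True,
    ).dropna(axis=0)
    k = wide.shape[1]
    if k < 2 or wide.shape[0] < 2:
        return pd.Series(math.nan, index=wide.columns, name=measure)
    centered = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    se = centered.std(ddof=1) / math.sqrt(wide.shape[0])
    return se * math.sqrt(k / (k - 1))


@dataclass
class ReportBundle:
    """Everything one analysis run produces."""

    report: pd.DataFrame
    baseline: pd.DataFrame
    fine: pd.DataFrame
    exclusions: pd.DataFrame
    vectors: dict
    log: list

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "report.csv", index=False)
        self.baseline.to_csv(out / "baseline.csv", index=False)
        self.fine.to_csv(out / "fine_contrasts.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def _safe_bf(fn, *args, log: list, what: str, **kwargs) -> float:
    try:
        return fn(*args, **kwargs).bf
    except BayesFactorError as exc:
        log.append(f"{what}: undefined ({exc})")
        return math.nan


def _bayes_columns(
    vec: ContrastVector,
    tres: TestResult,
    orth_mean: float,
    uni_range: float | None,
    cfg: AnalysisConfig,
    log: list,
) -> dict:
    """All Bayes factors for one contrast vector, both prior directions.

    'early>late' hypothesizes stronger suppression early, i.e. a negative
    early-minus-late mean, hence the negative-direction prior.
    """
    out = {
        "bf_main_early_gt_late": math.nan,
        "bf_main_late_gt_early": math.nan,
        "bf_uni_early_gt_late": math.nan,
        "bf_uni_late_gt_early": math.nan,
        "bf_jzs": math.nan,
    }
    if not cfg.compute_bayes:
        return out
    if tres.degenerate or tres.n < 2:
        log.append(f"{vec.name}: degenerate vector, Bayes factors skipped")
        return out
    se = float(np.std(np.asarray(vec.values, dtype=float), ddof=1) / math.sqrt(tres.n))
    lik = LikelihoodSummary(tres.mean, se, tres.df)
    sd = bayes.prior_sd_from_orthogonal(orth_mean, as_variance=cfg.prior_scale_as_variance)
    if sd > 0:
        out["bf_main_early_gt_late"] = _safe_bf(
            bayes.bf_half_normal, lik, sd, "negative", cfg.likelihood,
            log=log, what=f"{vec.name} BF_main(early>late)")
        out["bf_main_late_gt_early"] = _safe_bf(
            bayes.bf_half_normal, lik, sd, "positive", cfg.likelihood,
            log=log, what=f"{vec.name} BF_main(late>early)")
    else:
        log.append(f"{vec.name}: orthogonal contrast is zero, BF_main undefined")
    if uni_range is not None and uni_range > 0:
        out["bf_uni_early_gt_late"] = _safe_bf(
            bayes.bf_uniform, lik, -uni_range, 0.0, cfg.likelihood,
            log=log, what=f"{vec.name} BF_uni(early>late)")
        out["bf_uni_late_gt_early"] = _safe_bf(
            bayes.bf_uniform, lik, 0.0, uni_range, cfg.likelihood,
            log=log, what=f"{vec.name} BF_uni(late>early)")
    out["bf_jzs"] = _safe_bf(bayes.bf_jzs, tres.t, tres.n,
                             log=log, what=f"{vec.name} BF_jzs")
    return out


def _orthogonal_mean(delta: pd.DataFrame, measure: str, participants) -> float:
    """Group mean of the per-participant active-vs-sham delta across all times."""
    sub = delta.loc[(delta["measure"] == measure)
                    & delta["participant_id"].isin(participants)]
    per_p = sub.groupby("participant_id")["delta"].mean()
    return float(per_p.mean()) if len(per_p) else math.nan


def run_report(trials: pd.DataFrame, config: AnalysisConfig | None = None) -> ReportBundle:
    """Run the full pre-registered analysis on a trial table.

    Order of operations: blink filter; participant-level exclusions (same
    button, all negative, illogical rate); measure computation; the PcU
    above-chance rule (PcU analyses only); per-vector Chauvenet outlier
    removal; t-tests, effect sizes and Bayes factors per contrast; gated
    fine-grained time contrasts.
    """
    cfg = config or AnalysisConfig()
    log: list[str] = [f"config: {cfg}"]
    n_raw = len(trials)
    trials = blink_filter(trials)
    log.append(f"blink filter: removed {n_raw - len(trials)} of {n_raw} trials")

    screen = participant_screen(trials)
    excluded_ids = set(screen.loc[screen["excluded"], "participant_id"])
    retained = trials.loc[~trials["participant_id"].isin(excluded_ids)]
    log.append(f"participant screen: excluded {sorted(excluded_ids)}")

    measures = list(dict.fromkeys(cfg.measures))
    mtable = measure_table(retained, measures, strict_table1=cfg.strict_table1)
    delta = sham_normalize(mtable)

    # PcU above-chance rule on pooled sham trials, PcU scope only.
    chance_rows = []
    pcu_excluded: set = set()
    if "PcU" in measures:
        for pid, sub in retained.loc[retained["tms_mode"] == "sham"].groupby(
            "participant_id", sort=True
        ):
            value, n = pcu(sub)
            z, excl = chance_test_pcu(value, n, alpha=cfg.alpha)
            chance_rows.append(dict(
                participant_id=pid, rule="chance_pcu", scope="measure_pcu_only",
                detail=f"sham PcU={value:.3f}, n={n}, z={z:.2f}", excluded=excl,
            ))
            if excl:
                pcu_excluded.add(pid)
        log.append(f"chance rule: {len(pcu_excluded)} participant(s) excluded from PcU")

    rows = []
    vectors: dict[str, ContrastVector] = {}
    gated: list[str] = []
    pcu_peak = math.nan
    if "PcU" in measures:
        keep = mtable.loc[(mtable["measure"] == "PcU")
                          & ~mtable["participant_id"].isin(pcu_excluded)]
        cell_means = keep.groupby(["tms_mode", "tms_time"], observed=True)["value"].mean()
        pcu_peak = float(cell_means.max()) if len(cell_means) else math.nan

    for m in measures:
        vec = early_late_contrast(delta, m, strict=cfg.strict_contrast_members)
        if m == "PcU" and pcu_excluded:
            vec = ContrastVector(vec.name, vec.values.drop(
                index=[p for p in pcu_excluded if p in vec.values.index]),
                provenance=vec.provenance)
        vec = vec.drop_outliers(mode=cfg.chauvenet_mode)
        vectors[vec.name] = vec
        tres = one_sample_t(vec.values)
        orth = _orthogonal_mean(delta, m, vec.values.index)
        uni_range = None
        if m == "PrC":
            uni_range = cfg.prc_uniform_range
        elif m == "PcU":
            uni_range = pcu_peak - 0.5 if math.isfinite(pcu_peak) else None
        bf_cols = _bayes_columns(vec, tres, orth, uni_range, cfg, log)
        rows.append(dict(
            measure=m, t=tres.t, p=tres.p, df=tres.df, mean=tres.mean,
            ci_low=tres.ci95[0], ci_high=tres.ci95[1], d=tres.cohens_d,
            **bf_cols, n_outliers=len(vec.excluded_outliers), n=tres.n,
        ))
        bf_main = np.nanmax([bf_cols["bf_main_early_gt_late"],
                             bf_cols["bf_main_late_gt_early"]]) if not all(
            math.isnan(v) for v in (bf_cols["bf_main_early_gt_late"],
                                    bf_cols["bf_main_late_gt_early"])) else math.nan
        if (tres.p < cfg.alpha) or (math.isfinite(bf_main) and
                                    (bf_main >= 3 or bf_main <= 1 / 3)):
            gated.append(m)

    report = pd.DataFrame(rows)

    # Baseline (BIP-in-isolation and across-times) analyses.
    baseline_rows = []
    bip = delta.loc[delta["tms_time"] == "BIP_only"]
    for m in measures:
        v = bip.loc[bip["measure"] == m].set_index("participant_id")["delta"].dropna()
        if m == "PcU":
            v = v.drop(index=[p for p in pcu_excluded if p in v.index])
        tr = one_sample_t(v)
        baseline_rows.append(dict(analysis=f"{m} active_vs_sham_BIP", t=tr.t, p=tr.p,
                                  df=tr.df, mean=tr.mean, ci_low=tr.ci95[0],
                                  ci_high=tr.ci95[1], d=tr.cohens_d, n=tr.n))
    if "PcU" in measures:
        active_bip = mtable.loc[(mtable["measure"] == "PcU")
                                & (mtable["tms_mode"] == "active")
                                & (mtable["tms_time"] == "BIP_only")]
        for tag, drop in (("with_exclusions", True), ("without_exclusions", False)):
            v = active_bip.set_index("participant_id")["value"].dropna()
            if drop:
                v = v.drop(index=[p for p in pcu_excluded if p in v.index])
            tr = one_sample_t(v, null=0.5)
            baseline_rows.append(dict(
                analysis=f"PcU active_BIP_vs_chance_{tag}", t=tr.t, p=tr.p, df=tr.df,
                mean=tr.mean, ci_low=tr.ci95[0], ci_high=tr.ci95[1],
                d=tr.cohens_d, n=tr.n))
    baseline = pd.DataFrame(baseline_rows)

    # Gated fine-grained time contrasts.
    fine_rows = []
    ta, tb = cfg.fine_pair
    for m in measures:
        if m not in gated:
            log.append(f"fine contrast {m} {ta}_vs_{tb}: gate closed, skipped")
            continue
        vec = fine_contrast(delta, m, ta, tb)
        if m == "PcU" and pcu_excluded:
            vec = ContrastVector(vec.name, vec.values.drop(
                index=[p for p in pcu_excluded if p in vec.values.index]),
                provenance=vec.provenance)
        vec = vec.drop_outliers(mode=cfg.chauvenet_mode)
        vectors[vec.name] = vec
        tres = one_sample_t(vec.values)
        orth = _orthogonal_mean(delta, m, vec.values.index)
        uni_range = cfg.prc_uniform_range if m == "PrC" else (
            pcu_peak - 0.5 if m == "PcU" and math.isfinite(pcu_peak) else None)
        bf_cols = _bayes_columns(vec, tres, orth, uni_range, cfg, log)
        fine_rows.append(dict(
            measure=m, contrast=f"{ta}_vs_{tb}", t=tres.t, p=tres.p, df=tres.df,
            mean=tres.mean, ci_low=tres.ci95[0], ci_high=tres.ci95[1],
            d=tres.cohens_d, **bf_cols, n_outliers=len(vec.excluded_outliers),
            n=tres.n))
    fine = pd.DataFrame(fine_rows)

    exclusions = pd.concat(
        [screen, pd.DataFrame.from_records(
            chance_rows, columns=screen.columns)], ignore_index=True)
    for name, vec in vectors.items():
        for pid in vec.excluded_outliers:
            exclusions.loc[len(exclusions)] = dict(
                participant_id=pid, rule="chauvenet", scope="vector_point",
                detail=name, excluded=True)
    exclusions["excluded"] = exclusions["excluded"].astype(bool)

    return ReportBundle(report, baseline, fine, exclusions, vectors, log)
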