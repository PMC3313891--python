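"""Reproducibility and accuracy evaluation of the reconstruction.

Quantifies how well statistics computed from reconstructed IPD agree with
reference values, using the vocabulary of gauge repeatability &
reproducibility studies:

* **mean error (ME)** -- systematic bias of reconstructed minus reference,
  with a normal-theory CI;
* **mean absolute error (MAE)** -- the typical magnitude of a single
  reconstruction's error, with a Monte-Carlo CI obtained by folding normal
  draws that share the observed mean and variance;
* **variance components** -- a balanced two-way random-effects ANOVA
  (exemplar x observer with replicates) decomposing error variation into
  exemplar, observer, interaction and within-cell parts; the interaction is
  pooled into error when its F test is non-significant.  The
  *reproducibility* SD combines the within- and between-observer parts;
  the *exemplar* SD captures how much accuracy depends on which curve is
  reconstructed.  CIs come from scaled chi-square resampling of the mean
  squares.

Differences are taken on the natural scale for survival probabilities and
on the log scale for medians, hazard ratios and their standard errors,
because multiplicative error is the natural description for the latter.

:func:`recovery_study` runs the whole pipeline -- simulate, digitize,
build risk table, reconstruct at each information level, re-estimate --
and emits one report per (information level, statistic).  The human-observer
factor of a real reproducibility study is emulated by replicate
digitization-noise seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols

from .errors import ConsistencyError
from .reconstruct import derive_ipd, reconstruct
from .survstats import cox_hr, km_curve, median_survival, surv_prob_at
from .synthetic import (
    DigitizationNoise,
    TrialSpec,
    exact_digitize,
    make_risk_table,
    perturb_curve,
    pick_risk_times,
    simulate_trial,
)
from .types import InfoLevel, ReconstructionInput

__all__ = [
    "mean_error",
    "mean_abs_error",
    "variance_components",
    "VarianceComponents",
    "AccuracyReport",
    "recovery_study",
    "DEFAULT_N_MC",
]

#: Monte-Carlo sample size for all simulated confidence intervals.
DEFAULT_N_MC = 150_000

#: Statistic kinds and the scale their errors are measured on.
STAT_SCALES = {
    "survprob": "natural",
    "median": "log",
    "hr": "log",
    "se_log_hr": "log",
}


class Interval(tuple):
    """(estimate, lo95, hi95) triple."""

    def __new__(cls, estimate: float, lo95: float, hi95: float):
        return super().__new__(cls, (estimate, lo95, hi95))

    @property
    def estimate(self) -> float:
        return self[0]

    @property
    def lo95(self) -> float:
        return self[1]

    @property
    def hi95(self) -> float:
        return self[2]


def mean_error(diffs: Sequence[float]) -> Interval:
    """Mean error with a normal-theory 95% CI.

    The CI uses the sample variance of the differences; a constant vector
    gives a zero-width interval.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("mean_error needs at least 2 differences")
    me = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(d.size))
    z = stats.norm.ppf(0.975)
    return Interval(me, me - z * se, me + z * se)


def mean_abs_error(
    diffs: Sequence[float], n_mc: int = DEFAULT_N_MC, seed: int = 0
) -> Interval:
    """Mean absolute error with a Monte-Carlo 95% interval.

    The interval describes the distribution of a *single* absolute error:
    ``n_mc`` draws are taken from the normal distribution with the observed
    mean and variance, folded, and the 2.5/97.5 percentiles reported.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("mean_abs_error needs at least 2 differences")
    mae = float(np.abs(d).mean())
    rng = np.random.default_rng(seed)
    draws = np.abs(rng.normal(d.mean(), d.std(ddof=1), size=n_mc))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return Interval(mae, float(lo), float(hi))


@dataclass(frozen=True)
class VarianceComponents:
    """Variance decomposition of reconstruction errors."""

    sigma_r: Interval  # reproducibility SD (within + between observer)
    sigma_e: Interval  # exemplar SD
    sigma_observer: float
    sigma_within: float
    sigma_interaction: float
    interaction_pooled: bool
    interaction_p: float
    anova: pd.DataFrame


def _check_balanced(df: pd.DataFrame) -> tuple[int, int, int]:
    counts = df.groupby(["exemplar", "observer"]).size()
    a = df["exemplar"].nunique()
    b = df["observer"].nunique()
    if len(counts) != a * b or counts.nunique() != 1:
        full = counts.reindex(
            pd.MultiIndex.from_product(
                [df["exemplar"].unique(), df["observer"].unique()],
                names=["exemplar", "observer"],
            ),
            fill_value=0,
        )
        bad = full[full != full.max()].index[0]
        raise ConsistencyError(
            f"unbalanced layout: cell (exemplar={bad[0]!r}, observer={bad[1]!r}) "
            f"has {int(full.loc[bad])} replicates, others have {int(full.max())}"
        )
    return a, b, int(counts.iloc[0])


def variance_components(
    data: pd.DataFrame,
    pool_threshold: float = 0.10,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> VarianceComponents:
    """Two-way random-effects variance decomposition of a balanced error table.

    ``data`` needs columns ``exemplar``, ``observer``, ``diff`` and a
    balanced layout (equal replicates in every exemplar x observer cell,
    at least 2).  Components are solved from the expected mean squares of
    the two-way ANOVA; the interaction is pooled into within-cell error
    when its F-test p-value exceeds ``pool_threshold``.  Negative moment
    estimates are clamped to 0.  CIs for the reproducibility and exemplar
    SDs are obtained by resampling each mean square as SS / chi-square(df)
    and re-solving, ``n_mc`` times.
    """
    df = data.copy()
    required = {"exemplar", "observer", "diff"}
    if not required <= set(df.columns):
        raise ValueError(f"data needs columns {sorted(required)}")
    a, b, r = _check_balanced(df)
    if a < 2 or b < 2 or r < 2:
        raise ConsistencyError(
            "variance decomposition needs >= 2 exemplars, >= 2 observers and "
            ">= 2 replicates per cell"
        )
    model = ols("diff ~ C(exemplar) * C(observer)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_e = float(table.loc["C(exemplar)", "sum_sq"])
    ss_o = float(table.loc["C(observer)", "sum_sq"])
    ss_i = float(table.loc["C(exemplar):C(observer)", "sum_sq"])
    ss_w = float(table.loc["Residual", "sum_sq"])
    df_e, df_o = a - 1, b - 1
    df_i, df_w = (a - 1) * (b - 1), a * b * (r - 1)

    f_int = (ss_i / df_i) / (ss_w / df_w)
    p_int = float(stats.f.sf(f_int, df_i, df_w))
    pooled = p_int > pool_threshold

    def solve(ms_e, ms_o, ms_i, ms_w, pooled_ms):
        # vectorized over Monte-Carlo draws as well as plain scalars
        if pooled:
            ms_err = pooled_ms
            v_int = np.zeros_like(np.asarray(ms_err, dtype=float))
        else:
            ms_err = ms_w
            v_int = np.maximum((ms_i - ms_w) / r, 0.0)
        base = ms_err if pooled else ms_i
        v_o = np.maximum((ms_o - base) / (a * r), 0.0)
        v_e = np.maximum((ms_e - base) / (b * r), 0.0)
        v_w = np.asarray(ms_err, dtype=float)
        return v_e, v_o, v_int, v_w

    pooled_ms = (ss_i + ss_w) / (df_i + df_w)
    v_e, v_o, v_int, v_w = solve(ss_e / df_e, ss_o / df_o, ss_i / df_i,
                                 ss_w / df_w, pooled_ms)
    sigma_r_hat = float(np.sqrt(v_w + v_int + v_o))
    sigma_e_hat = float(np.sqrt(v_e))

    rng = np.random.default_rng(seed)
    ms_e_s = ss_e / rng.chisquare(df_e, n_mc)
    ms_o_s = ss_o / rng.chisquare(df_o, n_mc)
    ms_i_s = ss_i / rng.chisquare(df_i, n_mc)
    ms_w_s = ss_w / rng.chisquare(df_w, n_mc)
    pooled_ms_s = (ss_i + ss_w) / rng.chisquare(df_i + df_w, n_mc)
    ve_s, vo_s, vi_s, vw_s = solve(ms_e_s, ms_o_s, ms_i_s, ms_w_s, pooled_ms_s)
    sr_s = np.sqrt(vw_s + vi_s + vo_s)
    se_s = np.sqrt(ve_s)
    sr_lo, sr_hi = np.percentile(sr_s, [2.5, 97.5])
    se_lo, se_hi = np.percentile(se_s, [2.5, 97.5])

    return VarianceComponents(
        sigma_r=Interval(sigma_r_hat, float(sr_lo), float(sr_hi)),
        sigma_e=Interval(sigma_e_hat, float(se_lo), float(se_hi)),
        sigma_observer=float(np.sqrt(v_o)),
        sigma_within=float(np.sqrt(v_w)),
        sigma_interaction=float(np.sqrt(v_int)),
        interaction_pooled=pooled,
        interaction_p=p_int,
        anova=table,
    )


@dataclass(frozen=True)
class AccuracyReport:
    """ME/MAE (always) and variance components (when the layout allows)."""

    statistic: str
    info_level: str
    scale: str
    n: int
    me: Interval
    mae: Interval
    sigma_r: Optional[Interval] = None
    sigma_e: Optional[Interval] = None


def _arm_statistics(ipd: pd.DataFrame, surv_times: Sequence[float]) -> dict:
    curve = km_curve(ipd)
    out = {}
    for t in surv_times:
        out[("survprob", t)] = surv_prob_at(curve, t).estimate
    med = median_survival(curve).estimate
    if med is not None and med > 0:
        out[("median", None)] = med
    return out


def _trial_statistics(
    arm_frames: dict[str, pd.DataFrame], surv_times: Sequence[float]
) -> dict:
    stats_out = {}
    labels = list(arm_frames)
    for arm, frame in arm_frames.items():
        for key, val in _arm_statistics(frame, surv_times).items():
            stats_out[(key[0], arm, key[1])] = val
    if len(labels) == 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hr = cox_hr(arm_frames[labels[0]], arm_frames[labels[1]])
        if np.isfinite(hr.hr) and hr.hr > 0 and np.isfinite(hr.se_log_hr):
            stats_out[("hr", None, None)] = hr.hr
            stats_out[("se_log_hr", None, None)] = hr.se_log_hr
    return stats_out


def _reconstruct_arms(
    trial, level: InfoLevel, noise: DigitizationNoise, noise_seed: int,
    n_risk_intervals: int,
) -> dict[str, pd.DataFrame]:
    out = {}
    for j, arm in enumerate(trial.arm_labels):
        truth = trial.arm_ipd(arm)
        curve = exact_digitize(truth, arm)
        risk_times = pick_risk_times(curve, n_risk_intervals)
        if not noise.is_null:
            curve = perturb_curve(curve, noise, noise_seed + j,
                                  protect_times=risk_times)
        table, totevents = make_risk_table(truth, risk_times, curve)
        inp = ReconstructionInput(curve, table, totevents).at_level(level)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = reconstruct(inp)
            records = derive_ipd(result.km, result.plan, curve, arm)
        out[arm] = pd.DataFrame(records, columns=["time", "event", "arm"])
    return out


def recovery_study(
    specs: Sequence[TrialSpec],
    info_levels: Iterable[InfoLevel | str] = tuple(InfoLevel),
    surv_time_fracs: Sequence[float] = (0.25, 0.5),
    n_observers: int = 1,
    n_replicates: int = 1,
    noise: DigitizationNoise = DigitizationNoise(),
    n_risk_intervals: int = 5,
    n_mc: int = 10_000,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], AccuracyReport], pd.DataFrame]:
    """Full-pipeline accuracy study over a grid of simulated trials.

    For each trial spec (an *exemplar*), reference statistics are computed
    from the true IPD; each emulated *observer* x *replicate* digitizes the
    curves (with ``noise``, default exact), reconstructs at every requested
    information level and recomputes the statistics.  Survival
    probabilities are read at ``surv_time_fracs`` of each trial's maximum
    follow-up.  Returns the per-(level, statistic) reports and the raw
    comparison table (columns exemplar, observer, replicate, statistic,
    info_level, reconstructed, reference, scale, diff).
    """
    levels = [InfoLevel(l) for l in info_levels]
    rows = []
    for ex_id, spec in enumerate(specs):
        trial = simulate_trial(spec)
        max_fu = float(trial.ipd["time"].max())
        surv_times = [f * max_fu for f in surv_time_fracs]
        truth_frames = {arm: trial.arm_ipd(arm) for arm in trial.arm_labels}
        ref = _trial_statistics(truth_frames, surv_times)
        for obs in range(n_observers):
            for rep in range(n_replicates):
                noise_seed = (spec.seed * 1009 + obs * 131 + rep) % (2**31 - 1)
                for level in levels:
                    recon = _reconstruct_arms(
                        trial, level, noise, noise_seed, n_risk_intervals
                    )
                    got = _trial_statistics(recon, surv_times)
                    for key, ref_val in ref.items():
                        if key not in got:
                            continue
                        kind = key[0]
                        scale = STAT_SCALES[kind]
                        rec_val = got[key]
                        if scale == "log":
                            if rec_val <= 0 or ref_val <= 0:
                                continue
                            diff = np.log(rec_val) - np.log(ref_val)
                        else:
                            diff = rec_val - ref_val
                        rows.append(
                            {
                                "exemplar": ex_id,
                                "observer": obs,
                                "replicate": rep,
                                "statistic": kind,
                                "info_level": level.value,
                                "reconstructed": rec_val,
                                "reference": ref_val,
                                "scale": scale,
                                "diff": diff,
                            }
                        )
    comparison = pd.DataFrame(rows)
    reports: dict[tuple[str, str], AccuracyReport] = {}
    for (level, kind), sub in comparison.groupby(["info_level", "statistic"]):
        diffs = sub["diff"].to_numpy()
        if diffs.size < 2:
            continue
        me = mean_error(diffs)
        mae = mean_abs_error(diffs, n_mc=n_mc, seed=seed)
        sigma_r = sigma_e = None
        if (
            sub["exemplar"].nunique() >= 2
            and sub["observer"].nunique() >= 2
            and n_replicates >= 2
        ):
            try:
                vc = variance_components(sub, n_mc=n_mc, seed=seed)
                sigma_r, sigma_e = vc.sigma_r, vc.sigma_e
            except ConsistencyError:
                pass
        reports[(level, kind)] = AccuracyReport(
            statistic=kind,
            info_level=level,
            scale=STAT_SCALES[kind],
            n=int(diffs.size),
            me=me,
            mae=mae,
            sigma_r=sigma_r,
            sigma_e=sigma_e,
        )
    return reports, comparison


def report_frame(reports: dict[tuple[str, str], AccuracyReport]) -> pd.DataFrame:
    """Flatten recovery-study reports into a printable matrix."""
    rows = []
    for (level, kind), rep in sorted(reports.items()):
        rows.append(
            {
                "statistic": kind,
                "info_level": level,
                "scale": rep.scale,
                "n": rep.n,
                "ME": rep.me.estimate,
                "ME_lo": rep.me.lo95,
                "ME_hi": rep.me.hi95,
                "MAE": rep.mae.estimate,
                "MAE_lo": rep.mae.lo95,
                "MAE_hi": rep.mae.hi95,
                "sigma_r": rep.sigma_r.estimate if rep.sigma_r else np.nan,
                "sigma_e": rep.sigma_e.estimate if rep.sigma_e else np.nan,
            }
        )
    return pd.DataFrame(rows)
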