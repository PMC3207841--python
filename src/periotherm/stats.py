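"""Window statistics, entropy, distributional tests and the mixed ANOVA.

Each 2-second window of the mean-temperature series is summarised by six
measures: range, mean, variance (biased, 1/n), skewness (g1 = m3/m2^1.5),
Pearson kurtosis (m4/m2^2, normal = 3) and Shannon entropy (histogram with
1000 equally spaced bins between the window's min and max, counts
normalised by the number of samples, base-2 logarithm).

The pre/post-stimulus comparison is a three-way mixed ANOVA — window
(pre/post) and side (left/right periorbital) fixed, participant random —
expressed statsmodels-style: :class:`PeriorbitalAnova` is built from a
long-format table, and its :meth:`~PeriorbitalAnova.fit` returns a
:class:`PeriorbitalAnovaResults` carrying the expected-mean-squares F
table.  Because post-exclusion trial counts differ between cells, each
participant's cell means are taken first (the unweighted-means solution),
which keeps the EMS denominators valid: fixed main effects test against
their interaction with participant.

Normality within windows is checked by a chi-squared goodness-of-fit test
on equiprobable bins under the fitted normal, and whole-trial stationarity
by the Wald–Wolfowitz runs test about the series median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

MEASURES = ("range", "mean", "variance", "skewness", "kurtosis", "entropy")

#: long-format per-window table; one row per (participant, session, trial,
#: side, window), carrying the six measures plus the trial flags.
STUDY_TABLE_COLUMNS = (
    "participant",
    "session",
    "trial",
    "side",
    "window",
    *MEASURES,
    "stimulus_flag",
    "formal_startle_flag",
    "usable_flag",
)


@dataclass
class WindowStats:
    """Summary measures of one 2-s window (temperatures in Kelvin)."""

    range: float
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    entropy: float = math.nan
    degenerate: bool = False  # constant window: skewness/kurtosis undefined

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in MEASURES}


def summary_stats(window) -> WindowStats:
    """Range, mean and biased central-moment statistics of a window.

    Kurtosis is on the Pearson scale (normal = 3).  A constant window has
    range and variance 0 and undefined (NaN) skewness/kurtosis, flagged
    ``degenerate``.
    """
    x = np.asarray(window, dtype=np.float64).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples (kurtosis undefined below that)")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return WindowStats(
            range=0.0, mean=mean, variance=0.0,
            skewness=math.nan, kurtosis=math.nan, degenerate=True,
        )
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return WindowStats(
        range=float(x.max() - x.min()),
        mean=mean,
        variance=m2,
        skewness=m3 / m2**1.5,
        kurtosis=m4 / m2**2,
    )


def shannon_entropy(window, n_bins: int = 1000) -> float:
    """Shannon entropy (bits) of the window's histogram.

    Bins are equally spaced between the window's min and max, with the
    final bin closed so the maximum is counted; probabilities are counts
    over the sample size and 0*log(0) is taken as 0.  A constant window has
    entropy 0.
    """
    x = np.asarray(window, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p: float
    reject: bool
    n_bins: int
    degenerate: bool = False


def chi2_normality(window, alpha: float = 0.05, min_expected: float = 5.0) -> Chi2Result:
    """Chi-squared goodness-of-fit test of normality within a window.

    The sample is binned into k equiprobable bins under Normal(mean, sd)
    with ML (1/n) scale, k chosen so every expected count is at least
    ``min_expected``; the statistic sum((O-E)^2/E) is referred to
    chi-squared with k - 3 degrees of freedom (two estimated parameters).
    A zero-variance window is rejected outright and flagged.
    """
    x = np.asarray(window, dtype=np.float64).ravel()
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples")
    k = max(4, min(int(n // min_expected), 50))
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        return Chi2Result(
            statistic=math.inf, df=k - 3, p=0.0, reject=True, n_bins=k, degenerate=True
        )
    edges = sps.norm.ppf(np.arange(1, k) / k, loc=mean, scale=sd)
    counts, _ = np.histogram(x, bins=np.concatenate(([-np.inf], edges, [np.inf])))
    expected = n / k
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = k - 3
    p = float(sps.chi2.sf(statistic, df))
    return Chi2Result(statistic=statistic, df=df, p=p, reject=bool(p < alpha), n_bins=k)


@dataclass
class RunsTestResult:
    n_runs: int
    n_above: int
    n_below: int
    z: float
    p: float
    nonstationary: bool
    indeterminate: bool = False


def runs_test(series, alpha: float = 0.05) -> RunsTestResult:
    """Wald–Wolfowitz runs test about the median of a full-trial series.

    Values equal to the median are dropped; the two-sided p comes from the
    normal approximation of the runs distribution.  Too few values on
    either side of the median yields an indeterminate (flagged) result.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size < 20:
        raise ValueError("need at least 20 samples")
    med = float(np.median(x))
    s = x[x != med] > med
    n1 = int(s.sum())
    n2 = int(s.size - n1)
    if n1 < 2 or n2 < 2:
        return RunsTestResult(
            n_runs=1 if s.size else 0, n_above=n1, n_below=n2,
            z=math.nan, p=math.nan, nonstationary=False, indeterminate=True,
        )
    runs = 1 + int(np.count_nonzero(s[1:] != s[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    z = (runs - mu) / math.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return RunsTestResult(
        n_runs=runs, n_above=n1, n_below=n2, z=float(z), p=p,
        nonstationary=bool(p < alpha),
    )


# --------------------------------------------------------------------------
# three-way mixed ANOVA (window x side fixed, participant random)
# --------------------------------------------------------------------------


class PeriorbitalAnova:
    """Three-way repeated-measures mixed ANOVA on per-window statistics.

    Parameters
    ----------
    table : DataFrame
        Long format with at least ``participant``, ``window`` (pre/post),
        ``side`` (left/right) and the measure column; one row per window of
        one trial.  Trials within a (participant, window, side) cell are
        replicates and are averaged first (unweighted means).
    measure : str
        Which column to analyse (one of the six window measures).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        measure: str,
        participant_col: str = "participant",
        window_col: str = "window",
        side_col: str = "side",
    ):
        for col in (participant_col, window_col, side_col, measure):
            if col not in table.columns:
                raise ValueError(f"table lacks required column {col!r}")
        self.measure = measure
        self.participant_col = participant_col
        self.window_col = window_col
        self.side_col = side_col
        data = table[[participant_col, window_col, side_col, measure]].dropna()
        self.participants = sorted(data[participant_col].unique())
        if len(self.participants) < 2:
            raise ValueError("need at least 2 participants")
        self.window_levels = sorted(data[window_col].unique())
        self.side_levels = sorted(data[side_col].unique())
        if len(self.window_levels) != 2 or len(self.side_levels) != 2:
            raise ValueError("window and side must each have exactly 2 levels")
        cell = data.groupby([participant_col, window_col, side_col])[measure].mean()
        P = len(self.participants)
        cells = np.full((P, 2, 2), np.nan)
        for ip, p in enumerate(self.participants):
            for iw, w in enumerate(self.window_levels):
                for isd, s in enumerate(self.side_levels):
                    try:
                        cells[ip, iw, isd] = cell.loc[(p, w, s)]
                    except KeyError:
                        raise ValueError(
                            f"missing cell: participant={p!r}, window={w!r}, side={s!r}"
                        ) from None
        self.cell_means = cells

    @classmethod
    def from_study_table(cls, study_table: pd.DataFrame, measure: str) -> "PeriorbitalAnova":
        """Build from a study table, keeping only usable stimulus trials."""
        t = study_table
        mask = np.ones(len(t), dtype=bool)
        if "usable_flag" in t.columns:
            mask &= t["usable_flag"].fillna(False).astype(bool)
        if "stimulus_flag" in t.columns:
            mask &= t["stimulus_flag"].astype(bool)
        return cls(t[mask], measure)

    def fit(self) -> "PeriorbitalAnovaResults":
        """Expected-mean-squares decomposition of the P x 2 x 2 cell-mean table."""
        y = self.cell_means  # (P, window, side)
        P = y.shape[0]
        g = y.mean()
        mw = y.mean(axis=(0, 2))  # (2,)
        ms_ = y.mean(axis=(0, 1))  # (2,)
        mp = y.mean(axis=(1, 2))  # (P,)
        mws = y.mean(axis=0)  # (2, 2)
        mwp = y.mean(axis=2)  # (P, 2)
        msp = y.mean(axis=1)  # (P, 2)

        ss = {
            "window": 2 * P * float(((mw - g) ** 2).sum()),
            "side": 2 * P * float(((ms_ - g) ** 2).sum()),
            "participant": 4 * float(((mp - g) ** 2).sum()),
            "window:side": P * float(
                ((mws - mw[:, None] - ms_[None, :] + g) ** 2).sum()
            ),
            "window:participant": 2 * float(
                ((mwp - mw[None, :] - mp[:, None] + g) ** 2).sum()
            ),
            "side:participant": 2 * float(
                ((msp - ms_[None, :] - mp[:, None] + g) ** 2).sum()
            ),
        }
        fitted = (
            mw[None, :, None] + ms_[None, None, :] + mp[:, None, None]
            + (mws - mw[:, None] - ms_[None, :])[None, :, :]
            + (mwp - mw[None, :] - mp[:, None])[:, :, None]
            + (msp - ms_[None, :] - mp[:, None])[:, None, :]
            + g
        )
        ss["window:side:participant"] = float(((y - fitted) ** 2).sum())

        df = {
            "window": 1,
            "side": 1,
            "participant": P - 1,
            "window:side": 1,
            "window:participant": P - 1,
            "side:participant": P - 1,
            "window:side:participant": P - 1,
        }
        # EMS denominators (restricted mixed model): fixed effects test
        # against their interaction with the random participant factor.
        denom = {
            "window": "window:participant",
            "side": "side:participant",
            "window:side": "window:side:participant",
            "participant": "window:side:participant",
        }
        ms = {e: ss[e] / df[e] for e in ss}
        rows = []
        flags = []
        for effect in (
            "window", "side", "participant", "window:side",
            "window:participant", "side:participant", "window:side:participant",
        ):
            den = denom.get(effect)
            if den is None:
                F = p = math.nan
                df2 = math.nan
            else:
                df2 = df[den]
                if ms[den] == 0.0:
                    # forced/degenerate effect: no denominator variance left
                    F = math.inf if ms[effect] > 0 else math.nan
                    p = 0.0 if ms[effect] > 0 else math.nan
                    flags.append(f"zero denominator mean square for {effect}")
                else:
                    F = ms[effect] / ms[den]
                    p = float(sps.f.sf(F, df[effect], df2))
            rows.append(
                {
                    "effect": effect,
                    "ss": ss[effect],
                    "df": df[effect],
                    "ms": ms[effect],
                    "denom": den if den is not None else "",
                    "df_denom": df2,
                    "F": F,
                    "p": p,
                }
            )
        return PeriorbitalAnovaResults(
            model=self,
            anova_table=pd.DataFrame(rows).set_index("effect"),
            flags=flags,
        )


@dataclass
class PeriorbitalAnovaResults:
    """F table of the fitted mixed ANOVA, statsmodels-results style."""

    model: PeriorbitalAnova
    anova_table: pd.DataFrame
    flags: list = field(default_factory=list)

    @property
    def pvalues(self) -> pd.Series:
        return self.anova_table["p"]

    @property
    def fvalues(self) -> pd.Series:
        return self.anova_table["F"]

    def summary(self) -> str:
        lines = [
            f"Mixed ANOVA for measure {self.model.measure!r} "
            f"({self.model.cell_means.shape[0]} participants; "
            "window, side fixed; participant random)",
            "",
            self.anova_table.to_string(
                float_format=lambda v: f"{v:.6g}", na_rep="-"
            ),
        ]
        if self.flags:
            lines += ["", "flags: " + "; ".join(self.flags)]
        return "\n".join(lines)

    def plot_cell_means(self, ax=None):
        """Interaction plot of the participant-averaged cell means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        means = m.cell_means.mean(axis=0)  # (window, side)
        for isd, s in enumerate(m.side_levels):
            ax.plot(m.window_levels, means[:, isd], marker="o", label=str(s))
        ax.set_xlabel("window")
        ax.set_ylabel(m.measure)
        ax.legend(title="side")
        return ax


def mixed_anova(table: pd.DataFrame, measure: str) -> PeriorbitalAnovaResults:
    """Fit the three-way mixed ANOVA for one measure (convenience wrapper)."""
    return PeriorbitalAnova(table, measure).fit()


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------


@dataclass
class StudyReport:
    """Group means +/- sd by window and side, with significance annotations."""

    tables: Dict[str, pd.DataFrame]  # subset name -> group-mean table
    anovas: Dict[str, Dict[str, PeriorbitalAnovaResults]]
    alpha: float
    empty_subsets: list = field(default_factory=list)

    def to_markdown(self) -> str:
        out = []
        for name, tbl in self.tables.items():
            out.append(f"## {name}")
            if name in self.empty_subsets:
                out.append("*(no trials in this subset)*")
                out.append("")
                continue
            out.append("")
            out.append(tbl.to_markdown(floatfmt=".4g"))
            out.append("")
            out.append(
                f"Pairs marked `*` differ significantly at p < {self.alpha} "
                "(marked on both members of the pair)."
            )
            out.append("")
        return "\n".join(out)


def _group_table(
    rows: pd.DataFrame,
    anovas: Dict[str, PeriorbitalAnovaResults],
    alpha: float,
    measures: Sequence[str],
) -> pd.DataFrame:
    cols = {}
    for by, levels in (("window", ("pre", "post")), ("side", ("left", "right"))):
        for level in levels:
            sub = rows[rows[by] == level]
            col = {}
            for m in measures:
                vals = sub[m].dropna()
                mark = ""
                res = anovas.get(m)
                if res is not None:
                    p = res.pvalues.get(by, math.nan)
                    if np.isfinite(p) and p < alpha:
                        mark = "*"
                mu = vals.mean() if len(vals) else math.nan
                sd = vals.std(ddof=0) if len(vals) > 1 else 0.0
                col[m] = f"{mu:.4g} ± {sd:.2g}{mark}" if len(vals) else "—"
            cols[f"{by}={level}"] = col
    return pd.DataFrame(cols).reindex(list(measures))


def build_report(
    study_table: pd.DataFrame,
    alpha: float = 0.05,
    measures: Sequence[str] = MEASURES,
) -> StudyReport:
    """Group means ± sd and per-measure ANOVAs for (a) all usable stimulus
    trials and (b) the formal-startle subset."""
    t = study_table
    usable = t["usable_flag"].fillna(False).astype(bool) if "usable_flag" in t else True
    stim = t["stimulus_flag"].astype(bool)
    startle = (
        t["formal_startle_flag"].fillna(False).astype(bool)
        if "formal_startle_flag" in t
        else pd.Series(False, index=t.index)
    )
    subsets = {
        "all usable stimulus trials": t[usable & stim],
        "formal-startle subset": t[usable & stim & startle],
    }
    tables: Dict[str, pd.DataFrame] = {}
    all_anovas: Dict[str, Dict[str, PeriorbitalAnovaResults]] = {}
    empty = []
    for name, rows in subsets.items():
        anovas: Dict[str, PeriorbitalAnovaResults] = {}
        if rows.empty:
            empty.append(name)
            tables[name] = pd.DataFrame()
            all_anovas[name] = anovas
            continue
        for m in measures:
            try:
                anovas[m] = mixed_anova(rows, m)
            except ValueError:
                # subset too small for the mixed model: report means only
                pass
        tables[name] = _group_table(rows, anovas, alpha, measures)
        all_anovas[name] = anovas
    return StudyReport(tables=tables, anovas=all_anovas, alpha=alpha, empty_subsets=empty)
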