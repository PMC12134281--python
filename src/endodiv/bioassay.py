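"""Bioassay analytics: DPPH scavenging, dose–response fitting, ANOVA + Duncan.

Covers the numeric side of a standard bioprospecting screen:

* DPPH radical scavenging, (C − T)/C × 100 from 517 nm absorbances;
* MTT viability / cytotoxicity percentages;
* four-parameter logistic (4PL) dose–response fitting with IC50/CC50
  read off the fitted curve, exposed as a scikit-learn style estimator;
* selectivity index CC50(normal) / IC50(tumor) with the ">3 means highly
  selective" rule;
* one-way ANOVA and Duncan's multiple range test with letter displays for
  inhibition-zone screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .diversity import UndefinedInputError, round_value

__all__ = [
    "dpph_scavenging",
    "summarize_dpph",
    "viability_percent",
    "cytotoxicity_percent",
    "FourParamLogistic",
    "DoseResponseCurve",
    "fit_dose_response",
    "SelectivityResult",
    "selectivity_index",
    "AnovaResult",
    "one_way_anova",
    "duncan_mrt",
    "summarize_zones",
]


# -- DPPH -----------------------------------------------------------------


def dpph_scavenging(T: float, C: float) -> float:
    """DPPH scavenging % = (C − T)/C × 100.

    T is the sample absorbance, C the DPPH control absorbance at 517 nm.
    Values are not clipped: a negative result (sample more absorbing than
    the control, a pro-oxidant artifact) is preserved for flagging.
    """
    if C <= 0:
        raise UndefinedInputError("control absorbance must be positive")
    if T < 0:
        raise UndefinedInputError("sample absorbance cannot be negative")
    return (C - T) / C * 100.0


def summarize_dpph(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean ± sd scavenging from replicate absorbance pairs.

    Input columns: sample_id, replicate, absorbance, control_absorbance.
    The percent transform is applied per replicate (not to averaged
    absorbances — the order matters for the sd), then summarized.
    A ``pro_oxidant`` flag marks samples with any negative replicate.
    """
    required = {"sample_id", "replicate", "absorbance", "control_absorbance"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"missing DPPH column(s) {sorted(missing)}")
    df = records.copy()
    df["scavenging_pct"] = [
        dpph_scavenging(t, c) for t, c in zip(df["absorbance"], df["control_absorbance"])
    ]
    out = (
        df.groupby("sample_id")["scavenging_pct"]
        .agg(mean="mean", sd="std", n="count", pro_oxidant=lambda s: bool((s < 0).any()))
        .reset_index()
    )
    return out.sort_values("mean", ascending=False, ignore_index=True)


# -- MTT viability --------------------------------------------------------


def viability_percent(abs_treated: float, abs_untreated: float) -> float:
    """MTT viability % = treated / untreated absorbance × 100."""
    if abs_untreated <= 0:
        raise UndefinedInputError("untreated absorbance must be positive")
    if abs_treated < 0:
        raise UndefinedInputError("treated absorbance cannot be negative")
    return abs_treated / abs_untreated * 100.0


def cytotoxicity_percent(abs_treated: float, abs_untreated: float) -> float:
    """Cytotoxicity % = 100 − viability %."""
    return 100.0 - viability_percent(abs_treated, abs_untreated)


# -- 4PL dose-response ----------------------------------------------------


def _four_pl(c: np.ndarray, lower: float, upper: float, hill: float, midpoint: float) -> np.ndarray:
    return lower + (upper - lower) / (1.0 + (c / midpoint) ** hill)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic dose–response model.

    Fits viability(c) = lower + (upper − lower) / (1 + (c/midpoint)^hill)
    by least squares, with the midpoint parameterised on the log scale for
    conditioning. ``hill`` > 0 gives a curve decreasing in concentration
    (the usual cytotoxicity shape); the sign is chosen by the data.

    Parameters
    ----------
    tol : float
        Optimizer convergence tolerance.
    max_iter : int
        Maximum number of least-squares function evaluations.

    Attributes
    ----------
    lower_, upper_, hill_, midpoint_ : float
        Fitted asymptotes, slope and inflection concentration.
    residuals_ : ndarray
        Per-point residuals at the solution.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 10_000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if c.shape != v.shape:
            raise ValueError("concentration and response must have equal length")
        if np.unique(c).size < 4:
            raise ValueError("need at least 4 distinct concentrations for a 4PL fit")
        if (c <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if not np.isfinite(v).all():
            raise ValueError("responses must be finite")

        log_c = np.log(c)
        # direction of the response decides the sign of the hill slope
        slope_sign = 1.0 if np.polyfit(log_c, v, 1)[0] <= 0 else -1.0

        def residual(theta):
            lower, upper, hill, log_mid = theta
            return _four_pl(c, lower, upper, hill, math.exp(log_mid)) - v

        v_lo, v_hi = float(v.min()), float(v.max())
        span = max(v_hi - v_lo, 1.0)
        theta0 = np.array([v_lo, v_hi, slope_sign * 1.0, float(np.mean(log_c))])
        bounds = (
            [v_lo - 2 * span, v_lo - 2 * span, -50.0, log_c.min() - 10.0],
            [v_hi + 2 * span, v_hi + 2 * span, 50.0, log_c.max() + 10.0],
        )
        sol = optimize.least_squares(
            residual,
            theta0,
            bounds=bounds,
            xtol=self.tol,
            ftol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_iter,
        )
        lower, upper, hill, log_mid = sol.x
        # canonical orientation: `upper_` is the response at c -> 0
        if hill < 0:
            lower, upper, hill = upper, lower, -hill
        self.lower_ = float(lower)
        self.upper_ = float(upper)
        self.hill_ = float(hill)
        self.midpoint_ = float(math.exp(log_mid))
        self.residuals_ = residual(sol.x)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "midpoint_")
        c = np.asarray(X, dtype=float).ravel()
        return _four_pl(c, self.lower_, self.upper_, self.hill_, self.midpoint_)

    def inhibitory_concentration(self, level: float = 50.0) -> float | None:
        """Concentration at which the fitted curve crosses ``level`` %.

        Returns None when the level is outside the open interval between the
        fitted asymptotes (the curve never reaches it).
        """
        check_is_fitted(self, "midpoint_")
        lo, hi = sorted((self.lower_, self.upper_))
        if not lo < level < hi:
            return None
        ratio = (self.upper_ - level) / (level - self.lower_)
        return float(self.midpoint_ * ratio ** (1.0 / self.hill_))


@dataclass(frozen=True)
class DoseResponseCurve:
    """A fitted 4PL curve with its IC50 (None when 50% is never reached)."""

    concentrations: np.ndarray
    viability_pct: np.ndarray
    lower: float
    upper: float
    hill: float
    midpoint: float
    ic50: float | None
    rmse: float

    @property
    def ic50_defined(self) -> bool:
        return self.ic50 is not None


def fit_dose_response(
    concentrations: Sequence[float], viability_pct: Sequence[float]
) -> DoseResponseCurve:
    """Least-squares 4PL fit; IC50 solved from the fitted parameters.

    The same routine serves tumor-line IC50 and normal-line CC50 — the two
    differ only in which cells produced the viability series.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability_pct, dtype=float)
    order = np.argsort(c, kind="stable")
    c, v = c[order], v[order]
    model = FourParamLogistic().fit(c, v)
    resid = model.predict(c) - v
    return DoseResponseCurve(
        concentrations=c,
        viability_pct=v,
        lower=model.lower_,
        upper=model.upper_,
        hill=model.hill_,
        midpoint=model.midpoint_,
        ic50=model.inhibitory_concentration(50.0),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


# -- selectivity index ----------------------------------------------------


@dataclass(frozen=True)
class SelectivityResult:
    """SI = CC50(normal) / IC50(tumor); >3 counts as highly selective."""

    value: float
    as_printed: float  # truncated to 2 decimals, the usual reporting style
    high_selectivity: bool


def selectivity_index(cc50: float, ic50: float) -> SelectivityResult:
    if ic50 <= 0 or cc50 <= 0:
        raise UndefinedInputError("CC50 and IC50 must be positive")
    value = cc50 / ic50
    return SelectivityResult(
        value=value,
        as_printed=round_value(value, 2, mode="truncate"),
        high_selectivity=value > 3.0,
    )


# -- ANOVA and Duncan's multiple range test -------------------------------


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        items = groups.items()
    else:
        items = ((f"group{i + 1}", g) for i, g in enumerate(groups))
    out = {str(k): np.asarray(list(v), dtype=float) for k, v in items}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for name, vals in out.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    return out


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA decomposition.

    ``groups`` is a mapping name → replicate values, or an iterable of
    replicate vectors. F = MS_between / MS_within; p from the F(df_b, df_w)
    distribution. A zero within-group variance with identical means gives
    F = 0 rather than NaN.
    """
    data = _as_groups(groups)
    all_vals = np.concatenate(list(data.values()))
    grand = all_vals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_between = len(data) - 1
    df_within = all_vals.size - len(data)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        F = 0.0 if ms_between == 0 else math.inf
    else:
        F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_within)) if math.isfinite(F) else 0.0
    if F == 0.0:
        p = 1.0
    return AnovaResult(
        F=float(F),
        df_between=df_between,
        df_within=df_within,
        p=p,
        ms_within=float(ms_within),
        group_means={k: float(v.mean()) for k, v in data.items()},
        group_sizes={k: int(v.size) for k, v in data.items()},
    )


def duncan_critical_ranges(
    n_means: int, df_within: int, ms_within: float, n_harmonic: float, alpha: float
) -> dict[int, float]:
    """Least significant ranges R_p for spans p = 2..n_means.

    Uses Duncan's protection level alpha_p = 1 − (1 − alpha)^(p−1) and the
    studentized-range quantile computed numerically:
    R_p = q(1 − alpha_p; p, df) · sqrt(MS_within / n_h).
    """
    out = {}
    se = math.sqrt(ms_within / n_harmonic)
    for p in range(2, n_means + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, p, df_within)
        out[p] = float(q * se)
    return out


def _homogeneous_spans(means: np.ndarray, ranges: Mapping[int, float]) -> list[tuple[int, int]]:
    """Maximal spans of ranked means declared homogeneous by Duncan's rule.

    Means are sorted descending. The widest span is tested first; a span
    whose observed range does not exceed its R_p is declared homogeneous
    and never subdivided (the protection rule). Significant spans are
    split into their two one-shorter sub-spans.
    """
    k = means.size
    homogeneous: set[tuple[int, int]] = set()
    to_test: set[tuple[int, int]] = {(0, k - 1)} if k >= 2 else set()
    for width in range(k, 1, -1):
        next_level: set[tuple[int, int]] = set()
        for i, j in sorted(to_test):
            if j - i + 1 != width or any(a <= i and j <= b for a, b in homogeneous):
                continue
            if means[i] - means[j] <= ranges[width] + 1e-12:
                homogeneous.add((i, j))
            else:
                if j - i >= 2:
                    next_level.update({(i + 1, j), (i, j - 1)})
        to_test = next_level
    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a, b) != (i, j) and a <= i and j <= b for a, b in homogeneous)
    ]
    return sorted(maximal)


def duncan_mrt(groups, alpha: float = 0.05) -> dict[str, str]:
    """Duncan's multiple range test letter display.

    Groups sharing any letter are not significantly different at the given
    protection level. Unequal replication is handled through the harmonic
    mean of the group sizes. The display is independent of input order
    (groups are ranked by mean, ties broken by name).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    anova = one_way_anova(groups)
    names = sorted(anova.group_means, key=lambda k: (-anova.group_means[k], k))
    means = np.array([anova.group_means[k] for k in names])
    sizes = np.array([anova.group_sizes[k] for k in names], dtype=float)
    n_h = sizes.size / (1.0 / sizes).sum()
    if anova.ms_within == 0:
        # degenerate: zero within-group variance — any mean difference separates
        letters_idx: list[tuple[int, int]] = []
        start = 0
        for i in range(1, len(names) + 1):
            if i == len(names) or means[i] != means[start]:
                letters_idx.append((start, i - 1))
                start = i
        spans = letters_idx
    else:
        ranges = duncan_critical_ranges(len(names), anova.df_within, anova.ms_within, n_h, alpha)
        spans = _homogeneous_spans(means, ranges)
    display = {name: "" for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    covered = [False] * len(names)
    letter_i = 0
    for i, j in spans:
        for idx in range(i, j + 1):
            display[names[idx]] += alphabet[letter_i % 26]
            covered[idx] = True
        letter_i += 1
    for idx, name in enumerate(names):
        if not covered[idx]:
            display[name] = alphabet[letter_i % 26]
            letter_i += 1
    return display


# -- inhibition-zone summaries -------------------------------------------


def summarize_zones(
    records: pd.DataFrame, alpha: float = 0.05, control_id: str = "control"
) -> pd.DataFrame:
    """Mean ± sd inhibition zones per (extract, pathogen) with Duncan letters.

    Input columns: extract_id, pathogen_id, replicate, zone_mm. Per
    pathogen, extracts are ranked by mean zone (rank 1 = largest; solvent
    control rows are kept in the output but excluded from ranking and the
    letter display). Ties in the ranking are broken lexicographically and
    flagged in ``tied``.
    """
    required = {"extract_id", "pathogen_id", "replicate", "zone_mm"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"missing zone column(s) {sorted(missing)}")
    if records.empty:
        return pd.DataFrame(
            columns=["pathogen_id", "extract_id", "mean", "sd", "n", "rank", "letters", "tied", "is_control"]
        )
    if (records["zone_mm"] < 0).any():
        raise ValueError("zone_mm must be non-negative")
    rows = []
    for pathogen, sub in records.groupby("pathogen_id"):
        stats_df = (
            sub.groupby("extract_id")["zone_mm"].agg(mean="mean", sd="std", n="count").reset_index()
        )
        stats_df["is_control"] = stats_df["extract_id"].str.lower() == control_id.lower()
        test_groups = {
            e: sub.loc[sub["extract_id"] == e, "zone_mm"].to_numpy()
            for e in stats_df.loc[~stats_df["is_control"], "extract_id"]
        }
        letters: dict[str, str] = {}
        if len(test_groups) >= 2 and all(len(v) >= 2 for v in test_groups.values()):
            letters = duncan_mrt(test_groups, alpha=alpha)
        ranked = stats_df.loc[~stats_df["is_control"]].sort_values(
            ["mean", "extract_id"], ascending=[False, True], kind="stable"
        )
        rank_of = {e: i + 1 for i, e in enumerate(ranked["extract_id"])}
        mean_counts = ranked["mean"].round(12).value_counts()
        for _, r in stats_df.iterrows():
            mean_r = round(r["mean"], 12)
            rows.append(
                {
                    "pathogen_id": pathogen,
                    "extract_id": r["extract_id"],
                    "mean": r["mean"],
                    "sd": r["sd"],
                    "n": r["n"],
                    "rank": rank_of.get(r["extract_id"]),
                    "letters": letters.get(r["extract_id"]),
                    "tied": bool(not r["is_control"] and mean_counts.get(mean_r, 0) > 1),
                    "is_control": bool(r["is_control"]),
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["pathogen_id", "is_control", "rank"], ignore_index=True
    )
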