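"""Assay analysis: normalization, dose-response fitting and per-band statistics.

The analysis mirrors the assay's own logic.  Every experiment (one
plate, five illuminated bands plus a dark subdivision) is first
normalized to its dark A2E-untreated wells, which removes the
between-experiment cell-density scale.  Apoptosis is expressed as the
caspase-3/7 luminescence divided by the viability fluorescence of the
same well, again normalized to the dark untreated ratio.  Experiment
means (not wells) are the unit of replication for inference: at each
A2E concentration a one-way ANOVA across groups gates Dunnett
many-to-one comparisons of every band against the dark control, with
significance tiers * p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bands import DARK

CHANNELS = ("viability", "apoptosis", "necrosis")
#: per-well normalized column produced for each channel
_PCT = {"viability": "viability_pct", "apoptosis": "apoptosis_pct", "necrosis": "necrosis_pct"}

#: fixed stream for the Dunnett multivariate-t integration, so that
#: reported p-values are reproducible (documented tolerance ~1e-3).
_DUNNETT_RNG = 745

SIG_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float, gated: bool = True) -> str:
    if not gated or not np.isfinite(p):
        return "ns"
    for threshold, label in SIG_TIERS:
        if p < threshold:
            return label
    return "ns"


# ---------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------

def _dark_untreated_mask(df: pd.DataFrame) -> pd.Series:
    return (df["band_nm"] == DARK) & (df["a2e_uM"] == 0.0)


def normalize_plate(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize viability and necrosis to the dark untreated control.

    Each experiment's signals are divided by the mean of its own dark
    0 uM wells and expressed in percent (columns ``viability_pct`` and
    ``necrosis_pct``).  Fails loudly if an experiment lacks dark
    untreated wells.
    """
    out = records.copy()
    for col in ("viability_pct", "necrosis_pct"):
        out[col] = np.nan
    for exp, grp in records.groupby("experiment"):
        ctrl = grp[_dark_untreated_mask(grp)]
        if ctrl.empty:
            raise ValueError(f"experiment {exp!r} has no dark 0 uM control wells")
        for raw, col in (("viability", "viability_pct"), ("necrosis", "necrosis_pct")):
            ref = ctrl[raw].mean()
            if ref <= 0:
                raise ValueError(f"experiment {exp!r}: non-positive dark control {raw}")
            out.loc[grp.index, col] = 100.0 * grp[raw] / ref
    return out


def apoptosis_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Per-well caspase/viability ratio normalized to the dark untreated mean.

    Wells with non-positive viability are excluded (ratio set to NaN)
    with a warning.
    """
    out = records.copy()
    bad = out["viability"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} wells with non-positive viability")
    ratio = np.where(bad, np.nan, out["caspase"] / out["viability"].where(~bad))
    out["_ratio"] = ratio
    out["apoptosis_pct"] = np.nan
    for exp, grp in out.groupby("experiment"):
        ctrl = grp[_dark_untreated_mask(grp)]
        if ctrl.empty:
            raise ValueError(f"experiment {exp!r} has no dark 0 uM control wells")
        ref = ctrl["_ratio"].mean()
        if not np.isfinite(ref) or ref <= 0:
            raise ValueError(f"experiment {exp!r}: invalid dark control caspase/viability ratio")
        out.loc[grp.index, "apoptosis_pct"] = 100.0 * grp["_ratio"] / ref
    return out.drop(columns="_ratio")


def normalize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Full per-well normalization: viability, necrosis and apoptosis ratio."""
    return apoptosis_ratio(normalize_plate(records))


def experiment_means(normalized: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Average wells within each (experiment, band, A2E level) cell.

    The experiment mean is the unit of replication for all inference.
    """
    col = _PCT[channel]
    means = (
        normalized.groupby(["experiment", "band_nm", "a2e_uM"], sort=False)[col]
        .mean()
        .reset_index()
        .rename(columns={col: "value"})
    )
    return means


# ---------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit of viability against A2E concentration."""

    top: float
    bottom: float
    ic50: float
    hill: float
    r_squared: float
    n_points: int
    flagged: bool = False
    message: str = ""

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return four_parameter_logistic(d, self.top, self.bottom, self.ic50, self.hill)


def four_parameter_logistic(dose, top, bottom, ic50, hill):
    """``bottom + (top - bottom) / (1 + (dose/ic50)**hill)``; value is
    ``top`` at dose 0 and the midpoint at dose = ic50."""
    d = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


HILL_STARTS = (0.5, 1.0, 2.0, 4.0, 8.0)


def fit_dose_response(doses, responses) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start over the Hill slope.

    Requires at least 4 dose levels.  Flat inputs (no transition) and
    fits that fail to converge from every start are returned flagged.
    The fit is invariant to the ordering of the points.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("doses and responses must have equal length")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct dose levels")
    span = y.max() - y.min()
    scale = max(abs(y).max(), 1.0)
    if span < 1e-9 * scale:
        return DoseResponseFit(
            top=float(y.mean()), bottom=float(y.mean()), ic50=np.nan, hill=np.nan,
            r_squared=1.0, n_points=int(x.size), flagged=True,
            message="no transition in the data",
        )
    positive = x[x > 0]
    ic50_guess = float(np.exp(np.mean(np.log(positive)))) if positive.size else 1.0
    best = None
    for hill0 in HILL_STARTS:
        p0 = (float(y.max()), float(y.min()), ic50_guess, hill0)
        try:
            with warnings.catch_warnings():
                # the covariance estimate is unused; ill-conditioned fits
                # (e.g. 4 points, 4 parameters) are judged by SSE below
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    four_parameter_logistic, x, y, p0=p0,
                    bounds=([-np.inf, -np.inf, 1e-12, 0.05], [np.inf, np.inf, np.inf, 50.0]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - four_parameter_logistic(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return DoseResponseFit(
            top=np.nan, bottom=np.nan, ic50=np.nan, hill=np.nan, r_squared=np.nan,
            n_points=int(x.size), flagged=True, message="no start converged",
        )
    sse, (top, bottom, ic50, hill) = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    return DoseResponseFit(
        top=float(top), bottom=float(bottom), ic50=float(ic50), hill=float(hill),
        r_squared=r2, n_points=int(x.size),
    )


# ---------------------------------------------------------------------
# per-band inference
# ---------------------------------------------------------------------

def pairwise_ttest(group_a, group_b) -> float:
    """Two-sample two-sided t-test p-value (equal-variance).

    Degenerate case: two zero-variance groups with equal means give
    p = 1 (no evidence of a difference).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
    return float(p)


def band_statistics(
    normalized: pd.DataFrame,
    channel: str,
    alpha_gate: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANOVA-gated Dunnett comparisons of every band against the dark control.

    At each A2E concentration, experiment-level means form one group per
    band plus the dark control group.  A one-way ANOVA across all groups
    gates the Dunnett many-to-one procedure: adjusted p-values are
    reported for every band, but bands are flagged significant only when
    the ANOVA itself rejects at ``alpha_gate``.  Groups observed in
    fewer than 2 experiments are excluded with a warning.

    Returns one row per (band, A2E level) including the dark control
    rows, with columns ``band_nm, a2e_uM, channel, mean, sem, n, anova_p,
    p, significant, stars``.
    """
    means = experiment_means(normalized, channel)
    rows = []
    for level, sub in means.groupby("a2e_uM", sort=True):
        groups = {}
        for band, g in sub.groupby("band_nm", sort=False):
            vals = g["value"].dropna().to_numpy()
            if vals.size < 2:
                warnings.warn(
                    f"{channel} @ {level} uM: band {band} observed in "
                    f"{vals.size} experiment(s); excluded from inference"
                )
                continue
            groups[band] = vals
        if DARK not in groups:
            warnings.warn(f"{channel} @ {level} uM: no replicated dark control; skipped")
            continue
        control = groups[DARK]
        band_keys = [b for b in groups if b != DARK]
        samples = [groups[b] for b in band_keys]
        anova_p = np.nan
        pvals = np.full(len(band_keys), np.nan)
        if band_keys:
            if np.ptp(np.concatenate(samples + [control])) == 0:
                # all observations identical: direction-free, nothing to detect
                anova_p = 1.0
                pvals = np.ones(len(band_keys))
            else:
                anova_p = float(stats.f_oneway(control, *samples).pvalue)
                with warnings.catch_warnings():
                    # a zero-variance group (e.g. the exactly-100 dark
                    # untreated control) triggers a harmless precision
                    # warning inside the multivariate-t integration
                    warnings.simplefilter("ignore", RuntimeWarning)
                    pvals = stats.dunnett(*samples, control=control, rng=_DUNNETT_RNG).pvalue
        gate_open = np.isfinite(anova_p) and anova_p < alpha_gate
        ordered = sorted(band_keys, key=float) + [DARK]
        for band in ordered:
            vals = groups[band]
            if band == DARK:
                p_adj = np.nan
            else:
                p_adj = float(pvals[band_keys.index(band)])
            sig = bool(gate_open and np.isfinite(p_adj) and p_adj < alpha)
            rows.append(
                {
                    "band_nm": band,
                    "a2e_uM": level,
                    "channel": channel,
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                    "n": int(vals.size),
                    "anova_p": anova_p,
                    "p": p_adj,
                    "significant": sig,
                    "stars": stars(p_adj, gated=gate_open) if band != DARK else "",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# action spectrum
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ActionSpectrum:
    """Per-band normalized outcomes with uncertainty and significance.

    ``table`` holds one row per (band, A2E level, channel); see
    :func:`band_statistics` for the columns.
    """

    table: pd.DataFrame = field(repr=False)

    def channel(self, channel: str) -> pd.DataFrame:
        return self.table[self.table["channel"] == channel]

    def significant_bands(self, channel: str, a2e_uM: float) -> list[float]:
        t = self.table
        sel = t[
            (t["channel"] == channel)
            & (t["a2e_uM"] == a2e_uM)
            & (t["band_nm"] != DARK)
            & t["significant"]
        ]
        return sorted(float(b) for b in sel["band_nm"])

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            cols = ["band_nm", "a2e_uM", "channel", "mean", "sem", "n", "p", "stars"]
            self.table[cols].to_csv(fh, index=False)


def assemble_action_spectrum(
    records: pd.DataFrame,
    alpha_gate: float = 0.05,
    alpha: float = 0.05,
) -> ActionSpectrum:
    """Run the full analysis chain on raw long-format records."""
    normalized = normalize_records(records)
    tables = [
        band_statistics(normalized, ch, alpha_gate=alpha_gate, alpha=alpha)
        for ch in CHANNELS
    ]
    return ActionSpectrum(pd.concat(tables, ignore_index=True))


@dataclass(frozen=True)
class ToxicRange:
    """The maximal contiguous run of significant bands in the blue-green block."""

    bands: tuple[float, ...]
    interval_nm: tuple[float, float] | None
    secondary_runs: tuple[tuple[float, ...], ...] = ()


def toxic_range(
    spectrum: ActionSpectrum,
    channel: str,
    a2e_uM: float,
    step_nm: float = 10.0,
    half_width_nm: float = 5.0,
    blue_green: tuple[float, float] = (390.0, 520.0),
) -> ToxicRange:
    """Longest contiguous run of significant bands within the blue-green block.

    Contiguity means consecutive centres ``step_nm`` apart.  The wavelength
    interval spanned is ``[min_center - half_width, max_center + half_width]``.
    Significant bands outside the block (the 630 nm control) and shorter
    runs are reported as secondary runs.
    """
    sig = spectrum.significant_bands(channel, a2e_uM)
    in_block = [b for b in sig if blue_green[0] <= b <= blue_green[1]]
    out_block = [b for b in sig if not (blue_green[0] <= b <= blue_green[1])]
    runs: list[list[float]] = []
    for b in in_block:
        if runs and abs(b - runs[-1][-1] - step_nm) < 1e-9:
            runs[-1].append(b)
        else:
            runs.append([b])
    runs += [[b] for b in out_block]
    if not runs:
        return ToxicRange(bands=(), interval_nm=None)
    runs.sort(key=lambda r: (-len(r), r[0]))
    primary, rest = runs[0], runs[1:]
    return ToxicRange(
        bands=tuple(primary),
        interval_nm=(primary[0] - half_width_nm, primary[-1] + half_width_nm),
        secondary_runs=tuple(tuple(r) for r in rest),
    )
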