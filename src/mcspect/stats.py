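"""Summary statistics for FWHM tables: means, SDs, paired t-tests, CIs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairedStatsResult", "mean_sd", "paired_t_ci", "build_report"]


@dataclass(frozen=True)
class PairedStatsResult:
    """Paired two-sided Student's t-test of differences d = a - b."""

    mean_diff: float
    sd_diff: float
    percent: float  # mean over pairs of d_i / b_i, in %
    t_stat: float
    df: int
    p_two_sided: float
    ci95: tuple[float, float]
    n: int


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a sample SD")
    return float(v.mean()), float(v.std(ddof=1))


def paired_t_ci(a, b, alpha: float = 0.05) -> PairedStatsResult:
    """Paired t statistics of a - b with a two-sided p and a 95% CI.

    The percent column uses the per-pair convention mean(d_i / b_i) * 100.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    se = sd / np.sqrt(n)
    if sd == 0.0:
        t_stat = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t_stat = mean / se
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    half = t_crit * se if sd > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = float(np.mean(np.where(b != 0, d / b, np.nan)) * 100.0)
    return PairedStatsResult(
        mean, sd, percent, float(t_stat), df, p, (mean - half, mean + half), n
    )


def _require_columns(df: pd.DataFrame):
    needed = {"realization", "variant", "line", "direction", "fwhm_mm"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"resolution table is missing columns {sorted(missing)}")


def build_report(table: pd.DataFrame, variant_pairs=()) -> dict:
    """Aggregate a per-line FWHM table into the standard summaries.

    Returns a dict with
      overall    : per-variant (mean, sd) over every line, direction and
                   realization (camera or seed);
      per_group  : DataFrame of per-realization, per-direction rows with
                   the individual line values and their mean +/- SD;
      xy_paired  : per-variant PairedStatsResult of the Y - X differences
                   paired over (realization, line);
      pairs      : PairedStatsResult for each requested (a, b) variant
                   pair, paired over (realization, line, direction).
    Missing cells raise rather than being silently dropped.
    """
    _require_columns(table)
    if table.empty:
        return {"overall": {}, "per_group": pd.DataFrame(), "xy_paired": {}, "pairs": {}}
    variants = list(dict.fromkeys(table["variant"]))
    lines = sorted(table["line"].unique())
    realizations = sorted(table["realization"].unique())

    overall = {}
    for v in variants:
        vals = table.loc[table["variant"] == v, "fwhm_mm"]
        overall[v] = mean_sd(vals)

    rows = []
    for v in variants:
        for r in realizations:
            for direction in sorted(table["direction"].unique()):
                sel = table[
                    (table["variant"] == v)
                    & (table["realization"] == r)
                    & (table["direction"] == direction)
                ].set_index("line")["fwhm_mm"]
                if set(sel.index) != set(lines):
                    raise ValueError(
                        f"incomplete table for variant={v}, realization={r}, "
                        f"direction={direction}"
                    )
                m, s = mean_sd([sel[l] for l in lines])
                rows.append(
                    {
                        "variant": v,
                        "realization": r,
                        "direction": direction,
                        **{f"line_{l}": sel[l] for l in lines},
                        "mean": m,
                        "sd": s,
                    }
                )
    per_group = pd.DataFrame(rows)

    xy = {}
    pivot = table.pivot_table(
        index=["variant", "realization", "line"], columns="direction", values="fwhm_mm"
    )
    if {"x", "y"} <= set(pivot.columns):
        for v in variants:
            sub = pivot.loc[v]
            xy[v] = paired_t_ci(sub["y"].to_numpy(), sub["x"].to_numpy())

    pairs = {}
    flat = table.set_index(["variant", "realization", "line", "direction"])["fwhm_mm"]
    for a, b in variant_pairs:
        ka = flat.loc[a].sort_index()
        kb = flat.loc[b].sort_index()
        if not ka.index.equals(kb.index):
            raise ValueError(f"variants {a} and {b} do not share the same cells")
        pairs[(a, b)] = paired_t_ci(ka.to_numpy(), kb.to_numpy())

    return {"overall": overall, "per_group": per_group, "xy_paired": xy, "pairs": pairs}


def report_text(report: dict) -> str:
    """Human-readable rendering with the conventional 1-decimal rounding."""
    lines = ["Overall FWHM (mean +/- SD, mm):"]
    for v, (m, s) in report["overall"].items():
        lines.append(f"  {v:6s} {m:5.1f} +/- {s:.1f}")
    if len(report["per_group"]):
        lines.append("\nPer realization and direction:")
        lines.append(report["per_group"].round(1).to_string(index=False))
    if report["xy_paired"]:
        lines.append("\nY - X paired differences:")
        for v, r in report["xy_paired"].items():
            lines.append(
                f"  {v:6s} {r.mean_diff:4.1f} +/- {r.sd_diff:.1f} mm   "
                f"{r.percent:3.0f}%   P={r.p_two_sided:.3g}   "
                f"95% CI [{r.ci95[0]:.1f}, {r.ci95[1]:.1f}]"
            )
    for (a, b), r in report.get("pairs", {}).items():
        lines.append(
            f"\n{a} - {b}: {r.mean_diff:.1f} +/- {r.sd_diff:.1f} mm, "
            f"P={r.p_two_sided:.3g}, 95% CI [{r.ci95[0]:.1f}, {r.ci95[1]:.1f}]"
        )
    return "\n".join(lines)
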