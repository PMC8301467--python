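"""Left-right symmetry inference and baseline-referenced Z scores.

Confidence intervals for the mean paired difference come in two flavours:
the paired t interval (normality assumed) and the percentile bootstrap
(B = 10,000 by default, seeded, resampling per-animal differences with
replacement - identical to resampling (left, right) pairs for this
statistic).  Z scores standardize an observed measure against a baseline
cohort: z = (observed - baseline mean) / baseline SD (ddof = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LEVEL = 0.90
DEFAULT_B = 10_000

ORIENTATIONS = ("left_minus_right", "defect_minus_contra", "right_minus_left")


@dataclass
class PairedSample:
    metric: str
    animal_ids: list
    left: np.ndarray
    right: np.ndarray
    units: str = "mm"

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape or self.left.ndim != 1:
            raise ValueError("left/right must be 1D arrays of equal length")
        bad = [a for a, l, r in zip(self.animal_ids, self.left, self.right)
               if not (np.isfinite(l) and np.isfinite(r))]
        if bad:
            raise ValueError(f"incomplete pair for animal(s): {', '.join(map(str, bad))}")

    @property
    def n(self) -> int:
        return len(self.left)


@dataclass(frozen=True)
class SymmetryResult:
    metric: str
    n: int
    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    level: float = DEFAULT_LEVEL
    method: str = "paired_t"
    B: int | None = None
    seed: int | None = None
    degenerate: bool = False

    def contains_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


@dataclass(frozen=True)
class ZScoreResult:
    metric: str
    observed: float
    baseline_mean: float
    baseline_sd: float
    z: float


def paired_differences(sample: PairedSample, orientation: str = "left_minus_right",
                       defect_side: str = "left") -> np.ndarray:
    """Per-animal differences in the stated orientation (units preserved)."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation {orientation!r} not in {ORIENTATIONS}")
    d = sample.left - sample.right
    if orientation == "right_minus_left":
        d = -d
    elif orientation == "defect_minus_contra" and defect_side == "right":
        d = -d
    return d


def paired_t_ci(differences, level: float = DEFAULT_LEVEL,
                metric: str = "", units: str = "mm") -> SymmetryResult:
    """Closed-form paired-t interval: mean +/- t_{1-(1-level)/2, n-1} * sd/sqrt(n)."""
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        return SymmetryResult(metric, n, mean, 0.0, mean, mean, level, "paired_t",
                              degenerate=True)
    tcrit = float(stats.t.ppf(1 - (1 - level) / 2, n - 1))
    half = tcrit * sd / np.sqrt(n)
    return SymmetryResult(metric, n, mean, sd, mean - half, mean + half, level, "paired_t")


def bootstrap_ci(differences, level: float = DEFAULT_LEVEL, B: int = DEFAULT_B,
                 seed: int = 0, metric: str = "") -> SymmetryResult:
    """Percentile bootstrap interval of the mean paired difference."""
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    if B < 100:
        raise ValueError("need B >= 100 bootstrap resamples")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    n = len(d)
    rng = np.random.default_rng(seed)
    means = d[rng.integers(0, n, size=(B, n))].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return SymmetryResult(
        metric, n, float(np.mean(d)), float(np.std(d, ddof=1)), float(lo), float(hi),
        level, "bootstrap", B=B, seed=seed, degenerate=bool(np.ptp(d) == 0),
    )


def zscore(observed: float, baseline_differences, metric: str = "") -> ZScoreResult:
    """Standardize an observed measure against a baseline cohort."""
    base = np.asarray(baseline_differences, dtype=float)
    if base.ndim != 1 or len(base) < 2:
        raise ValueError("baseline cohort needs n >= 2")
    mean = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    if sd == 0:
        raise ValueError("baseline SD is 0: Z score undefined")
    return ZScoreResult(metric, float(observed), mean, sd, (float(observed) - mean) / sd)


def coverage_simulation(n: int = 8, level: float = DEFAULT_LEVEL,
                        method: str = "paired_t", reps: int = 5000,
                        B: int = 1000, seed: int = 0, sd: float = 1.0) -> float:
    """Empirical coverage of the CI under zero-mean normal differences.

    Simulates ``reps`` symmetric cohorts of ``n`` differences ~ N(0, sd)
    and returns the fraction of intervals containing 0.
    """
    if reps < 100:
        raise ValueError("need reps >= 100")
    rng = np.random.default_rng(seed)
    draws = rng.normal(0.0, sd, size=(reps, n))
    if method == "paired_t":
        mean = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        tcrit = stats.t.ppf(1 - (1 - level) / 2, n - 1)
        half = tcrit * sds / np.sqrt(n)
        hits = np.abs(mean) <= half
        return float(np.mean(hits))
    if method == "bootstrap":
        alpha = (1 - level) / 2
        hits = np.empty(reps, dtype=bool)
        chunk = max(1, int(5e6 / (B * n)))
        for start in range(0, reps, chunk):
            block = draws[start:start + chunk]
            idx = rng.integers(0, n, size=(len(block), B, n))
            means = np.take_along_axis(
                block[:, None, :], idx, axis=2
            ).mean(axis=2)
            lo = np.quantile(means, alpha, axis=1)
            hi = np.quantile(means, 1 - alpha, axis=1)
            hits[start:start + len(block)] = (lo <= 0) & (0 <= hi)
        return float(np.mean(hits))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------


def paired_samples_from_table(table: pd.DataFrame, timepoint: str = "baseline"):
    """Pivot a tidy metric table into per-metric PairedSamples."""
    required = {"animal_id", "side", "timepoint", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metric table is missing column(s): {sorted(missing)}")
    sub = table[table["timepoint"] == timepoint]
    samples = {}
    for metric, grp in sub.groupby("metric"):
        wide = grp.pivot_table(index="animal_id", columns="side", values="value")
        if "left" not in wide.columns or "right" not in wide.columns:
            continue
        wide = wide.dropna(subset=["left", "right"])
        units = grp["units"].iloc[0] if "units" in grp.columns else "mm"
        samples[metric] = PairedSample(
            metric, list(wide.index), wide["left"].to_numpy(), wide["right"].to_numpy(),
            units=units,
        )
    if not samples:
        raise ValueError(f"no complete left/right pairs at timepoint {timepoint!r}")
    return samples


def symmetry_report(table: pd.DataFrame, level: float = DEFAULT_LEVEL,
                    B: int = DEFAULT_B, seed: int = 0,
                    orientation: str = "left_minus_right",
                    baseline_timepoint: str = "baseline") -> dict:
    """Per-metric symmetry CIs at baseline plus Z scores for later timepoints.

    Returns ``{"results": DataFrame, "zscores": DataFrame, "differences": dict}``;
    the differences dict feeds the dot plots.
    """
    samples = paired_samples_from_table(table, baseline_timepoint)
    rows, diffs = [], {}
    for metric, sample in samples.items():
        d = paired_differences(sample, orientation)
        diffs[metric] = d
        for res in (paired_t_ci(d, level, metric), bootstrap_ci(d, level, B, seed, metric)):
            rows.append({
                "metric": metric, "n": res.n, "mean_diff": res.mean_diff,
                "sd_diff": res.sd_diff, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "level": res.level, "method": res.method, "B": res.B, "seed": res.seed,
                "units": sample.units,
            })
    zrows = []
    later = [t for t in table["timepoint"].unique() if t != baseline_timepoint]
    for tp in later:
        try:
            post = paired_samples_from_table(table, tp)
        except ValueError:
            continue
        for metric, sample in post.items():
            if metric not in diffs:
                continue
            base = diffs[metric]
            d = paired_differences(sample, orientation)
            for animal, obs in zip(sample.animal_ids, d):
                zr = zscore(obs, base, metric)
                zrows.append({
                    "metric": metric, "timepoint": tp, "animal_id": animal,
                    "observed_diff": zr.observed, "baseline_mean": zr.baseline_mean,
                    "baseline_sd": zr.baseline_sd, "z": zr.z,
                })
    return {
        "results": pd.DataFrame(rows),
        "zscores": pd.DataFrame(zrows),
        "differences": diffs,
    }


def plot_symmetry(report: dict, path, title: str = "Left-right differences at baseline"):
    """Dot plot of per-animal differences with both CIs per metric."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diffs = report["differences"]
    results = report["results"]
    fig, ax = plt.subplots(figsize=(1.8 + 1.6 * len(diffs), 4.0))
    rng = np.random.default_rng(0)
    for i, (metric, d) in enumerate(diffs.items()):
        jitter = rng.uniform(-0.12, 0.12, len(d))
        ax.plot(i + jitter, d, "o", color="0.4", ms=5, alpha=0.8, zorder=3)
        sub = results[results["metric"] == metric]
        for off, (_, row) in zip((-0.22, 0.22), sub.iterrows()):
            ax.vlines(i + off, row["ci_low"], row["ci_high"], lw=3,
                      color="tab:blue" if row["method"] == "paired_t" else "tab:orange")
            ax.plot(i + off, row["mean_diff"], "_", ms=12, color="k", zorder=4)
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xticks(range(len(diffs)), list(diffs))
    ax.set_ylabel("left - right difference")
    ax.set_title(title)
    from matplotlib.lines import Line2D
    ax.legend(handles=[
        Line2D([], [], color="tab:blue", lw=3, label="paired t CI"),
        Line2D([], [], color="tab:orange", lw=3, label="bootstrap CI"),
    ], loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
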