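"""Factorial experiment runner and statistical comparison of stent designs.

The study design crosses stent designs x expansion diameters x plaque
modes x synthetic bifurcation geometries (seeds), runs the reduced-order
deployment for every cell, and collects one :class:`MetricsReport` row per
cell into a tidy table.  Prolapse follows its own protocol (deployment
against the bare normal wall, no plaque assignment), so it is computed once
per (design, diameter, geometry) and attached to every plaque mode of that
cell block.

Group comparisons mirror the conventional bench-statistics workflow:
normality of each group is screened (Lilliefors-corrected
Kolmogorov-Smirnov); normal data go through one-way analysis of variance
with Bonferroni-corrected pairwise t tests, non-normal data through the
Friedman rank test (seeds as blocks) with Dunn's multiple-comparison test.
Summaries are mean +/- SEM across geometry seeds.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import DESIGN_CATALOG
from .metrics import MetricsReport, compute_metrics
from .solver import SolverConfig, expand_stent
from .vessel import (VesselParams, assign_heterogeneous_plaque,
                     assign_homogeneous_plaque, generate_bifurcation)

__all__ = [
    "FactorialDesign",
    "ResultsTable",
    "run_factorial",
    "expansion_difference",
    "compare_groups",
    "make_report",
    "sample_vessel_params",
    "DEFAULT_DESIGNS",
    "DEFAULT_DIAMETERS",
    "DEFAULT_PLAQUE_MODES",
]

DEFAULT_DESIGNS = ("MEGATRON_9", "MEGATRON_10", "MEGATRON_12", "SYNERGY")
DEFAULT_DIAMETERS = (3.5, 4.5, 5.0)
DEFAULT_PLAQUE_MODES = ("very_soft", "soft", "neutral", "stiff",
                        "very_stiff", "heterogeneous")


@dataclass(frozen=True)
class FactorialDesign:
    """Factor grid of the computational experiment."""

    designs: tuple[str, ...] = DEFAULT_DESIGNS
    diameters: tuple[float, ...] = DEFAULT_DIAMETERS
    plaque_modes: tuple[str, ...] = DEFAULT_PLAQUE_MODES
    geometry_seeds: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self):
        if not (self.designs and self.diameters and self.plaque_modes
                and self.geometry_seeds):
            raise ValueError("all factors must be non-empty")
        for d in self.designs:
            if d not in DESIGN_CATALOG:
                raise ValueError(f"unknown design {d!r}")
        valid = set(DEFAULT_PLAQUE_MODES)
        for m in self.plaque_modes:
            if m not in valid:
                raise ValueError(f"unknown plaque mode {m!r}")

    @property
    def n_cells(self) -> int:
        return (len(self.designs) * len(self.diameters)
                * len(self.plaque_modes) * len(self.geometry_seeds))


@dataclass
class ResultsTable:
    """Tidy results: one row per factorial cell, plus failure log."""

    frame: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    @property
    def attempted(self) -> int:
        return len(self.frame) + len(self.failures)

    @property
    def completed(self) -> int:
        return len(self.frame)

    def to_csv(self) -> str:
        """Deterministic CSV serialization (fixed float format)."""
        return self.frame.to_csv(index=False, float_format="%.8g",
                                 lineterminator="\n")


def sample_vessel_params(seed: int) -> VesselParams:
    """Per-geometry anatomical variation of the synthetic cohort.

    Proximal reference diameters 4.2-4.9 mm (LM-like, below the 5.0 mm
    study ceiling), area stenoses 40-70%, and modest variation in
    eccentricity, wall thickness and taper.
    """
    rng = np.random.default_rng(100_003 + seed)
    prox = rng.uniform(4.2, 4.9)
    return VesselParams(
        proximal_diameter=round(prox, 3),
        distal_diameter=round(prox * rng.uniform(0.74, 0.82), 3),
        side_branch_diameter=round(prox * rng.uniform(0.60, 0.70), 3),
        stenosis_severity=round(rng.uniform(0.40, 0.70), 3),
        stenosis_center_z=round(rng.uniform(16.0, 20.0), 2),
        stenosis_width=round(rng.uniform(3.0, 5.0), 2),
        eccentricity=round(rng.uniform(0.3, 0.7), 3),
        wall_thickness_mean=round(rng.uniform(0.15, 0.21), 3),
        wall_thickness_ripple=0.03,
    )


def _vessel_for(seed: int, mode: str):
    base = generate_bifurcation(sample_vessel_params(seed), seed=seed)
    if mode == "heterogeneous":
        return assign_heterogeneous_plaque(base)
    return assign_homogeneous_plaque(base, mode)


def run_factorial(fd: FactorialDesign | None = None,
                  config: SolverConfig | None = None,
                  progress: bool = False) -> ResultsTable:
    """Run every factorial cell and collect the metrics table.

    Deterministic for a fixed seed set.  Failed cells are logged with the
    solver residual and excluded from the frame, never silently dropped.
    """
    fd = fd or FactorialDesign()
    config = config or SolverConfig()
    rows, failures = [], []
    for seed in fd.geometry_seeds:
        bare = generate_bifurcation(sample_vessel_params(seed), seed=seed)
        vessels = {m: _vessel_for(seed, m) for m in fd.plaque_modes}
        for design_name, diameter in itertools.product(fd.designs,
                                                       fd.diameters):
            design = DESIGN_CATALOG[design_name]
            try:
                prolapse_state = expand_stent(design, bare, config,
                                              target_inner_diameter=diameter)
            except Exception as exc:  # logged, not fatal
                prolapse_state = None
                failures.append({"design": design_name,
                                 "diameter": diameter,
                                 "plaque_mode": "(prolapse protocol)",
                                 "geometry_seed": seed, "error": str(exc)})
            for mode in fd.plaque_modes:
                try:
                    st = expand_stent(design, vessels[mode], config,
                                      target_inner_diameter=diameter)
                    rep = compute_metrics(st, prolapse_state=prolapse_state,
                                          plaque_mode=mode,
                                          target_diameter=diameter,
                                          geometry_seed=seed)
                    rows.append(rep.row())
                except Exception as exc:
                    failures.append({"design": design_name,
                                     "diameter": diameter,
                                     "plaque_mode": mode,
                                     "geometry_seed": seed,
                                     "error": str(exc)})
            if progress:
                print(f"seed {seed} {design_name} {diameter:.1f} mm done")
    frame = pd.DataFrame(rows, columns=list(MetricsReport.FIELDS))
    return ResultsTable(frame=frame, failures=failures)


# ---------------------------------------------------------------------------
# design differences
# ---------------------------------------------------------------------------

def expansion_difference(table: ResultsTable, design_a: str, design_b: str,
                         metric: str = "msd") -> pd.DataFrame:
    """Percentage difference (a - b)/b x 100 per (diameter, plaque mode).

    Differences are computed per geometry seed (paired), then summarized as
    mean +/- SEM across seeds.
    """
    df = table.frame
    for d in (design_a, design_b):
        if d not in set(df["design"]):
            raise ValueError(f"design {d!r} not present in the table")
    a = df[df["design"] == design_a]
    b = df[df["design"] == design_b]
    keys = ["diameter", "plaque_mode", "geometry_seed"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    expect = df[keys].drop_duplicates()
    if len(merged) < len(expect):
        have = merged[keys].drop_duplicates()
        missing = expect.merge(have, how="left", indicator=True,
                               on=keys).query("_merge == 'left_only'")
        raise ValueError("missing cells for comparison: "
                         + missing[keys].to_string(index=False))
    merged["pct_diff"] = ((merged[f"{metric}_a"] - merged[f"{metric}_b"])
                          / merged[f"{metric}_b"] * 100.0)
    out = (merged.groupby(["diameter", "plaque_mode"])["pct_diff"]
           .agg(mean="mean", sem=lambda x: float(stats.sem(x, ddof=1))
                if len(x) > 1 else 0.0, n="count")
           .reset_index())
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _lilliefors_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Kolmogorov-Smirnov normality screen with estimated parameters.

    Uses the Lilliefors small-sample critical values (linear interpolation
    of the standard table); groups too small to test are treated as normal.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4 or np.std(x, ddof=1) == 0:
        return True
    z = (x - x.mean()) / np.std(x, ddof=1)
    d = stats.kstest(z, "norm").statistic
    # Lilliefors 5% critical values for n = 4..30, then asymptotic 0.886/sqrt(n)
    table = {4: 0.375, 5: 0.343, 6: 0.323, 7: 0.304, 8: 0.288, 9: 0.274,
             10: 0.262, 12: 0.242, 15: 0.220, 20: 0.190, 25: 0.173,
             30: 0.161}
    n = len(x)
    if n in table:
        crit = table[n]
    elif n < 30:
        ks = sorted(table)
        lo = max(k for k in ks if k <= n)
        hi = min(k for k in ks if k >= n)
        crit = np.interp(n, [lo, hi], [table[lo], table[hi]])
    else:
        crit = 0.886 / math.sqrt(n)
    return d < crit


def _bonferroni_pairwise_t(groups: dict) -> dict:
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    out = {}
    for a, b in itertools.combinations(names, 2):
        t, p = stats.ttest_ind(groups[a], groups[b])
        out[(a, b)] = min(p * m, 1.0)
    return out


def _friedman(groups: dict) -> tuple[float, float]:
    return stats.friedmanchisquare(*groups.values())


def _dunn_pairwise(groups: dict) -> dict:
    """Dunn's rank-based multiple comparisons after a Friedman test.

    Within-block ranks; z_ij = (Rbar_i - Rbar_j) / sqrt(k(k+1)/(6n)),
    two-sided normal p values, Bonferroni-adjusted over the pairs.
    """
    names = list(groups)
    data = np.column_stack([np.asarray(groups[n], dtype=float)
                            for n in names])
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rbar = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    m = k * (k - 1) // 2
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        z = (rbar[i] - rbar[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(names[i], names[j])] = min(p * m, 1.0)
    return out


def compare_groups(table: ResultsTable | pd.DataFrame, metric: str,
                   grouping: str, restrict: dict | None = None,
                   force_branch: str | None = None) -> dict:
    """Omnibus + post-hoc comparison of a metric across factor levels.

    Observations are per-geometry-seed means within each level of
    ``grouping`` (the seed is the experimental unit).  A normality screen
    selects the parametric branch (one-way analysis of variance with
    Bonferroni pairwise t tests) or the rank branch (Friedman over seed
    blocks with Dunn's test); ``force_branch`` ("anova" or "friedman")
    overrides the gate, so both branches are always explicitly available.

    Returns a dict with the branch, omnibus statistic and p value, the
    adjusted pairwise p values and the group summaries.
    """
    df = table.frame if isinstance(table, ResultsTable) else table
    if restrict:
        for k, v in restrict.items():
            df = df[df[k] == v]
    agg = (df.groupby([grouping, "geometry_seed"])[metric].mean()
           .reset_index())
    levels = sorted(agg[grouping].unique(), key=str)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    groups = {lv: agg[agg[grouping] == lv].sort_values("geometry_seed")
              [metric].to_numpy() for lv in levels}
    sizes = {lv: len(g) for lv, g in groups.items()}
    if min(sizes.values()) < 3:
        raise ValueError("need at least 3 observations per group")
    if len(set(sizes.values())) != 1:
        raise ValueError("unbalanced groups: incomplete seed blocks")

    branch = force_branch
    if branch is None:
        branch = ("anova" if all(_lilliefors_normal(g)
                                 for g in groups.values()) else "friedman")
    if branch == "anova":
        if all(np.allclose(g, list(groups.values())[0])
               for g in groups.values()):
            stat, p = 0.0, 1.0
            pairwise = {pair: 1.0 for pair in
                        itertools.combinations(levels, 2)}
        else:
            stat, p = stats.f_oneway(*groups.values())
            pairwise = _bonferroni_pairwise_t(groups)
    elif branch == "friedman":
        stat, p = _friedman(groups)
        pairwise = _dunn_pairwise(groups)
    else:
        raise ValueError("force_branch must be 'anova' or 'friedman'")
    summary = {lv: {"mean": float(np.mean(g)),
                    "sem": float(stats.sem(g, ddof=1)) if len(g) > 1
                    else 0.0,
                    "n": len(g)} for lv, g in groups.items()}
    return {"branch": branch, "statistic": float(stat), "p_value": float(p),
            "pairwise_adjusted_p": pairwise, "groups": summary}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

REPORT_METRICS = ("msd", "ccd", "prolapse", "sar", "normalized_hoop_force",
                  "radial_strength")


def make_report(table: ResultsTable, out_dir: str | None = None,
                plots: bool = True) -> dict[str, str]:
    """Grouped mean +/- SEM summaries per metric, plus bar figures.

    Returns ``{name: csv_text}``; when ``out_dir`` is given the CSVs (and
    PNG figures, if ``plots``) are also written there.  Regenerating from
    the same table is byte-identical (fixed float formatting).
    """
    df = table.frame
    outputs: dict[str, str] = {}
    for metric in REPORT_METRICS:
        if df.empty:
            summary = pd.DataFrame(columns=["design", "diameter",
                                            "plaque_mode", "mean", "sem",
                                            "n"])
        else:
            summary = (df.groupby(["design", "diameter", "plaque_mode"])
                       [metric]
                       .agg(mean="mean",
                            sem=lambda x: float(stats.sem(x, ddof=1))
                            if len(x) > 1 else 0.0,
                            n="count")
                       .reset_index()
                       .sort_values(["design", "diameter", "plaque_mode"]))
        outputs[metric] = summary.to_csv(index=False, float_format="%.8g",
                                         lineterminator="\n")
    if out_dir is not None:
        import pathlib
        p = pathlib.Path(out_dir)
        p.mkdir(parents=True, exist_ok=True)
        for metric, text in outputs.items():
            (p / f"summary_{metric}.csv").write_text(text)
        (p / "results.csv").write_text(table.to_csv())
        if plots and not df.empty:
            _write_plots(df, p)
    return outputs


def _write_plots(df: pd.DataFrame, out_dir) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    for metric in REPORT_METRICS:
        fig, axes = plt.subplots(1, len(sorted(df["diameter"].unique())),
                                 figsize=(4 * df["diameter"].nunique(), 3.2),
                                 sharey=True, squeeze=False)
        for ax, dia in zip(axes[0], sorted(df["diameter"].unique())):
            sub = df[df["diameter"] == dia]
            piv = (sub.groupby(["plaque_mode", "design"])[metric].mean()
                   .unstack("design"))
            piv.plot.bar(ax=ax, legend=(ax is axes[0][0]))
            ax.set_title(f"{dia:.1f} mm")
            ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(out_dir / f"fig_{metric}.png", dpi=110)
        plt.close(fig)
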