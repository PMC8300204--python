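"""Treatment comparison: aggregation, confidence intervals, Tukey letter tables.

The experimental unit is one 15-min recording mean (not single frames,
which are strongly autocorrelated). Units are crossed by lighting
treatment (e.g. blue / green / red), period of day and thermal-comfort
class; comparisons are two-way ANOVA on unit means followed by Tukey HSD
(Tukey-Kramer for unbalanced cells) with a compact letter display:

* lowercase letters compare treatments within one level of the second
  factor (one row of the table);
* uppercase letters compare levels of the second factor within one
  treatment (one column).

Groups sharing a letter are not significantly different at the stated
alpha (default 0.05).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from matplotlib.figure import Figure
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonTable",
    "aggregate_units",
    "mean_ci",
    "anova_tukey",
    "compact_letter_display",
    "report",
]

RESPONSE_COLUMNS = {"unrest": "unrest_index_cm", "cluster": "cluster_index"}


def aggregate_units(indexes: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """One observation unit per recording: mean indexes plus metadata.

    ``indexes`` is a concatenated index table carrying the recording
    metadata columns ``recording_id, treatment, date, period`` alongside
    the per-frame ``cluster_index`` / ``unrest_index_cm`` values (invalid
    frames hold NaN and are excluded from the means). ``labels`` maps
    ``recording_id`` to a comfort class; recordings labelled ``missing``
    or absent from ``labels`` are dropped with a log entry.
    """
    needed = {"recording_id", "treatment", "date", "period", "cluster_index", "unrest_index_cm"}
    if missing := needed - set(indexes.columns):
        raise ValueError(f"index table lacks columns {sorted(missing)}")
    g = indexes.groupby(["recording_id", "treatment", "date", "period"], sort=True)
    units = g.agg(
        cluster_index=("cluster_index", "mean"),
        unrest_index_cm=("unrest_index_cm", "mean"),
        n_frames=("cluster_index", "size"),
    ).reset_index()
    merged = units.merge(
        labels[["recording_id", "comfort"]], on="recording_id", how="left"
    )
    bad = merged["comfort"].isna() | (merged["comfort"] == "missing")
    if bad.any():
        logger.warning(
            "aggregate_units: %d recordings without a comfort label excluded",
            int(bad.sum()),
        )
    return merged.loc[~bad].reset_index(drop=True)


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Two-sided t-based confidence interval ``(mean, lower, upper)``."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n < 2:
        raise ValueError("a confidence interval needs n >= 2 values")
    m = float(arr.mean())
    sem = float(arr.std(ddof=1)) / np.sqrt(n)
    half = float(sps.t.ppf(0.5 + level / 2.0, df=n - 1)) * sem
    return m, m - half, m + half


# ---------------------------------------------------------------------------
# Tukey letters


def compact_letter_display(
    groups: list[str],
    significant_pairs: set[frozenset],
    means: dict[str, float],
    alphabet: str = "abcdefghij",
) -> dict[str, str]:
    """Letters such that two groups share one iff they are not significantly
    different.

    Implemented via maximal cliques of the not-different graph, so the
    display is always consistent with the pairwise decision matrix.
    Cliques (hence letters) are ordered by the largest group mean they
    contain, giving 'a' to the top group.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for x, y in itertools.combinations(groups, 2):
        if frozenset((x, y)) not in significant_pairs:
            g.add_edge(x, y)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-max(means[m] for m in c), sorted(c)))
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            letters[member].append(letter)
    return {grp: "".join(sorted(ls)) for grp, ls in letters.items()}


def _tukey_pairs(values: pd.Series, groups: pd.Series, alpha: float):
    """Significant pairs and group means from a one-way Tukey HSD.

    Groups with fewer than 2 observations are omitted (and logged);
    returns (group order, means, significant pair set, omitted groups).
    """
    counts = groups.value_counts()
    keep = counts[counts >= 2].index
    omitted = sorted(set(counts.index) - set(keep))
    if omitted:
        logger.warning("Tukey: omitting groups with <2 units: %s", omitted)
    sel = groups.isin(keep)
    vals, grp = values[sel], groups[sel]
    order = sorted(keep)
    means = {g: float(vals[grp == g].mean()) for g in order}
    sig: set[frozenset] = set()
    if len(order) >= 2 and float(np.var(vals.to_numpy())) > 0:
        res = pairwise_tukeyhsd(vals.to_numpy(), grp.to_numpy(), alpha=alpha)
        for (a, b), rej in zip(
            itertools.combinations(res.groupsunique, 2), res.reject
        ):
            if bool(rej):
                sig.add(frozenset((a, b)))
    return order, means, sig, omitted


@dataclass
class ComparisonTable:
    """Tukey-lettered cell means for factor_b levels x treatments."""

    response: str
    factor_b: str
    alpha: float
    cell_means: pd.DataFrame  # rows: factor_b levels, cols: treatments
    letters_lower: pd.DataFrame  # across treatments within a level
    letters_upper: pd.DataFrame  # across levels within a treatment
    anova: pd.DataFrame

    @property
    def treatment_pvalue(self) -> float:
        return float(self.anova.loc["C(treatment)", "PR(>F)"])

    def formatted(self, ndigits: int = 2) -> pd.DataFrame:
        """Cells as ``mean UPPERlower`` strings, the journal-table style."""
        out = self.cell_means.round(ndigits).astype(str)
        for lev in out.index:
            for trt in out.columns:
                up = self.letters_upper.loc[lev, trt]
                lo = self.letters_lower.loc[lev, trt]
                if pd.notna(self.cell_means.loc[lev, trt]):
                    out.loc[lev, trt] = f"{out.loc[lev, trt]} {up.upper()}{lo}"
        return out


def anova_tukey(
    units: pd.DataFrame,
    response: Literal["unrest", "cluster"],
    factor_b: Literal["period", "comfort"],
    alpha: float = 0.05,
) -> ComparisonTable:
    """Two-way ANOVA plus Tukey letter display on recording means.

    Lowercase letters come from Tukey HSD across treatments within each
    ``factor_b`` level; uppercase letters from Tukey HSD across levels
    within each treatment. Empty or singleton cells are omitted from the
    affected comparison and logged.
    """
    col = RESPONSE_COLUMNS[response]
    df = units.dropna(subset=[col]).copy()
    if df["treatment"].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValueError("need >= 2 levels of each factor")
    df = df.rename(columns={col: "_y", factor_b: "_b"})
    model = smf.ols("_y ~ C(treatment) * C(_b)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova.index = [i.replace("_b", factor_b) for i in anova.index]

    treatments = sorted(df["treatment"].unique())
    levels = sorted(df["_b"].unique())
    cell_means = pd.DataFrame(index=levels, columns=treatments, dtype=float)
    letters_lower = pd.DataFrame("", index=levels, columns=treatments)
    letters_upper = pd.DataFrame("", index=levels, columns=treatments)

    for lev in levels:
        sub = df[df["_b"] == lev]
        order, means, sig, _ = _tukey_pairs(sub["_y"], sub["treatment"], alpha)
        cld = compact_letter_display(order, sig, means)
        for trt in order:
            cell_means.loc[lev, trt] = means[trt]
            letters_lower.loc[lev, trt] = cld[trt]
    for trt in treatments:
        sub = df[df["treatment"] == trt]
        order, means, sig, _ = _tukey_pairs(sub["_y"], sub["_b"], alpha)
        cld = compact_letter_display(order, sig, means, alphabet="ABCDEFGHIJ")
        for lev in order:
            letters_upper.loc[lev, trt] = cld[lev]

    return ComparisonTable(
        response=response,
        factor_b=factor_b,
        alpha=alpha,
        cell_means=cell_means,
        letters_lower=letters_lower,
        letters_upper=letters_upper,
        anova=anova,
    )


# ---------------------------------------------------------------------------
# report bundle


def _ci_figure(units: pd.DataFrame) -> Figure:
    fig = Figure(figsize=(8, 3.2))
    for ax, (resp, col) in zip(fig.subplots(1, 2), RESPONSE_COLUMNS.items()):
        trts = sorted(units["treatment"].unique())
        for i, trt in enumerate(trts):
            vals = units.loc[units["treatment"] == trt, col].dropna()
            if len(vals) >= 2:
                m, lo, hi = mean_ci(vals)
                ax.errorbar(i, m, yerr=[[m - lo], [hi - m]], fmt="o", capsize=4)
        ax.set_xticks(range(len(trts)), trts)
        ax.set_title(f"{resp} index: mean and 95% CI")
    fig.tight_layout()
    return fig


def _daily_figure(units: pd.DataFrame) -> Figure:
    fig = Figure(figsize=(8, 3.2))
    for ax, (resp, col) in zip(fig.subplots(1, 2), RESPONSE_COLUMNS.items()):
        daily = units.groupby(["date", "treatment"])[col].mean().reset_index()
        for trt, g in daily.groupby("treatment"):
            ax.plot(g["date"], g[col], marker=".", label=str(trt))
        ax.set_title(f"daily mean {resp} index")
        ax.legend(fontsize="small")
        ax.tick_params(axis="x", labelrotation=45)
    fig.tight_layout()
    return fig


def _interaction_figure(units: pd.DataFrame) -> Figure:
    fig = Figure(figsize=(8, 3.2))
    order = ["cold", "comfort", "heat"]
    for ax, (resp, col) in zip(fig.subplots(1, 2), RESPONSE_COLUMNS.items()):
        cm = units.groupby(["comfort", "treatment"])[col].mean().reset_index()
        for trt, g in cm.groupby("treatment"):
            g = g.set_index("comfort").reindex([o for o in order if o in g["comfort"].values])
            ax.plot(g.index, g[col], marker="o", label=str(trt))
        ax.set_title(f"{resp} index by comfort class")
        ax.legend(fontsize="small")
    fig.tight_layout()
    return fig


def report(
    units: pd.DataFrame,
    out_dir: str | Path,
    variant: str = "n_minus_1",
    alpha: float = 0.05,
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Write the comparison bundle: Tukey tables, figures, run manifest.

    Produces, under ``out_dir``: ``tables/`` with cell means and letter
    displays per response x factor, ``figures/`` with the CI, daily-mean
    and comfort-interaction plots, and ``manifest.json`` echoing the
    configuration, index variant and seed. Raises ``ValueError`` on an
    empty unit list.
    """
    if len(units) == 0:
        raise ValueError("no observation units to report on")
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(parents=True, exist_ok=True)

    tables: dict[str, ComparisonTable] = {}
    written = []
    for resp in ("unrest", "cluster"):
        for fb in ("period", "comfort"):
            if fb not in units.columns or units[fb].nunique() < 2:
                logger.warning("report: skipping %s x %s (insufficient levels)", resp, fb)
                continue
            tab = anova_tukey(units, resp, fb, alpha=alpha)
            key = f"{resp}_by_{fb}"
            tables[key] = tab
            tab.formatted().to_csv(out / "tables" / f"{key}_letters.csv")
            tab.cell_means.to_csv(out / "tables" / f"{key}_means.csv")
            tab.anova.to_csv(out / "tables" / f"{key}_anova.csv")
            written.append(key)

    units.to_csv(out / "tables" / "units.csv", index=False)
    figs = {
        "ci_means.png": _ci_figure(units),
        "daily_means.png": _daily_figure(units),
    }
    if "comfort" in units.columns:
        figs["interaction_comfort.png"] = _interaction_figure(units)
    for name, fig in figs.items():
        fig.savefig(out / "figures" / name, dpi=110, metadata={"Software": "hensight"})

    from . import __version__

    manifest = {
        "package": "hensight",
        "version": __version__,
        "index_variant": variant,
        "alpha": alpha,
        "seed": seed,
        "n_units": int(len(units)),
        "tables": written,
        "config": config or {},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return {"tables": tables, "manifest": manifest, "out_dir": str(out)}
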