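"""Crude-vs-processed biomarker comparison.

Assembles the compounds x samples EIC peak-area matrix (missing or
unintegrable peaks are stored as zero), normalizes each compound to its
maximum across all samples ("relative intensity"), and tests per-compound
group differences with a two-way fixed-effects ANOVA (group x compound)
followed by Bonferroni-corrected per-compound contrasts — the classic
desktop-statistics "two-way ANOVA + Bonferroni post-tests" workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "MONITORED_COMPOUNDS",
    "PROCESSING_AFFECTED",
    "IntensityMatrix",
    "AnovaResult",
    "build_intensity_matrix",
    "two_way_anova_bonferroni",
    "plot_group_means",
]

#: The twelve EIC-monitored constituents used for profile comparison.
MONITORED_COMPOUNDS: tuple[str, ...] = (
    "sucrose",
    "gallic acid",
    "procyanidin B",
    "catechin",
    "6-methoxyl-2-acetyl-3-methyljuglone-8-O-glu",
    "tetrahydroxystilbene-O-di-glu",
    "THSG",
    "citreorosein-O-glu",
    "torachrysone-O-glu",
    "emodin-8-O-glu",
    "emodin-O-(malonyl)-glu",
    "emodin",
)

#: The eight markers whose abundance shifts between crude and steamed root.
PROCESSING_AFFECTED: tuple[str, ...] = (
    "sucrose",
    "gallic acid",
    "procyanidin B",
    "catechin",
    "THSG",
    "torachrysone-O-glu",
    "emodin-8-O-glu",
    "emodin-O-(malonyl)-glu",
)

_STAR_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float, alpha_tiers=_STAR_TIERS) -> str:
    for cut, label in alpha_tiers:
        if p < cut:
            return label
    return "ns"


@dataclass
class IntensityMatrix:
    """EIC peak areas, compounds x (group, batch, replicate) samples."""

    data: pd.DataFrame  # rows: compound; columns: MultiIndex (group, batch, replicate)

    def __post_init__(self):
        if (self.data.to_numpy() < 0).any():
            raise ValueError("peak areas must be >= 0")

    @property
    def compounds(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.data.columns.get_level_values("group")))

    def relative(self) -> pd.DataFrame:
        """Each compound scaled to its maximum area across all samples."""
        maxima = self.data.max(axis=1)
        if (maxima == 0).any():
            zeros = list(maxima.index[maxima == 0])
            raise ValueError(f"compounds never detected: {zeros}")
        return self.data.div(maxima, axis=0)

    def to_long(self, relative: bool = True) -> pd.DataFrame:
        wide = self.relative() if relative else self.data
        long = wide.stack(["group", "batch", "replicate"], future_stack=True)
        long.name = "value"
        return long.reset_index().rename(columns={"level_0": "compound"})


def build_intensity_matrix(
    samples: pd.DataFrame | Sequence[tuple],
    compounds: Sequence[str] | None = None,
) -> IntensityMatrix:
    """Assemble the intensity matrix from long-format records.

    ``samples`` is either a DataFrame with columns
    (group, batch, replicate, compound, area) or a sequence of
    ``(group, batch, replicate, {compound: area})`` tuples. Compounds absent
    from a sample are stored as zero (the missing -> zero rule for peaks
    that could not be detected or integrated). Duplicate
    (group, batch, replicate, compound) keys are rejected.
    """
    if not isinstance(samples, pd.DataFrame):
        rows = []
        for group, batch, replicate, areas in samples:
            for compound, area in areas.items():
                rows.append((group, batch, replicate, compound, area))
        samples = pd.DataFrame(
            rows, columns=["group", "batch", "replicate", "compound", "area"]
        )
    required = {"group", "batch", "replicate", "compound", "area"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    keys = ["group", "batch", "replicate", "compound"]
    if samples.duplicated(subset=keys).any():
        dupes = samples[samples.duplicated(subset=keys, keep=False)]
        raise ValueError(
            f"duplicate sample keys:\n{dupes[keys].drop_duplicates()}"
        )
    wide = samples.pivot_table(
        index="compound",
        columns=["group", "batch", "replicate"],
        values="area",
        fill_value=0.0,
        aggfunc="sum",
    )
    if compounds is not None:
        wide = wide.reindex(list(compounds), fill_value=0.0)
    return IntensityMatrix(data=wide.astype(float))


@dataclass
class AnovaResult:
    """Two-way ANOVA with per-compound Bonferroni-corrected group contrasts."""

    anova_table: pd.DataFrame      # group / compound / interaction / residual
    contrasts: pd.DataFrame        # per-compound raw p, adjusted p, stars
    alpha: float
    bonferroni_m: int

    @property
    def flagged(self) -> list[str]:
        return list(self.contrasts.index[self.contrasts["significant"]])


def two_way_anova_bonferroni(
    matrix: IntensityMatrix,
    alpha: float = 0.05,
    replicate_handling: str = "batch_means",
    log_transform: bool = False,
) -> AnovaResult:
    """Group x compound fixed-effects ANOVA on relative intensities.

    ``replicate_handling``: "batch_means" (default) averages technical
    replicates so batches are the experimental n; "replicates" uses every
    replicate as a unit. Each compound's group contrast is a t-test on the
    pooled residual mean square of the full model, Bonferroni-multiplied by
    the number of compounds; significance tiers are * 0.05 / ** 0.01 /
    *** 0.001 on the adjusted p-values.
    """
    if replicate_handling not in ("batch_means", "replicates"):
        raise ValueError("replicate_handling must be 'batch_means' or 'replicates'")
    long = matrix.to_long(relative=True)
    if log_transform:
        if (long["value"] <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        long["value"] = np.log(long["value"])
    if replicate_handling == "batch_means":
        long = (
            long.groupby(["group", "batch", "compound"], as_index=False)["value"]
            .mean()
        )
    groups = sorted(long["group"].unique())
    compounds = matrix.compounds
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if len(compounds) < 2:
        raise ValueError("need at least 2 compounds")
    cell_sizes = long.groupby(["group", "compound"])["value"].size()
    if (cell_sizes < 2).any():
        raise ValueError("need at least 2 observations per group x compound cell")

    fit = smf.ols("value ~ C(group) * C(compound)", data=long).fit()
    # relative intensities are O(1); an SSR at rounding-error level means a
    # constant-within-cell design with nothing to test against
    if fit.df_resid <= 0 or fit.ssr < 1e-10:
        raise ValueError(
            "degenerate design: no residual variance to test against"
        )
    anova_table = sm.stats.anova_lm(fit, typ=2)

    if len(groups) != 2:
        raise ValueError("per-compound contrasts are defined for exactly 2 groups")
    g1, g2 = groups
    mse = fit.mse_resid
    dof = fit.df_resid
    rows = []
    from scipy import stats as sps

    m = len(compounds)
    for compound in compounds:
        sub = long[long["compound"] == compound]
        x1 = sub.loc[sub["group"] == g1, "value"]
        x2 = sub.loc[sub["group"] == g2, "value"]
        diff = x2.mean() - x1.mean()
        se = np.sqrt(mse * (1.0 / len(x1) + 1.0 / len(x2)))
        t = diff / se
        raw_p = 2.0 * sps.t.sf(abs(t), dof)
        adj_p = min(1.0, raw_p * m)
        rows.append(
            {
                "compound": compound,
                f"mean_{g1}": x1.mean(),
                f"mean_{g2}": x2.mean(),
                "diff": diff,
                "t": t,
                "raw_p": raw_p,
                "adj_p": adj_p,
                "stars": _stars(adj_p),
                "significant": adj_p < alpha,
            }
        )
    contrasts = pd.DataFrame(rows).set_index("compound")
    return AnovaResult(
        anova_table=anova_table,
        contrasts=contrasts,
        alpha=alpha,
        bonferroni_m=m,
    )


def plot_group_means(matrix: IntensityMatrix, result: AnovaResult, path=None):
    """Bar plot of mean +- SD relative intensity per group with star tiers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rel = matrix.relative()
    groups = matrix.groups
    compounds = matrix.compounds
    x = np.arange(len(compounds))
    width = 0.8 / len(groups)
    fig, ax = plt.subplots(figsize=(max(8, len(compounds) * 0.9), 4.5))
    for i, g in enumerate(groups):
        sub = rel.xs(g, axis=1, level="group")
        ax.bar(
            x + i * width,
            sub.mean(axis=1),
            width,
            yerr=sub.std(axis=1, ddof=1),
            capsize=2,
            label=g,
        )
    for i, compound in enumerate(compounds):
        star = result.contrasts.loc[compound, "stars"]
        if star != "ns":
            ax.text(x[i] + 0.4 * width, 1.02, star, ha="center")
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels(compounds, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("Relative intensity")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
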