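"""Model/Results interface for preprocessing-robustness analysis.

:class:`PreprocessingRobustness` is built from a long-format feature
table (one row per subject x preprocessing coordinate x feature) and a
declaration of which preprocessing element is varied (the "raters") and
which are held fixed (the strata).  ``fit()`` computes, per feature and
stratum:

* the two-way mixed single-rater absolute-agreement ICC with its
  variability band,
* per-subject coefficients of variation and their median summary,
* optionally the repeated-measures correlation between the feature and
  the varied (numeric) element, Bonferroni-adjusted over the family of
  all tests for the effect.

Rows with undefined feature values are removed listwise per ICC matrix
(the crossed ANOVA needs a complete layout); removal counts are kept in
the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

__all__ = ["PreprocessingRobustness", "RobustnessResults", "EFFECT_LAYOUT"]

# effect id -> (varied column, stratum column, rmcorr applicable)
EFFECT_LAYOUT = {
    "A": ("voxel_size_mm", "bin_width_ms", True),
    "B": ("bin_width_ms", "voxel_size_mm", True),
    "C": ("filter", None, False),
}


@dataclass
class RobustnessResults:
    effect: str
    icc_table: pd.DataFrame
    cv_records: pd.DataFrame
    cv_summary_table: pd.DataFrame
    rmcorr_table: pd.DataFrame | None
    n_dropped_subject_rows: int
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            f"Preprocessing robustness results — effect {self.effect}",
            "=" * 56,
            f"features analysed:      {self.icc_table[['feature_class', 'feature_name']].drop_duplicates().shape[0]}",
            f"ICC matrices:           {len(self.icc_table)}",
            f"subject rows dropped:   {self.n_dropped_subject_rows}",
            "",
            "ICC band counts (matrices):",
        ]
        for band, cnt in self.icc_table["band"].value_counts().items():
            lines.append(f"  {band:<12} {cnt}")
        med = self.cv_summary_table["median_cv_percent"]
        lines.append("")
        lines.append(
            f"median CV%: min={med.min():.2f}  median={med.median():.2f}  max={med.max():.2f}"
        )
        if self.rmcorr_table is not None and len(self.rmcorr_table):
            sig = int(self.rmcorr_table["significant"].sum())
            lines.append(
                f"rmcorr: {sig}/{len(self.rmcorr_table)} tests significant "
                f"(Bonferroni, alpha={self.alpha})"
            )
        return "\n".join(lines)


class PreprocessingRobustness:
    """Robustness model over a long-format feature table."""

    def __init__(
        self,
        table: pd.DataFrame,
        varied: str,
        stratum: str | None = None,
        rm_x: bool = False,
        alpha: float = 0.05,
        effect: str = "?",
    ):
        required = {"subject_id", "feature_class", "feature_name", "value", varied}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"feature table is missing columns: {sorted(missing)}")
        self.table = table
        self.varied = varied
        self.stratum = stratum
        self.rm_x = rm_x
        self.alpha = alpha
        self.effect = effect

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, effect: str, alpha: float = 0.05):
        """Configure the model for one of the canonical effects:
        A (vary voxel size), B (vary bin width), C (vary filter)."""
        if effect not in EFFECT_LAYOUT:
            raise ValueError(f"effect must be one of {sorted(EFFECT_LAYOUT)}, got {effect!r}")
        varied, stratum, rm = EFFECT_LAYOUT[effect]
        return cls(table, varied=varied, stratum=stratum, rm_x=rm, alpha=alpha, effect=effect)

    def fit(self) -> RobustnessResults:
        df = self.table
        group_cols = ["feature_class", "feature_name"]
        if self.stratum is not None:
            group_cols = group_cols + [self.stratum]

        icc_rows, cv_rows, rm_rows = [], [], []
        dropped_total = 0
        for keys, grp in df.groupby(group_cols, sort=True):
            wide = grp.pivot_table(
                index="subject_id", columns=self.varied, values="value", aggfunc="first"
            )
            complete = wide.dropna(axis=0, how="any")
            dropped = len(wide) - len(complete)
            dropped_total += dropped
            info = dict(zip(group_cols, keys))

            if len(complete) >= 2 and complete.shape[1] >= 2:
                est = stats.icc(complete.to_numpy())
                icc_rows.append(
                    {**info, "icc": est.value, "band": est.band, "degenerate": est.degenerate,
                     "n_subjects": len(complete), "n_dropped": dropped}
                )
                for sid, row in complete.iterrows():
                    cv_rows.append({**info, "subject_id": sid, "cv_percent": stats.cv(row.to_numpy())})
                if self.rm_x:
                    long = complete.reset_index().melt(
                        id_vars="subject_id", var_name="x", value_name="y"
                    )
                    est_rm = stats.rmcorr(
                        long["subject_id"].to_numpy(),
                        long["x"].to_numpy(dtype=float),
                        long["y"].to_numpy(dtype=float),
                    )
                    rm_rows.append(
                        {**info, "r_rm": est_rm.r_rm, "df": est_rm.df, "p_value": est_rm.p_value}
                    )
            else:
                icc_rows.append(
                    {**info, "icc": np.nan, "band": "undefined", "degenerate": True,
                     "n_subjects": len(complete), "n_dropped": dropped}
                )

        icc_table = pd.DataFrame(icc_rows)
        cv_records = pd.DataFrame(cv_rows)
        if len(cv_records):
            cv_summary_table = (
                cv_records.groupby(["feature_class", "feature_name"])["cv_percent"]
                .apply(stats.cv_summary)
                .rename("median_cv_percent")
                .reset_index()
            )
        else:
            cv_summary_table = pd.DataFrame(columns=["feature_class", "feature_name", "median_cv_percent"])

        rmcorr_table = None
        if self.rm_x:
            rmcorr_table = pd.DataFrame(rm_rows)
            if len(rmcorr_table):
                m = len(rmcorr_table)  # family: all tests for this effect
                rmcorr_table["p_bonferroni"] = np.minimum(1.0, rmcorr_table["p_value"] * m)
                rmcorr_table["significant"] = stats.bonferroni(
                    rmcorr_table["p_value"].to_numpy(), alpha=self.alpha
                )

        return RobustnessResults(
            effect=self.effect,
            icc_table=icc_table,
            cv_records=cv_records,
            cv_summary_table=cv_summary_table,
            rmcorr_table=rmcorr_table,
            n_dropped_subject_rows=dropped_total,
            alpha=self.alpha,
        )
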