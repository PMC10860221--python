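"""Richness-normalized HGT-rate modelling and retention of transferred genes.

The contig-level HGT counts (taxonomic-discordance calls per sample) are
normalized by species richness and modelled with a linear mixed model:
treatment, sex and timepoint as fixed effects, a per-participant random
intercept, and a likelihood-ratio test deciding whether the interaction
terms stay in the model (they are excluded when the LRT is non-significant,
and the reduced model is reported). Retention tracks each distinct
engraftment-dependent (recipient, cluster) unit through the week-6/12/26
abundance series; a unit is retained at a timepoint when its cluster
abundance is above the (configurable, default 0) copies-per-million
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from ._util import percent


@dataclass
class LmmSpec:
    """Fixed-effect layout for a random-intercept linear mixed model.

    ``fixed_effects`` is an ordered list of (column, reference level);
    ``random_intercept`` names the grouping column.
    """

    response: str
    fixed_effects: list[tuple[str, str]]
    random_intercept: str


@dataclass
class LmmResult:
    params: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p
    lrt_p_interactions: float | None
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def coef(self, term_substring: str) -> pd.Series:
        hits = self.params[self.params["term"].str.contains(term_substring, regex=False)]
        if len(hits) != 1:
            raise KeyError(f"{term_substring!r} matches {len(hits)} coefficients")
        return hits.iloc[0]

    def summary(self) -> str:
        lines = ["term".ljust(42) + "estimate   ci_low  ci_high        p"]
        for _, r in self.params.iterrows():
            lines.append(
                f"{r['term']:<42}{r['estimate']:>8.4f} {r['ci_low']:>8.4f} "
                f"{r['ci_high']:>8.4f} {r['p']:>8.2g}"
            )
        if self.lrt_p_interactions is not None:
            lines.append(f"LRT (interactions vs none): p = {self.lrt_p_interactions:.4g}")
        return "\n".join(lines)


def normalize_hgt_rate(waafle: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalized HGT count: contig events / species richness."""
    if (waafle["species_richness"] <= 0).any():
        bad = waafle.loc[waafle["species_richness"] <= 0, "sample_id"]
        raise ValueError(f"species richness must be positive; offending sample(s): {sorted(bad)[:10]}")
    out = waafle.copy()
    out["normalized_hgt"] = out["n_hgt_contigs"] / out["species_richness"]
    return out


def _formula(spec: LmmSpec, interactions: bool) -> str:
    terms = [f"C({col}, Treatment('{ref}'))" for col, ref in spec.fixed_effects]
    op = " * " if interactions else " + "
    return f"{spec.response} ~ {op.join(terms)}"


def fit_lmm(data: pd.DataFrame, spec: LmmSpec, lrt: bool = True) -> LmmResult:
    """REML fit of the random-intercept model, with Wald normal 95% CIs.

    When ``lrt`` is true, full (all interactions) and reduced (no
    interactions) models are compared with a likelihood-ratio test on ML
    fits; the reduced model is what gets reported either way (matching an
    analysis that excluded interactions after a non-significant LRT).
    """
    for col, ref in spec.fixed_effects:
        if ref not in set(data[col]):
            raise ValueError(f"reference level {ref!r} absent from column {col!r}")
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        lrt_p = None
        if lrt and len(spec.fixed_effects) > 1:
            full = smf.mixedlm(_formula(spec, True), data, groups=data[spec.random_intercept]).fit(reml=False)
            red_ml = smf.mixedlm(_formula(spec, False), data, groups=data[spec.random_intercept]).fit(reml=False)
            stat = 2 * (full.llf - red_ml.llf)
            ddf = full.df_modelwc - red_ml.df_modelwc
            lrt_p = float(stats.chi2.sf(max(stat, 0.0), ddf)) if ddf > 0 else 1.0
        model = smf.mixedlm(_formula(spec, False), data, groups=data[spec.random_intercept])
        fit = model.fit(reml=True)
        caught = sorted({str(w.message) for w in wlist})

    fe = fit.fe_params
    se = fit.bse_fe
    z = stats.norm.ppf(0.975)
    params = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.values,
            "se": se.values,
            "ci_low": fe.values - z * se.values,
            "ci_high": fe.values + z * se.values,
            "p": 2 * stats.norm.sf(np.abs(fe.values / se.values)),
        }
    )
    return LmmResult(
        params=params,
        lrt_p_interactions=lrt_p,
        converged=bool(getattr(fit, "converged", True)),
        warnings=caught,
    )


WAAFLE_SPEC = LmmSpec(
    response="normalized_hgt",
    fixed_effects=[("arm", "placebo"), ("sex", "female"), ("timepoint", "baseline")],
    random_intercept="subject_id",
)

RETENTION_SPEC = LmmSpec(
    response="cpm",
    fixed_effects=[("sex", "female"), ("timepoint", "week6")],
    random_intercept="recipient_id",
)


@dataclass
class RetentionResult:
    by_sex: pd.DataFrame  # sex, n_units, retained_week12, pct_week12, retained_week26, pct_week26
    series: pd.DataFrame  # recipient_id, sex, cluster_id, timepoint, cpm
    qc_missing_week6: pd.DataFrame  # units without week-6 abundance, excluded


def retention(
    events: pd.DataFrame,
    abundance: pd.DataFrame,
    samples: pd.DataFrame,
    cpm_threshold: float = 0.0,
) -> RetentionResult:
    """Retention of engraftment-dependent clusters at weeks 12 and 26.

    Duplicate events of the same cluster (different genes) collapse to one
    (recipient, cluster) unit, because abundance is cluster-level. Retention
    at t = units with cpm > threshold at t / units detected (with abundance)
    at week 6.
    """
    units = events.drop_duplicates(["recipient_id", "cluster_id"])[
        ["recipient_id", "sex", "cluster_id"]
    ].reset_index(drop=True)

    rec_samples = samples[samples["timepoint"].isin(("week6", "week12", "week26"))]
    ab = abundance.merge(rec_samples, on="sample_id", how="inner")
    grid = units.merge(
        ab[["subject_id", "cluster_id", "timepoint", "cpm"]],
        left_on=["recipient_id", "cluster_id"],
        right_on=["subject_id", "cluster_id"],
        how="left",
    ).drop(columns="subject_id")

    wide = grid.pivot_table(
        index=["recipient_id", "sex", "cluster_id"],
        columns="timepoint",
        values="cpm",
        aggfunc="first",
    ).reset_index()
    # units with no abundance rows at all drop out of the pivot; reinstate
    # them so they land in the QC report rather than vanishing silently
    wide = units.merge(wide, on=["recipient_id", "sex", "cluster_id"], how="left")
    for tp in ("week6", "week12", "week26"):
        if tp not in wide.columns:
            wide[tp] = np.nan

    missing = wide[wide["week6"].isna() | (wide["week6"] <= cpm_threshold)]
    kept = wide[wide["week6"].notna() & (wide["week6"] > cpm_threshold)]

    rows = []
    for sex, sub in kept.groupby("sex"):
        n = len(sub)
        r12 = int((sub["week12"].fillna(0) > cpm_threshold).sum())
        r26 = int((sub["week26"].fillna(0) > cpm_threshold).sum())
        rows.append(
            {
                "sex": sex,
                "n_units": n,
                "retained_week12": r12,
                "pct_week12": percent(r12, n) if n else float("nan"),
                "retained_week26": r26,
                "pct_week26": percent(r26, n) if n else float("nan"),
            }
        )
    series = kept.melt(
        id_vars=["recipient_id", "sex", "cluster_id"],
        value_vars=["week6", "week12", "week26"],
        var_name="timepoint",
        value_name="cpm",
    )
    series["cpm"] = series["cpm"].fillna(0.0)
    return RetentionResult(
        by_sex=pd.DataFrame(rows, columns=[
            "sex", "n_units", "retained_week12", "pct_week12", "retained_week26", "pct_week26",
        ]),
        series=series.reset_index(drop=True),
        qc_missing_week6=missing[["recipient_id", "sex", "cluster_id"]].reset_index(drop=True),
    )


def retention_lmm(series: pd.DataFrame, lrt: bool = True) -> LmmResult:
    """LMM on the deduplicated abundance series: sex (ref female) and
    timepoint (ref week6) fixed effects, recipient random intercept."""
    return fit_lmm(series, RETENTION_SPEC, lrt=lrt)
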