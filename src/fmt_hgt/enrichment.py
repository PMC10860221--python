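"""Phylum-level overrepresentation of HGT-contributing engrafted strains.

The contingency table compares, per phylum, the engrafted donor strains
against the engrafted strains that contributed transfer events. The omnibus
test is Pearson's chi-squared; per-cell post-hoc tests use standardized
(adjusted) residuals with two-sided normal p-values and Benjamini–Hochberg
control across all cells. The phylum distribution of donor genes on
high-quality MAGs serves as the background reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PhylumContingency:
    phyla: list[str]
    counts_engrafted: np.ndarray
    counts_engrafted_with_hgt: np.ndarray
    background_fractions: np.ndarray | None = None

    def table(self) -> np.ndarray:
        return np.column_stack([self.counts_engrafted, self.counts_engrafted_with_hgt])


@dataclass
class EnrichmentResult:
    chi2: float
    df: int
    p: float
    cells: pd.DataFrame  # phylum, column, observed, expected, residual, p, p_adj, direction


def chi_squared(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of homogeneity on a contingency table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError(
            "chi-squared undefined: a cell has zero expected count; pool sparse categories first"
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def posthoc_residuals(table: np.ndarray) -> pd.DataFrame:
    """Per-cell standardized residuals with BH-adjusted two-sided p-values.

    r = (O - E) / sqrt(E (1 - row_margin/n) (1 - col_margin/n)), which is
    approximately standard normal under homogeneity; two-sided p = 2 Phi(-|r|).
    """
    table = np.asarray(table, dtype=float)
    chi_squared(table)  # shares the validity checks
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    denom = np.sqrt(expected * (1 - row / n) * (1 - col / n))
    residual = (table - expected) / denom
    raw_p = 2 * stats.norm.sf(np.abs(residual))
    adj_p = bh_adjust(raw_p.ravel()).reshape(raw_p.shape)
    rows = []
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            rows.append(
                {
                    "row": i,
                    "col": j,
                    "observed": table[i, j],
                    "expected": expected[i, j],
                    "residual": residual[i, j],
                    "p": raw_p[i, j],
                    "p_adj": adj_p[i, j],
                    "direction": "over" if residual[i, j] > 0 else ("under" if residual[i, j] < 0 else "none"),
                }
            )
    return pd.DataFrame(rows)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def build_contingency(
    engraftment: pd.DataFrame,
    engraftment_events: pd.DataFrame,
    species_phylum: dict[str, str],
    sex_of: dict[str, str],
    sex: str,
    count_mode: str = "species",
    background: pd.Series | None = None,
    drop_empty: bool = True,
) -> PhylumContingency:
    """Assemble the per-phylum engrafted vs engrafted-with-HGT table.

    ``count_mode="species"`` counts distinct (recipient, species) engraftment
    instances; ``"events"`` weights the with-HGT column by transfer events.
    Phyla with zero counts in both columns are dropped (logged by caller).
    """
    eng = engraftment[engraftment["recipient_id"].map(sex_of) == sex]
    eng_units = eng.drop_duplicates(["recipient_id", "species"]).copy()
    missing = sorted(set(eng_units["species"]) - set(species_phylum))
    if missing:
        raise ValueError(f"engrafted species lacking phylum classification: {missing}")
    eng_units["phylum"] = eng_units["species"].map(species_phylum)
    engrafted_counts = eng_units.groupby("phylum").size()

    ev = engraftment_events[engraftment_events["sex"] == sex].copy()
    ev["phylum"] = ev["engrafted_species"].map(species_phylum)
    if count_mode == "species":
        hgt_units = ev.drop_duplicates(["recipient_id", "engrafted_species"])
        hgt_counts = hgt_units.groupby("phylum").size()
    elif count_mode == "events":
        hgt_counts = (
            ev.drop_duplicates(["recipient_id", "cluster_id", "recipient_gene_id", "engrafted_species"])
            .groupby("phylum")
            .size()
        )
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")

    phyla = sorted(set(engrafted_counts.index) | set(hgt_counts.index))
    a = np.array([engrafted_counts.get(ph, 0) for ph in phyla], dtype=float)
    b = np.array([hgt_counts.get(ph, 0) for ph in phyla], dtype=float)
    if drop_empty:
        keep = (a + b) > 0
        phyla = [ph for ph, k in zip(phyla, keep) if k]
        a, b = a[keep], b[keep]
    bg = None
    if background is not None:
        bg = np.array([background.get(ph, 0.0) for ph in phyla], dtype=float)
    return PhylumContingency(phyla, a, b, bg)


def enrichment_test(contingency: PhylumContingency) -> EnrichmentResult:
    table = contingency.table()
    chi2, df, p = chi_squared(table)
    cells = posthoc_residuals(table)
    cells["phylum"] = [contingency.phyla[i] for i in cells["row"]]
    cells["column"] = np.where(cells["col"] == 0, "engrafted", "engrafted_with_hgt")
    cells = cells[
        ["phylum", "column", "observed", "expected", "residual", "p", "p_adj", "direction"]
    ]
    return EnrichmentResult(chi2=chi2, df=df, p=p, cells=cells)


def background_distribution(analysable_genes: pd.DataFrame, bundle) -> pd.Series:
    """Phylum fractions of donor genes on high-quality, classified MAGs."""
    donors = set(bundle.donors()["subject_id"])
    samples = bundle.samples
    donor_samples = set(samples.loc[samples["subject_id"].isin(donors), "sample_id"])
    donor_genes = analysable_genes[analysable_genes["sample_id"].isin(donor_samples)]
    if not len(donor_genes):
        raise ValueError("no donor genes on high-quality MAGs; background undefined")
    frac = donor_genes.groupby("phylum").size() / len(donor_genes)
    return frac.sort_index()
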