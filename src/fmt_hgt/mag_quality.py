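"""High-quality MAG filtering and the analysable gene universe.

A MAG is high-quality iff completeness > 90 and contamination < 5, with both
inequalities strict: a bin at exactly 90% completeness (or exactly 5%
contamination) is excluded and logged. Genes are analysable iff they sit on a
high-quality MAG whose species classification resolved; genes on unclassified
bins are excluded and their count/fraction reported (the study-scale analogue
of this fraction is ~5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._util import percent

logger = logging.getLogger(__name__)

COMPLETENESS_MIN = 90.0  # strict ">"
CONTAMINATION_MAX = 5.0  # strict "<"


@dataclass(frozen=True)
class GeneFilterStats:
    n_genes_on_hq_mags: int
    n_excluded_unclassified: int
    excluded_unclassified_pct: float  # reported to 2 decimals
    n_analysable: int


def filter_high_quality(
    mags: pd.DataFrame,
    completeness_min: float = COMPLETENESS_MIN,
    contamination_max: float = CONTAMINATION_MAX,
) -> pd.DataFrame:
    """Return the high-quality subset of a MAG table (strict thresholds)."""
    if mags["completeness"].isna().any() or mags["contamination"].isna().any():
        bad = mags.loc[mags["completeness"].isna() | mags["contamination"].isna(), "mag_id"]
        raise ValueError(f"MAG quality values missing for {sorted(bad)[:10]}")
    keep = (mags["completeness"] > completeness_min) & (mags["contamination"] < contamination_max)
    boundary = mags.loc[
        (mags["completeness"] == completeness_min) | (mags["contamination"] == contamination_max),
        "mag_id",
    ]
    if len(boundary):
        logger.info("excluding %d boundary-value MAG(s): %s", len(boundary), list(boundary[:5]))
    return mags.loc[keep].reset_index(drop=True)


def analysable_genes(
    genes: pd.DataFrame, hq_mags: pd.DataFrame
) -> tuple[pd.DataFrame, GeneFilterStats]:
    """Genes on high-quality, species-classified MAGs.

    Returns the retained gene table (with the MAG's phylum/species merged in)
    and the exclusion statistics for unclassified-species bins.
    """
    merged = genes.merge(
        hq_mags[["mag_id", "phylum", "species", "species_classified"]],
        on="mag_id",
        how="inner",
    )
    n_on_hq = len(merged)
    classified = merged["species_classified"].astype(bool)
    kept = merged.loc[classified].drop(columns="species_classified").reset_index(drop=True)
    n_excluded = n_on_hq - len(kept)
    pct = percent(n_excluded, n_on_hq, 2) if n_on_hq else 0.0
    stats = GeneFilterStats(
        n_genes_on_hq_mags=n_on_hq,
        n_excluded_unclassified=n_excluded,
        excluded_unclassified_pct=pct,
        n_analysable=len(kept),
    )
    logger.info(
        "analysable genes: %d of %d on HQ MAGs (%s%% excluded as species-unclassified)",
        stats.n_analysable, n_on_hq, pct,
    )
    return kept, stats
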