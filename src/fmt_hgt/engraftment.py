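"""Engraftment-dependent HGT: restrict transfer events to those facilitated
by donor strains that engrafted, attribute them to donors, and build
species/phylum transfer matrices.

An event is engraftment-dependent when one of its donor-side occurrences has
a matching strain-engraftment call — same recipient, same donor species, at
week 6 — and that engrafted species differs from the recipient species (a
concordant occurrence is vertical persistence, not transfer). Matching is on
(recipient, species); the donor identity is reported from the engraftment
table, so an event facilitated by a species engrafted from two donors is
attributed to each donor but counted once in event totals.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd


def filter_engraftment_dependent(
    events: pd.DataFrame, engraftment: pd.DataFrame
) -> pd.DataFrame:
    """Subset the long-format event table to engraftment-dependent rows.

    Returns one row per distinct
    (recipient, cluster, recipient_gene, engrafted_species, engrafted_donor),
    carrying the original event columns plus ``engrafted_species`` and
    ``engrafted_donor_id``.
    """
    if not len(events):
        return events.assign(engrafted_species=pd.Series(dtype=str),
                             engrafted_donor_id=pd.Series(dtype=str))
    eng = engraftment[engraftment["timepoint"] == "week6"]
    merged = events.merge(
        eng[["recipient_id", "donor_id", "species"]].rename(
            columns={"species": "engrafted_species", "donor_id": "engrafted_donor_id"}
        ),
        left_on=["recipient_id", "donor_species"],
        right_on=["recipient_id", "engrafted_species"],
        how="inner",
    )
    merged = merged[merged["engrafted_species"] != merged["recipient_species"]]
    merged = merged.drop_duplicates(
        ["recipient_id", "cluster_id", "recipient_gene_id", "engrafted_species", "engrafted_donor_id"]
    )
    return merged.reset_index(drop=True)


def distinct_events(filtered: pd.DataFrame) -> pd.DataFrame:
    """Collapse the attribution view to one row per transfer event:
    (recipient, cluster, recipient_gene, engrafted_species)."""
    return filtered.drop_duplicates(
        ["recipient_id", "cluster_id", "recipient_gene_id", "engrafted_species"]
    ).reset_index(drop=True)


def donor_attribution(filtered: pd.DataFrame) -> pd.DataFrame:
    """Event counts per (donor, recipient) pair for alluvial-style output,
    with per-donor totals by sex. Counts sum to the number of
    (event, engrafted donor) pairings."""
    if not len(filtered):
        return pd.DataFrame(columns=["sex", "engrafted_donor_id", "recipient_id", "n_events"])
    counts = (
        filtered.groupby(["sex", "engrafted_donor_id", "recipient_id"])
        .size()
        .rename("n_events")
        .reset_index()
        .sort_values(["sex", "engrafted_donor_id", "recipient_id"])
        .reset_index(drop=True)
    )
    return counts


def species_pair_matrix(
    events: pd.DataFrame,
    species_phylum: Mapping[str, str],
) -> pd.DataFrame:
    """Event counts indexed by (engrafted donor species, recipient species),
    annotated with both phyla for phylum-grouped display.

    Every species must have a phylum, either from MAG taxonomy or from the
    manual fill-in lookup; missing ones raise with the full list.
    """
    ev = distinct_events(events)
    if not len(ev):
        return pd.DataFrame(
            columns=["donor_phylum", "engrafted_species", "recipient_phylum", "recipient_species", "n_events"]
        )
    involved = set(ev["engrafted_species"]) | set(ev["recipient_species"])
    missing = sorted(s for s in involved if s not in species_phylum)
    if missing:
        raise ValueError(
            f"species lacking phylum classification (supply a manual lookup): {missing}"
        )
    counts = (
        ev.groupby(["engrafted_species", "recipient_species"]).size().rename("n_events").reset_index()
    )
    counts["donor_phylum"] = counts["engrafted_species"].map(species_phylum)
    counts["recipient_phylum"] = counts["recipient_species"].map(species_phylum)
    counts = counts[
        ["donor_phylum", "engrafted_species", "recipient_phylum", "recipient_species", "n_events"]
    ].sort_values(["donor_phylum", "engrafted_species", "recipient_phylum", "recipient_species"])
    return counts.reset_index(drop=True)
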