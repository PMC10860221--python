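"""Thin readers for common upstream-tool output dialects.

Each adapter converts one external format into (part of) the canonical
schema; none of them runs the upstream tool. They exist so that real CheckM /
GTDB-Tk / cd-hit / eggNOG-mapper / taxonomic-discordance outputs can be
dropped into the pipeline without hand-editing headers.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd


def read_checkm_quality(path: Path) -> pd.DataFrame:
    """CheckM-style quality TSV (columns ``Bin Id``, ``Completeness``,
    ``Contamination``) -> mag_id/completeness/contamination frame."""
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "mag_id": df["Bin Id"].astype(str),
            "completeness": df["Completeness"].astype(float),
            "contamination": df["Contamination"].astype(float),
        }
    )


def _parse_gtdb_classification(s: str) -> tuple[str, str, bool]:
    phylum = species = ""
    m = re.search(r"p__([^;]*)", s)
    if m:
        phylum = m.group(1).strip()
    m = re.search(r"s__([^;]*)", s)
    if m:
        species = m.group(1).strip()
    return phylum, species, bool(species)


def read_gtdbtk_summary(path: Path) -> pd.DataFrame:
    """GTDB-Tk summary TSV (``user_genome``, ``classification``) ->
    mag_id/phylum/species/species_classified frame. An empty ``s__`` field
    becomes species_classified=False rather than a sentinel string."""
    df = pd.read_csv(path, sep="\t")
    parsed = [_parse_gtdb_classification(str(c)) for c in df["classification"]]
    out = pd.DataFrame(parsed, columns=["phylum", "species", "species_classified"])
    out.insert(0, "mag_id", df["user_genome"].astype(str))
    return out


def read_cdhit_clstr(path: Path) -> pd.DataFrame:
    """cd-hit ``.clstr`` text format -> (gene_id, cluster_id) frame.

    Cluster ids are taken from the ``>Cluster N`` headers as ``cluster_N``.
    """
    rows: list[tuple[str, str]] = []
    cluster = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">Cluster"):
            cluster = "cluster_" + line.split()[1]
        elif line.strip():
            m = re.search(r">(\S+?)\.\.\.", line)
            if m is None or cluster is None:
                raise ValueError(f"unparseable .clstr line: {line!r}")
            rows.append((m.group(1), cluster))
    return pd.DataFrame(rows, columns=["gene_id", "cluster_id"])


def read_eggnog_annotations(path: Path) -> pd.DataFrame:
    """eggNOG-mapper annotations TSV (``query``/``#query``, ``COG_category``)
    -> (cluster_id, categories). '-' and NA become the empty string."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None if _headerless(path) else 0)
    if isinstance(df.columns[0], int):
        df.columns = ["query", "COG_category"] + [f"col{i}" for i in range(2, df.shape[1])]
    query_col = "#query" if "#query" in df.columns else "query"
    cats = df["COG_category"].fillna("").astype(str).str.replace("-", "", regex=False)
    return pd.DataFrame({"cluster_id": df[query_col].astype(str), "categories": cats})


def _headerless(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "COG_category" not in line
    return True


def read_waafle_counts(sample_calls: Iterable[tuple[str, Path, Path]],
                       richness: dict[str, int]) -> pd.DataFrame:
    """Per-sample taxonomic-discordance caller outputs -> waafle table.

    ``sample_calls`` yields (sample_id, hgt_contigs_tsv, no_hgt_contigs_tsv);
    each TSV has one row per contig. ``richness`` maps sample_id to its
    species count (from an upstream profiler).
    """
    rows = []
    for sample_id, hgt_path, clean_path in sample_calls:
        n_hgt = max(0, sum(1 for _ in open(hgt_path)) - 1)
        n_clean = max(0, sum(1 for _ in open(clean_path)) - 1)
        rows.append(
            {
                "sample_id": sample_id,
                "n_hgt_contigs": n_hgt,
                "n_contigs": n_hgt + n_clean,
                "species_richness": richness[sample_id],
            }
        )
    return pd.DataFrame(rows)
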