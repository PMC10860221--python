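"""Canonical tabular schema for the trial bundle, with validation and TSV I/O.

A *bundle* collects every per-sample summary table the pipeline consumes:
trial design (subjects, samples, donor assignment), MAG quality and taxonomy,
gene → MAG → cluster membership, strain-engraftment calls, cluster-level
abundances (copies per million reads), per-sample taxonomic-discordance HGT
contig counts with species richness, and COG annotations.

All tables are tab-separated with snake_case headers. Validation is total: it
collects *every* failing row across all invariants before raising, so a bad
bundle reports all of its problems at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Iterator, Mapping

import pandas as pd

from ._util import read_tsv, write_tsv

TIMEPOINTS = ("baseline", "week6", "week12", "week26")
ROLES = ("donor", "recipient")
ARMS = ("FMT", "placebo", "none")
SEXES = ("female", "male")
COG_ALPHABET = set("ABCDEFGHIJKLMNOPQRSTUVWYZ")

#: column name -> dtype, per table
COLUMNS: dict[str, dict[str, type]] = {
    "subjects": {"subject_id": str, "role": str, "arm": str, "sex": str},
    "samples": {"sample_id": str, "subject_id": str, "timepoint": str},
    "donor_assignment": {"recipient_id": str, "donor_id": str},
    "mags": {
        "mag_id": str,
        "sample_id": str,
        "completeness": float,
        "contamination": float,
        "phylum": str,
        "species": str,
        "species_classified": bool,
    },
    "genes": {"gene_id": str, "mag_id": str, "sample_id": str, "cluster_id": str},
    "engraftment": {"recipient_id": str, "donor_id": str, "species": str, "timepoint": str},
    "abundance": {"cluster_id": str, "sample_id": str, "cpm": float},
    "waafle": {
        "sample_id": str,
        "n_hgt_contigs": int,
        "n_contigs": int,
        "species_richness": int,
    },
    "cog": {"cluster_id": str, "categories": str},
}

OPTIONAL_TABLES = ("donor_assignment", "engraftment", "abundance", "waafle", "cog")


class ValidationError(ValueError):
    """Raised when a bundle violates its schema; carries every failing check."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "\n  ".join(errors[:25])
        more = f"\n  ... and {len(errors) - 25} more" if len(errors) > 25 else ""
        super().__init__(f"{len(errors)} validation error(s):\n  {preview}{more}")


def _empty(table: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=(object if t in (str, bool) else t))
                         for c, t in COLUMNS[table].items()})


@dataclass
class Bundle:
    """In-memory trial bundle: one DataFrame per canonical table."""

    subjects: pd.DataFrame
    samples: pd.DataFrame
    mags: pd.DataFrame
    genes: pd.DataFrame
    donor_assignment: pd.DataFrame = field(default_factory=lambda: _empty("donor_assignment"))
    engraftment: pd.DataFrame = field(default_factory=lambda: _empty("engraftment"))
    abundance: pd.DataFrame = field(default_factory=lambda: _empty("abundance"))
    waafle: pd.DataFrame = field(default_factory=lambda: _empty("waafle"))
    cog: pd.DataFrame = field(default_factory=lambda: _empty("cog"))

    def tables(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for f in fields(self):
            yield f.name, getattr(self, f.name)

    def species_phylum(self, manual: Mapping[str, str] | None = None) -> dict[str, str]:
        """species -> phylum lookup from MAG taxonomy, optionally extended by a
        manual fill-in table (mirrors curating phyla for species absent from
        the MAG classification)."""
        classified = self.mags[self.mags["species_classified"].astype(bool)]
        lookup = dict(zip(classified["species"], classified["phylum"]))
        if manual:
            lookup.update(manual)
        return lookup

    def recipients(self) -> pd.DataFrame:
        return self.subjects[self.subjects["role"] == "recipient"]

    def donors(self) -> pd.DataFrame:
        return self.subjects[self.subjects["role"] == "donor"]


def _check_columns(name: str, df: pd.DataFrame, errors: list[str]) -> bool:
    missing = [c for c in COLUMNS[name] if c not in df.columns]
    if missing:
        errors.append(f"{name}: missing column(s) {missing}")
        return False
    return True


def validate(bundle: Bundle) -> None:
    """Check schema, enum, uniqueness and cross-reference invariants.

    Every failing row is reported (by id), not just the first.
    """
    errors: list[str] = []
    ok = {name: _check_columns(name, df, errors) for name, df in bundle.tables()}
    if not all(ok.values()):
        raise ValidationError(errors)

    subj = bundle.subjects
    dup = subj["subject_id"][subj["subject_id"].duplicated()]
    if len(dup):
        errors.append(f"subjects: duplicate subject_id {sorted(dup)}")
    bad_role = subj.loc[~subj["role"].isin(ROLES), "subject_id"]
    if len(bad_role):
        errors.append(f"subjects: invalid role for {sorted(bad_role)}")
    bad_sex = subj.loc[~subj["sex"].isin(SEXES), "subject_id"]
    if len(bad_sex):
        errors.append(f"subjects: invalid sex for {sorted(bad_sex)}")
    # arm is defined iff role is recipient; donors carry the explicit "none"
    bad_arm = subj.loc[
        ((subj["role"] == "recipient") & ~subj["arm"].isin(("FMT", "placebo")))
        | ((subj["role"] == "donor") & (subj["arm"] != "none")),
        "subject_id",
    ]
    if len(bad_arm):
        errors.append(f"subjects: arm inconsistent with role for {sorted(bad_arm)}")

    samples = bundle.samples
    dup = samples["sample_id"][samples["sample_id"].duplicated()]
    if len(dup):
        errors.append(f"samples: duplicate sample_id {sorted(dup)}")
    known = set(subj["subject_id"])
    dangling = samples.loc[~samples["subject_id"].isin(known), "sample_id"]
    if len(dangling):
        errors.append(f"samples: subject_id not in subjects for sample(s) {sorted(dangling)}")

    sex_of = dict(zip(subj["subject_id"], subj["sex"]))
    role_of = dict(zip(subj["subject_id"], subj["role"]))
    arm_of = dict(zip(subj["subject_id"], subj["arm"]))

    merged = samples.merge(subj, on="subject_id", how="inner")
    rec_tp = merged[merged["role"] == "recipient"].groupby("subject_id")["timepoint"].agg(set)
    for rid in subj.loc[subj["role"] == "recipient", "subject_id"]:
        tps = rec_tp.get(rid, set())
        for required in ("baseline", "week6"):
            if required not in tps:
                errors.append(f"samples: recipient {rid} lacks a {required} sample")
        unknown = tps - set(TIMEPOINTS)
        if unknown:
            errors.append(f"samples: recipient {rid} has invalid timepoint(s) {sorted(unknown)}")
    donor_counts = merged[merged["role"] == "donor"].groupby("subject_id").size()
    for did in subj.loc[subj["role"] == "donor", "subject_id"]:
        if donor_counts.get(did, 0) < 1:
            errors.append(f"samples: donor {did} has no samples")

    da = bundle.donor_assignment
    if len(da):
        for _, row in da.iterrows():
            r, d = row["recipient_id"], row["donor_id"]
            if role_of.get(r) != "recipient" or role_of.get(d) != "donor":
                errors.append(f"donor_assignment: ({r}, {d}) roles do not resolve")
            elif sex_of[r] != sex_of[d]:
                errors.append(f"donor_assignment: donor {d} not sex-matched to recipient {r}")

    mags = bundle.mags
    dup = mags["mag_id"][mags["mag_id"].duplicated()]
    if len(dup):
        errors.append(f"mags: duplicate mag_id {sorted(dup)[:10]}")
    if mags["completeness"].isna().any() or mags["contamination"].isna().any():
        bad = mags.loc[mags["completeness"].isna() | mags["contamination"].isna(), "mag_id"]
        errors.append(f"mags: missing quality values for {sorted(bad)[:10]}")
    else:
        bad = mags.loc[
            (mags["completeness"] < 0) | (mags["completeness"] > 100) | (mags["contamination"] < 0),
            "mag_id",
        ]
        if len(bad):
            errors.append(f"mags: quality values out of range for {sorted(bad)[:10]}")
    known_samples = set(samples["sample_id"])
    dangling = mags.loc[~mags["sample_id"].isin(known_samples), "mag_id"]
    if len(dangling):
        errors.append(f"mags: sample_id not in samples for MAG(s) {sorted(dangling)[:10]}")

    genes = bundle.genes
    empty_cluster = genes.loc[genes["cluster_id"].astype(str) == "", "gene_id"]
    if len(empty_cluster):
        errors.append(f"genes: empty cluster_id for {sorted(empty_cluster)[:10]}")
    # a gene's MAG must exist, and in the same sample as the gene
    mag_sample = dict(zip(mags["mag_id"], mags["sample_id"]))
    gm = genes["mag_id"].map(mag_sample)
    dangling = genes.loc[gm.isna(), "gene_id"]
    if len(dangling):
        errors.append(f"genes: mag_id does not resolve for gene(s) {sorted(dangling)[:10]}")
    mismatched = genes.loc[gm.notna() & (gm != genes["sample_id"]), "gene_id"]
    if len(mismatched):
        errors.append(f"genes: MAG belongs to a different sample for gene(s) {sorted(mismatched)[:10]}")

    eng = bundle.engraftment
    for _, row in eng.iterrows():
        r, d = row["recipient_id"], row["donor_id"]
        if arm_of.get(r) != "FMT":
            errors.append(f"engraftment: recipient {r} is not in the FMT arm")
        if role_of.get(d) != "donor" or sex_of.get(d) != sex_of.get(r):
            errors.append(f"engraftment: donor {d} not a sex-matched donor for {r}")
        if row["timepoint"] != "week6":
            errors.append(f"engraftment: ({r}, {row['species']}) has timepoint {row['timepoint']!r}, expected week6")

    ab = bundle.abundance
    if len(ab):
        if (ab["cpm"] < 0).any():
            bad = ab.loc[ab["cpm"] < 0, "cluster_id"]
            errors.append(f"abundance: negative cpm for cluster(s) {sorted(set(bad))[:10]}")
        dup = ab[ab.duplicated(["cluster_id", "sample_id"])]
        if len(dup):
            errors.append(
                "abundance: duplicate (cluster_id, sample_id) pairs "
                f"{sorted(set(zip(dup['cluster_id'], dup['sample_id'])))[:10]}"
            )

    wf = bundle.waafle
    if len(wf):
        bad = wf.loc[wf["n_hgt_contigs"] > wf["n_contigs"], "sample_id"]
        if len(bad):
            errors.append(f"waafle: n_hgt_contigs > n_contigs for sample(s) {sorted(bad)[:10]}")
        bad = wf.loc[(wf["n_contigs"] <= 0) | (wf["species_richness"] <= 0), "sample_id"]
        if len(bad):
            errors.append(f"waafle: non-positive n_contigs/species_richness for {sorted(bad)[:10]}")

    cog = bundle.cog
    for _, row in cog.iterrows():
        letters = set(str(row["categories"]))
        unknown = letters - COG_ALPHABET
        if unknown:
            errors.append(f"cog: cluster {row['cluster_id']} has unknown letter(s) {sorted(unknown)}")

    if errors:
        raise ValidationError(errors)


def read_tables(paths: Mapping[str, Path] | str | Path, check: bool = True) -> Bundle:
    """Load a bundle from a table-name → path mapping, or a directory holding
    ``<table>.tsv`` files. Optional tables may be absent."""
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = {name: root / f"{name}.tsv" for name in COLUMNS
                 if (root / f"{name}.tsv").exists()}
    frames: dict[str, pd.DataFrame] = {}
    for name in COLUMNS:
        if name in paths:
            df = read_tsv(Path(paths[name]), COLUMNS[name])
            missing = [c for c in COLUMNS[name] if c not in df.columns]
            if missing:
                raise ValidationError([f"{name}: missing column(s) {missing}"])
            frames[name] = df[list(COLUMNS[name])]
        elif name in OPTIONAL_TABLES:
            frames[name] = _empty(name)
        else:
            raise ValidationError([f"required table {name!r} not provided"])
    bundle = Bundle(**frames)
    if check:
        validate(bundle)
    return bundle


def write_bundle(bundle: Bundle, out_dir: Path, meta: Mapping[str, Any] | None = None) -> None:
    """Write every table as ``<name>.tsv`` under ``out_dir`` (deterministic
    column order; metadata header lines are skipped on read)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables():
        cols = list(COLUMNS[name])
        write_tsv(df[cols] if len(df) else _empty(name), out / f"{name}.tsv", meta)


def write_results(
    results: Mapping[str, pd.DataFrame],
    out_dir: Path,
    version: str,
    cfg_hash: str,
    summary: Mapping[str, Any] | None = None,
) -> None:
    """Write result tables as TSV plus a JSON run summary.

    Every table carries the pipeline version and the configuration hash in
    ``#``-prefixed header lines.
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"pipeline_version": version, "config_hash": cfg_hash}
    for name, df in results.items():
        write_tsv(df, out / f"{name}.tsv", meta)
    if summary is not None:
        payload = {"pipeline_version": version, "config_hash": cfg_hash, **summary}
        (out / "run_summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
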