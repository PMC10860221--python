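"""Synthetic FMT trial generator with planted ground truth.

The generator emulates the structure of a two-arm, sex-matched,
placebo-controlled FMT trial: donors sampled over repeated donations,
recipients sampled at baseline and weeks 6/12/26, species with a realistic
phylum mixture, per-species gene clusters, donor-specific strain
engraftment, engraftment-dependent gene transfers, arm-independent
background cluster acquisition from an environmental pool overlapping the
donor pool, retention of transferred clusters through weeks 12/26, and
per-sample contig-level HGT counts with a planted longitudinal drift.

Design notes
------------
* Species influx at week 6 is symmetric across arms: every recipient gains
  new species from the sex-matched donor-cohort pool at the same rate. In
  the FMT arm an influx species matching an assigned donor is recorded as a
  strain engraftment; in the placebo arm the same influx is environmental
  and unrecorded. This keeps HTGC frequencies arm-null while still planting
  engraftment-dependent transfers only where engraftment was observed.
* Planted acquisitions (background and engraftment-dependent) satisfy the
  detection criteria by construction, and nothing else does: species' core
  clusters are unique to the species, resident clusters persist from
  baseline, and influx species appear with concordant taxonomy only. Under
  the default sex-cohort donor scope, detection therefore recovers exactly
  the planted set.
* One random-number stream per generated table, all spawned from the master
  seed, so adding a table never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import Bundle, COLUMNS

_STREAMS = (
    "species", "donors", "recipients", "influx", "transfers",
    "background", "cog", "abundance", "assembly", "waafle",
)

COG_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWYZ"


def _default_phylum_weights() -> dict[str, float]:
    # high-quality MAG phylum mixture of a western gut cohort
    return {
        "Firmicutes": 0.682,
        "Bacteroidetes": 0.218,
        "Actinobacteria": 0.042,
        "Proteobacteria": 0.058,
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic trial. See docs/methods.md for the
    reasoning behind each default."""

    seed: int = 0
    # trial design
    n_donors_female: int = 4
    n_donors_male: int = 5
    n_recipients_per_arm_per_sex: int = 22
    n_donations_per_donor: int = 6
    # community structure
    n_species: int = 80
    phylum_weights: dict[str, float] = field(default_factory=_default_phylum_weights)
    n_clusters_per_species: int = 5
    n_species_per_donor: int = 30
    n_resident_species: int = 25
    # acquisition processes
    background_acquisition_rate: float = 0.30
    background_overdispersion_sigma: float = 0.30
    engraftment_rate: float = 0.15
    bacteroidetes_engraftment_bias: float = 2.5
    transfer_rate_given_engraftment: float = 0.01
    bacteroidetes_hgt_multiplier: float = 6.0
    dominant_donor_weight: float = 3.0
    # retention and abundance
    retention_prob_week12: float = 0.858
    retention_prob_week26: float = 0.803
    cpm_lognormal_mu: float = 3.0
    cpm_lognormal_sigma: float = 1.0
    functional_shift_week26: float = 0.0
    # contig-level HGT counts
    drift_effect_week26: float = 0.37
    waafle_base_rate: float = 1.2
    waafle_subject_sd: float = 0.25
    waafle_noise_sd: float = 0.30
    mean_species_richness: float = 120.0
    richness_sd: float = 20.0
    mean_contigs: float = 96000.0
    contigs_sd: float = 15000.0
    # assembly decoys
    hq_mag_fraction: float = 0.20
    unclassified_gene_fraction: float = 0.0523
    # annotation
    cog_unannotated_prob: float = 0.19
    cog_second_letter_prob: float = 0.25

    def __post_init__(self) -> None:
        if self.n_donors_female < 1 or self.n_donors_male < 1:
            raise ValueError("need at least one donor per sex")
        if self.n_recipients_per_arm_per_sex < 1:
            raise ValueError("need at least one recipient per arm per sex")
        total = sum(self.phylum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phylum_weights must sum to 1 (got {total})")
        for name in (
            "background_acquisition_rate", "engraftment_rate",
            "transfer_rate_given_engraftment", "retention_prob_week12",
            "retention_prob_week26", "cog_unannotated_prob",
            "cog_second_letter_prob", "unclassified_gene_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1] (got {v})")
        if not 0.0 < self.hq_mag_fraction <= 1.0:
            raise ValueError("hq_mag_fraction must lie in (0, 1]")
        if self.bacteroidetes_hgt_multiplier < 1.0:
            raise ValueError("bacteroidetes_hgt_multiplier must be >= 1")
        if self.n_species_per_donor > self.n_species or self.n_resident_species > self.n_species:
            raise ValueError("per-subject species counts cannot exceed n_species")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth labels for recovery tests.

    ``planted`` has one row per planted HTGC unit: recipient_id, cluster_id,
    donor_id, donor_species, recipient_species, engraftment_dependent,
    retained_week12, retained_week26.
    """

    planted: pd.DataFrame
    engraftments: pd.DataFrame

    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.planted["recipient_id"], self.planted["cluster_id"]))

    def engraftment_dependent(self) -> pd.DataFrame:
        return self.planted[self.planted["engraftment_dependent"]].reset_index(drop=True)

    def retained_at(self) -> dict[tuple[str, str], set[str]]:
        out: dict[tuple[str, str], set[str]] = {}
        for r in self.planted.itertuples():
            tps = {"week6"}
            if r.retained_week12:
                tps.add("week12")
            if r.retained_week26:
                tps.add("week26")
            out[(r.recipient_id, r.cluster_id)] = tps
        return out


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def simulate(config: SimConfig) -> tuple[Bundle, GroundTruth]:
    """Generate a complete trial bundle plus its planted ground truth."""
    rng = _rngs(config.seed)

    # --- species universe -------------------------------------------------
    phyla = list(config.phylum_weights)
    weights = np.array([config.phylum_weights[p] for p in phyla])
    species = [f"s{i:04d}" for i in range(config.n_species)]
    sp_phylum = dict(zip(species, rng["species"].choice(phyla, size=config.n_species, p=weights)))
    clusters_of = {
        s: [f"c{i:04d}_{k}" for k in range(config.n_clusters_per_species)]
        for i, s in enumerate(species)
    }
    cluster_species = {c: s for s, cs in clusters_of.items() for c in cs}

    # --- subjects and samples --------------------------------------------
    subjects, samples = [], []
    donors_by_sex: dict[str, list[str]] = {"female": [], "male": []}
    donor_species: dict[str, list[str]] = {}
    donor_weight: dict[str, float] = {}
    for sex, n, tag in (("female", config.n_donors_female, "DF"), ("male", config.n_donors_male, "DM")):
        for i in range(n):
            did = f"{tag}{i + 1:02d}"
            donors_by_sex[sex].append(did)
            subjects.append((did, "donor", "none", sex))
            # the first donor of each sex is the dominant one: a broader strain
            # repertoire (hence more engraftment) and a heavier attribution
            # weight when several assigned donors carry an engrafted species
            n_sp = config.n_species_per_donor
            if i == 0:
                n_sp = min(config.n_species, int(round(1.5 * n_sp)))
            donor_species[did] = sorted(
                np.array(species)[rng["donors"].choice(config.n_species, n_sp, replace=False)]
            )
            donor_weight[did] = config.dominant_donor_weight if i == 0 else 1.0
            for j in range(config.n_donations_per_donor):
                samples.append((f"{did}_d{j + 1}", did, f"donation_{j + 1}"))

    recipients: list[str] = []
    rec_sex: dict[str, str] = {}
    rec_arm: dict[str, str] = {}
    residents: dict[str, list[str]] = {}
    assignment_rows = []
    for sex, tag in (("female", "RF"), ("male", "RM")):
        cohort = donors_by_sex[sex]
        idx = 0
        for arm in ("FMT", "placebo"):
            for _ in range(config.n_recipients_per_arm_per_sex):
                idx += 1
                rid = f"{tag}{idx:03d}"
                recipients.append(rid)
                rec_sex[rid], rec_arm[rid] = sex, arm
                subjects.append((rid, "recipient", arm, sex))
                for tp, suffix in (("baseline", "t0"), ("week6", "t6"), ("week12", "t12"), ("week26", "t26")):
                    samples.append((f"{rid}_{suffix}", rid, tp))
                residents[rid] = sorted(
                    np.array(species)[rng["recipients"].choice(config.n_species, config.n_resident_species, replace=False)]
                )
                assigned = (
                    sorted(np.array(cohort)[rng["recipients"].choice(len(cohort), 4, replace=False)])
                    if len(cohort) > 4 else list(cohort)
                )
                for did in assigned:
                    assignment_rows.append((rid, did))

    assigned_of: dict[str, list[str]] = {}
    for rid, did in assignment_rows:
        assigned_of.setdefault(rid, []).append(did)

    cohort_species: dict[str, list[str]] = {
        sex: sorted(set().union(*(donor_species[d] for d in ds)))
        for sex, ds in donors_by_sex.items()
    }

    # --- week-6 species influx (symmetric) + engraftment records ----------
    influx: dict[str, list[str]] = {}
    engraft_rows = []
    for rid in recipients:
        sex = rec_sex[rid]
        candidates = [s for s in cohort_species[sex] if s not in set(residents[rid])]
        probs = np.array([
            min(0.99, config.engraftment_rate * (config.bacteroidetes_engraftment_bias
                                                 if sp_phylum[s] == "Bacteroidetes" else 1.0))
            for s in candidates
        ])
        mask = rng["influx"].random(len(candidates)) < probs
        gained = [s for s, m in zip(candidates, mask) if m]
        influx[rid] = gained
        if rec_arm[rid] == "FMT":
            for s in gained:
                carriers = [d for d in assigned_of[rid] if s in set(donor_species[d])]
                if not carriers:
                    continue  # environmental influx, no engraftment call
                w = np.array([donor_weight[d] for d in carriers])
                donor = carriers[int(rng["influx"].choice(len(carriers), p=w / w.sum()))]
                engraft_rows.append((rid, donor, s, "week6"))

    engraftment_df = pd.DataFrame(engraft_rows, columns=list(COLUMNS["engraftment"]))
    engrafted_of: dict[str, dict[str, str]] = {}
    for rid, did, s, _ in engraft_rows:
        engrafted_of.setdefault(rid, {})[s] = did

    # --- engraftment-dependent transfers ----------------------------------
    planted_rows = []  # recipient, cluster, donor, donor_species, recipient_species, dependent
    for rid in recipients:
        for s, did in engrafted_of.get(rid, {}).items():
            p = config.transfer_rate_given_engraftment * (
                config.bacteroidetes_hgt_multiplier if sp_phylum[s] == "Bacteroidetes" else 1.0
            )
            p = min(1.0, p)
            for c in clusters_of[s]:
                if rng["transfers"].random() < p:
                    host = residents[rid][int(rng["transfers"].integers(len(residents[rid])))]
                    planted_rows.append((rid, c, did, s, host, True))

    # --- background acquisition (arm-independent) -------------------------
    for rid in recipients:
        sex = rec_sex[rid]
        excluded = set(residents[rid]) | set(influx[rid])
        pool = [c for s in cohort_species[sex] if s not in excluded for c in clusters_of[s]]
        f = float(np.exp(rng["background"].normal(0.0, config.background_overdispersion_sigma)))
        p = min(1.0, config.background_acquisition_rate * f)
        mask = rng["background"].random(len(pool)) < p
        for c, m in zip(pool, mask):
            if not m:
                continue
            s = cluster_species[c]
            host = residents[rid][int(rng["background"].integers(len(residents[rid])))]
            carriers = [d for d in donors_by_sex[sex] if s in set(donor_species[d])]
            donor = carriers[int(rng["background"].integers(len(carriers)))]
            planted_rows.append((rid, c, donor, s, host, False))

    planted = pd.DataFrame(
        planted_rows,
        columns=["recipient_id", "cluster_id", "donor_id", "donor_species",
                 "recipient_species", "engraftment_dependent"],
    )

    # --- COG annotations ---------------------------------------------------
    letters = list(COG_LETTERS)
    lw = np.full(len(letters), np.nan)
    lw[letters.index("S")] = 0.18
    lw[letters.index("R")] = 0.10
    rest = np.isnan(lw)
    lw[rest] = (1.0 - 0.28) / rest.sum()
    cog_rows = []
    for s in species:
        for c in clusters_of[s]:
            if rng["cog"].random() < config.cog_unannotated_prob:
                cats = ""
            else:
                first = letters[int(rng["cog"].choice(len(letters), p=lw))]
                cats = first
                if rng["cog"].random() < config.cog_second_letter_prob:
                    second = letters[int(rng["cog"].choice(len(letters), p=lw))]
                    if second != first:
                        cats = "".join(sorted(first + second))
            cog_rows.append((c, cats))
    cog_df = pd.DataFrame(cog_rows, columns=["cluster_id", "categories"])
    cluster_cats = dict(cog_rows)

    # --- genes and MAGs ----------------------------------------------------
    from .functional import METABOLISM  # letters of the metabolism class

    mag_rows: list[tuple] = []
    gene_rows: list[tuple] = []
    gene_counter = 0

    def new_gene_ids(n: int) -> list[str]:
        nonlocal gene_counter
        ids = [f"g{gene_counter + i:08d}" for i in range(n)]
        gene_counter += n
        return ids

    def add_species_mag(sample_id: str, s: str, extra_clusters: list[str] | None = None) -> None:
        nonlocal mag_rows, gene_rows
        mag_id = f"{sample_id}|{s}"
        comp = 91.0 + 8.0 * rng["assembly"].random()
        cont = 4.0 * rng["assembly"].random()
        mag_rows.append((mag_id, sample_id, round(comp, 2), round(cont, 2),
                         sp_phylum[s], s, True))
        cs = clusters_of[s] + (extra_clusters or [])
        for gid, c in zip(new_gene_ids(len(cs)), cs):
            gene_rows.append((gid, mag_id, sample_id, c))

    def add_decoys(sample_id: str, n_classified_genes: int, n_hq_mags: int) -> None:
        nonlocal mag_rows, gene_rows
        uf = config.unclassified_gene_fraction
        n_uncls = int(round(uf / (1.0 - uf) * n_classified_genes)) if uf > 0 else 0
        n_hq = n_hq_mags
        if n_uncls > 0:
            mag_id = f"{sample_id}|unclassified"
            comp = 91.0 + 8.0 * rng["assembly"].random()
            cont = 4.0 * rng["assembly"].random()
            mag_rows.append((mag_id, sample_id, round(comp, 2), round(cont, 2), "", "", False))
            for i, gid in enumerate(new_gene_ids(n_uncls)):
                gene_rows.append((gid, mag_id, sample_id, f"u_{sample_id}_{i}"))
            n_hq += 1
        if config.hq_mag_fraction < 1.0:
            n_lowq = int(round(n_hq * (1.0 - config.hq_mag_fraction) / config.hq_mag_fraction))
            comps = 40.0 + 50.0 * rng["assembly"].random(n_lowq)
            conts = 30.0 * rng["assembly"].random(n_lowq)
            gids = new_gene_ids(n_lowq)
            for i in range(n_lowq):
                mag_id = f"{sample_id}|lq{i}"
                s_idx = int(rng["assembly"].integers(config.n_species))
                mag_rows.append((mag_id, sample_id, round(comps[i], 2), round(conts[i], 2),
                                 sp_phylum[species[s_idx]], species[s_idx], True))
                gene_rows.append((gids[i], mag_id, sample_id, f"lq_{sample_id}_{i}"))

    planted_by_rid: dict[str, list[tuple[str, str]]] = {}
    for r in planted.itertuples():
        planted_by_rid.setdefault(r.recipient_id, []).append((r.cluster_id, r.recipient_species))

    for did in donor_species:
        for j in range(config.n_donations_per_donor):
            sid = f"{did}_d{j + 1}"
            for s in donor_species[did]:
                add_species_mag(sid, s)
            add_decoys(sid, len(donor_species[did]) * config.n_clusters_per_species,
                       len(donor_species[did]))

    for rid in recipients:
        res = residents[rid]
        # baseline, week12, week26: resident community only
        for suffix in ("t0", "t12", "t26"):
            sid = f"{rid}_{suffix}"
            for s in res:
                add_species_mag(sid, s)
            add_decoys(sid, len(res) * config.n_clusters_per_species, len(res))
        # week6: residents + influx species + planted acquisitions on hosts
        sid = f"{rid}_t6"
        extra: dict[str, list[str]] = {}
        for c, host in planted_by_rid.get(rid, []):
            extra.setdefault(host, []).append(c)
        n_extra = sum(len(v) for v in extra.values())
        for s in res:
            add_species_mag(sid, s, extra.get(s))
        for s in influx[rid]:
            add_species_mag(sid, s)
        n_cls = (len(res) + len(influx[rid])) * config.n_clusters_per_species + n_extra
        add_decoys(sid, n_cls, len(res) + len(influx[rid]))

    # --- abundance and retention ------------------------------------------
    metabolic = {
        c for c, cats in cluster_cats.items() if set(cats) & METABOLISM
    }
    tp_suffix = {"week6": "t6", "week12": "t12", "week26": "t26"}
    ab_rows = []
    retained12, retained26 = [], []
    for r in planted.itertuples():
        keep12 = bool(rng["abundance"].random() < config.retention_prob_week12)
        keep26 = bool(rng["abundance"].random() < config.retention_prob_week26)
        retained12.append(keep12)
        retained26.append(keep26)
        for tp, keep in (("week6", True), ("week12", keep12), ("week26", keep26)):
            cpm = 0.0
            if keep:
                cpm = float(np.exp(rng["abundance"].normal(config.cpm_lognormal_mu,
                                                           config.cpm_lognormal_sigma)))
                if tp == "week26" and config.functional_shift_week26 and r.cluster_id in metabolic:
                    cpm *= 1.0 + config.functional_shift_week26
            ab_rows.append((r.cluster_id, f"{r.recipient_id}_{tp_suffix[tp]}", round(cpm, 4)))
    planted = planted.assign(retained_week12=retained12, retained_week26=retained26)

    subjects_df = pd.DataFrame(subjects, columns=list(COLUMNS["subjects"]))
    samples_df = pd.DataFrame(samples, columns=list(COLUMNS["samples"]))
    bundle = Bundle(
        subjects=subjects_df,
        samples=samples_df,
        mags=pd.DataFrame(mag_rows, columns=list(COLUMNS["mags"])),
        genes=pd.DataFrame(gene_rows, columns=list(COLUMNS["genes"])),
        donor_assignment=pd.DataFrame(assignment_rows, columns=list(COLUMNS["donor_assignment"])),
        engraftment=engraftment_df,
        abundance=pd.DataFrame(ab_rows, columns=list(COLUMNS["abundance"])),
        cog=cog_df,
    )
    bundle.waafle = simulate_waafle_counts(config, bundle, rng=rng["waafle"])
    truth = GroundTruth(planted=planted, engraftments=engraftment_df.copy())
    return bundle, truth


def simulate_waafle_counts(
    config: SimConfig,
    bundle: Bundle,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample contig-level HGT counts with richness-correlated events,
    no arm effect, and an additive week-26 drift on the normalized scale."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed if seed is None else seed))
    subject_effect = {
        sid: float(rng.normal(0.0, config.waafle_subject_sd))
        for sid in bundle.subjects["subject_id"]
    }
    rows = []
    for r in bundle.samples.itertuples():
        richness = max(30, int(round(rng.normal(config.mean_species_richness, config.richness_sd))))
        rate = (
            config.waafle_base_rate
            + subject_effect[r.subject_id]
            + (config.drift_effect_week26 if r.timepoint == "week26" else 0.0)
            + float(rng.normal(0.0, config.waafle_noise_sd))
        )
        rate = max(rate, 0.02)
        n_hgt = int(round(richness * rate))
        n_contigs = max(n_hgt + 1, int(round(rng.normal(config.mean_contigs, config.contigs_sd))))
        rows.append((r.sample_id, n_hgt, n_contigs, richness))
    return pd.DataFrame(rows, columns=list(COLUMNS["waafle"]))
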