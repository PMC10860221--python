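"""Time-course set logic for horizontally transferred gene clusters (HTGCs).

For each trial participant (FMT *and* placebo recipients — the arm is never
consulted during detection), a gene cluster is called horizontally
transferred when, restricted to analysable genes:

  (i)   at least one gene of the cluster occurs in the participant's week-6
        sample,
  (ii)  no gene of the cluster occurs in the participant's baseline sample,
  (iii) at least one gene of the cluster occurs in an in-scope donor sample,
        and
  (iv)  the species of the participant's week-6 gene's MAG differs from the
        species of at least one in-scope donor occurrence's MAG.

Each distinct qualifying recipient gene is its own transfer event — distinct
genes from the same cluster count as different events. Donor scope is either
the whole sex-matched donor cohort (default, applied identically to both
arms) or the participant's assigned donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Bundle

DonorScope = Literal["sex_cohort", "assigned"]


@dataclass(frozen=True)
class DonorOccurrence:
    donor_id: str
    donor_sample_id: str
    donor_species: str
    donor_phylum: str


@dataclass(frozen=True)
class HgtEvent:
    cluster_id: str
    recipient_id: str
    recipient_gene_id: str
    recipient_species: str
    recipient_phylum: str
    donor_side: tuple[DonorOccurrence, ...]
    timepoint: str = "week6"

    def discordant_donor_species(self) -> set[str]:
        return {o.donor_species for o in self.donor_side if o.donor_species != self.recipient_species}


@dataclass
class HtgcSet:
    participant_id: str
    arm: str
    sex: str
    events: list[HgtEvent] = field(default_factory=list)

    @property
    def clusters(self) -> set[str]:
        return {e.cluster_id for e in self.events}


class DetectionIndex:
    """Pre-grouped views of the analysable gene table, shared across the
    per-participant detection calls so a whole-trial run stays cheap."""

    def __init__(self, bundle: Bundle, analysable: pd.DataFrame):
        self.bundle = bundle
        subj = bundle.subjects
        self.arm_of = dict(zip(subj["subject_id"], subj["arm"]))
        self.sex_of = dict(zip(subj["subject_id"], subj["sex"]))
        self.role_of = dict(zip(subj["subject_id"], subj["role"]))

        ag = analysable.merge(bundle.samples, on="sample_id", how="left")
        ag["role"] = ag["subject_id"].map(self.role_of)
        self.genes = ag

        rec = ag[ag["role"] == "recipient"]
        base = rec[rec["timepoint"] == "baseline"]
        self.baseline_clusters: dict[str, set[str]] = {
            sid: set(g) for sid, g in base.groupby("subject_id")["cluster_id"]
        }
        wk6 = rec[rec["timepoint"] == "week6"]
        self.week6_genes: dict[str, pd.DataFrame] = {
            sid: g for sid, g in wk6.groupby("subject_id")
        }
        self.week6_cluster_counts: dict[str, int] = {
            sid: g["cluster_id"].nunique() for sid, g in wk6.groupby("subject_id")
        }

        donors = ag[ag["role"] == "donor"].copy()
        donors["sex"] = donors["subject_id"].map(self.sex_of)
        self._donor_genes = donors
        self.assigned: dict[str, set[str]] = {
            rid: set(g) for rid, g in bundle.donor_assignment.groupby("recipient_id")["donor_id"]
        }
        self._occurrence_cache: dict[tuple, dict[str, list[DonorOccurrence]]] = {}

    def donor_occurrences(self, donor_ids: frozenset[str]) -> dict[str, list[DonorOccurrence]]:
        """cluster_id -> list of donor occurrences among `donor_ids`."""
        key = tuple(sorted(donor_ids))
        if key not in self._occurrence_cache:
            sub = self._donor_genes[self._donor_genes["subject_id"].isin(donor_ids)]
            occ: dict[str, list[DonorOccurrence]] = {}
            seen: set[tuple] = set()
            for cluster, did, sid, species, phylum in zip(
                sub["cluster_id"], sub["subject_id"], sub["sample_id"], sub["species"], sub["phylum"]
            ):
                k = (cluster, did, sid, species)
                if k in seen:
                    continue
                seen.add(k)
                occ.setdefault(cluster, []).append(DonorOccurrence(did, sid, species, phylum))
            self._occurrence_cache[key] = occ
        return self._occurrence_cache[key]

    def scope_donors(self, participant_id: str, donor_scope: DonorScope) -> frozenset[str]:
        if donor_scope == "assigned":
            donors = self.assigned.get(participant_id, set())
            if not donors:
                raise ValueError(f"no assigned donors recorded for {participant_id}")
            return frozenset(donors)
        sex = self.sex_of[participant_id]
        return frozenset(d for d, r in self.role_of.items() if r == "donor" and self.sex_of[d] == sex)


def detect_htgcs(
    participant_id: str,
    index: DetectionIndex,
    donor_scope: DonorScope = "sex_cohort",
) -> HtgcSet:
    """Detect the participant's horizontally transferred gene clusters."""
    if index.role_of.get(participant_id) != "recipient":
        raise ValueError(f"unknown participant {participant_id!r}")
    if participant_id not in index.baseline_clusters and participant_id not in index.week6_genes:
        # samples exist (bundle validated) but carry no analysable genes at all
        pass
    sample_tps = set(
        index.bundle.samples.loc[
            index.bundle.samples["subject_id"] == participant_id, "timepoint"
        ]
    )
    for required in ("baseline", "week6"):
        if required not in sample_tps:
            raise ValueError(f"participant {participant_id} lacks a {required} sample")

    result = HtgcSet(
        participant_id=participant_id,
        arm=index.arm_of[participant_id],
        sex=index.sex_of[participant_id],
    )
    wk6 = index.week6_genes.get(participant_id)
    if wk6 is None or not len(wk6):
        return result
    baseline = index.baseline_clusters.get(participant_id, set())
    occurrences = index.donor_occurrences(index.scope_donors(participant_id, donor_scope))

    for gene_id, cluster, species, phylum in zip(
        wk6["gene_id"], wk6["cluster_id"], wk6["species"], wk6["phylum"]
    ):
        if cluster in baseline:
            continue  # (ii)
        occ = occurrences.get(cluster)
        if not occ:
            continue  # (iii)
        if not any(o.donor_species != species for o in occ):
            continue  # (iv): discordance with at least one donor occurrence
        result.events.append(
            HgtEvent(
                cluster_id=cluster,
                recipient_id=participant_id,
                recipient_gene_id=gene_id,
                recipient_species=species,
                recipient_phylum=phylum,
                donor_side=tuple(occ),
            )
        )
    return result


def detect_all(
    index: DetectionIndex, donor_scope: DonorScope = "sex_cohort"
) -> dict[str, HtgcSet]:
    """Run detection for every recipient; identical code path for both arms."""
    out = {}
    for rid in index.bundle.recipients()["subject_id"]:
        out[rid] = detect_htgcs(rid, index, donor_scope)
    return out


def events_frame(sets: Iterable[HtgcSet]) -> pd.DataFrame:
    """Long-format event table, one row per (event, donor occurrence)."""
    rows = []
    for s in sets:
        for e in s.events:
            for o in e.donor_side:
                rows.append(
                    {
                        "recipient_id": e.recipient_id,
                        "arm": s.arm,
                        "sex": s.sex,
                        "cluster_id": e.cluster_id,
                        "recipient_gene_id": e.recipient_gene_id,
                        "recipient_species": e.recipient_species,
                        "recipient_phylum": e.recipient_phylum,
                        "donor_id": o.donor_id,
                        "donor_sample_id": o.donor_sample_id,
                        "donor_species": o.donor_species,
                        "donor_phylum": o.donor_phylum,
                        "timepoint": e.timepoint,
                    }
                )
    cols = [
        "recipient_id", "arm", "sex", "cluster_id", "recipient_gene_id",
        "recipient_species", "recipient_phylum", "donor_id", "donor_sample_id",
        "donor_species", "donor_phylum", "timepoint",
    ]
    return pd.DataFrame(rows, columns=cols)


def htgc_frequency(htgc_set: HtgcSet, index: DetectionIndex) -> float:
    """HTGC percentage: 100 x detected clusters / distinct analysable clusters
    in the participant's week-6 sample."""
    total = index.week6_cluster_counts.get(htgc_set.participant_id, 0)
    if total == 0:
        raise ValueError(
            f"HTGC frequency undefined: {htgc_set.participant_id} has no analysable clusters at week6"
        )
    return 100.0 * len(htgc_set.clusters) / total


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration over all rank assignments (with midranks for ties) when
    both groups have at most 8 observations; tie-corrected normal
    approximation otherwise. The two-sided exact p counts assignments whose
    rank-sum deviates from its mean by at least the observed amount.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("rank-sum test requires at least one observation per group")
    n, m = len(x), len(y)
    if n <= 8 and m <= 8:
        ranks = stats.rankdata(x + y)  # midranks
        w_obs = float(np.sum(ranks[:n]))
        mean_w = n * (n + m + 1) / 2.0
        dev = abs(w_obs - mean_w)
        total = comb(n + m, n)
        hits = 0
        for idx in combinations(range(n + m), n):
            if abs(float(np.sum(ranks[list(idx)])) - mean_w) >= dev - 1e-12:
                hits += 1
        return {"statistic": w_obs, "p": hits / total, "method": "exact"}
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "method": "normal"}


def compare_arms(frequencies: pd.DataFrame) -> dict[str, dict]:
    """Wilcoxon rank-sum comparison of per-participant HTGC frequencies
    between arms, overall and within each sex.

    ``frequencies`` needs columns participant_id / arm / sex / frequency.
    """
    out: dict[str, dict] = {}
    for label, sub in (("overall", frequencies),) + tuple(
        (sex, frequencies[frequencies["sex"] == sex]) for sex in ("female", "male")
    ):
        fmt = sub.loc[sub["arm"] == "FMT", "frequency"]
        plc = sub.loc[sub["arm"] == "placebo", "frequency"]
        if not len(fmt) or not len(plc):
            raise ValueError(f"compare_arms: empty arm in group {label!r}")
        out[label] = rank_sum_test(fmt, plc)
    return out


def classify_specificity(sets: Iterable[HtgcSet], sex: str) -> dict:
    """Partition the detected clusters of one sex into FMT-specific,
    placebo-specific and shared sets."""
    fmt_clusters: set[str] = set()
    placebo_clusters: set[str] = set()
    for s in sets:
        if s.sex != sex:
            continue
        if s.arm == "FMT":
            fmt_clusters |= s.clusters
        elif s.arm == "placebo":
            placebo_clusters |= s.clusters
    shared = fmt_clusters & placebo_clusters
    return {
        "sex": sex,
        "fmt_specific": fmt_clusters - shared,
        "placebo_specific": placebo_clusters - shared,
        "shared": shared,
        "counts": {
            "fmt_specific": len(fmt_clusters - shared),
            "placebo_specific": len(placebo_clusters - shared),
            "shared": len(shared),
        },
    }


def event_histogram(
    sets: Iterable[HtgcSet],
    clusters: set[str] | None = None,
    cap: int = 20,
) -> dict[str, int]:
    """Histogram of per-cluster transfer-event counts (bin width 1, terminal
    ``"20+"`` bin). ``clusters`` optionally restricts to a specificity class.
    Bin totals sum to the number of clusters counted."""
    counts: dict[str, int] = {}
    for s in sets:
        for e in s.events:
            if clusters is not None and e.cluster_id not in clusters:
                continue
            counts[e.cluster_id] = counts.get(e.cluster_id, 0) + 1
    hist: dict[str, int] = {}
    for n in counts.values():
        key = f"{cap}+" if n > cap else str(n)
        hist[key] = hist.get(key, 0) + 1
    return hist
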