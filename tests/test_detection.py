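"""HTGC detection set logic, frequencies, specificity, and the rank-sum test."""

import numpy as np
import pandas as pd
import pytest

from fmt_hgt import detection as det
from fmt_hgt import mag_quality as mq
from fmt_hgt.data_model import Bundle, COLUMNS

from conftest import toy_bundle


def build_index(bundle: Bundle) -> det.DetectionIndex:
    hq = mq.filter_high_quality(bundle.mags)
    analysable, _ = mq.analysable_genes(bundle.genes, hq)
    return det.DetectionIndex(bundle, analysable)


# ---------------------------------------------------------------- toy cases

def test_basic_transfer_detected():
    b = toy_bundle([("W", "spA", "c1"), ("D1", "spB", "c1")])
    s = det.detect_htgcs("RF001", build_index(b))
    assert s.clusters == {"c1"} and len(s.events) == 1
    assert s.events[0].discordant_donor_species() == {"spB"}


def test_baseline_presence_blocks_detection():
    b = toy_bundle([("W", "spA", "c1"), ("D1", "spB", "c1"), ("B", "spC", "c1")])
    assert det.detect_htgcs("RF001", build_index(b)).clusters == set()


def test_concordant_donor_species_is_vertical_not_horizontal():
    b = toy_bundle([("W", "spA", "c1"), ("D1", "spA", "c1")])
    assert det.detect_htgcs("RF001", build_index(b)).clusters == set()


def test_distinct_genes_same_cluster_are_separate_events():
    b = toy_bundle([("W", "spA", "c1"), ("W", "spD", "c1"), ("D1", "spB", "c1")])
    s = det.detect_htgcs("RF001", build_index(b))
    assert s.clusters == {"c1"} and len(s.events) == 2


def test_unanalysable_genes_are_invisible_to_all_criteria():
    # baseline occurrence on a low-quality MAG does not veto detection
    b = toy_bundle([
        ("W", "spA", "c1"), ("D1", "spB", "c1"), ("B", "spC", "c1", False),
    ])
    assert det.detect_htgcs("RF001", build_index(b)).clusters == {"c1"}
    # donor occurrence on an unclassified MAG cannot satisfy the donor criterion
    b2 = toy_bundle([("W", "spA", "c1"), ("D1", "spB", "c1", True, False)])
    assert det.detect_htgcs("RF001", build_index(b2)).clusters == set()


def test_unknown_participant_and_missing_samples_raise():
    b = toy_bundle([("W", "spA", "c1"), ("D1", "spB", "c1")])
    idx = build_index(b)
    with pytest.raises(ValueError, match="unknown participant"):
        det.detect_htgcs("RF999", idx)
    b2 = toy_bundle([("W", "spA", "c1")])
    b2.samples.drop(b2.samples[b2.samples["timepoint"] == "baseline"].index, inplace=True)
    with pytest.raises(ValueError, match="baseline"):
        det.detect_htgcs("RF001", build_index(b2))


# ------------------------------------------------- brute-force oracle check

def _oracle(bundle: Bundle, participant: str) -> list[tuple[str, str]]:
    """Independent nested-loop re-derivation of the detection criteria."""
    mags = {m.mag_id: m for m in bundle.mags.itertuples()}
    samples = {s.sample_id: s for s in bundle.samples.itertuples()}
    subj = {s.subject_id: s for s in bundle.subjects.itertuples()}

    def analysable(g):
        m = mags[g.mag_id]
        return m.completeness > 90 and m.contamination < 5 and bool(m.species_classified)

    sex = subj[participant].sex
    events = []
    for g in bundle.genes.itertuples():
        s = samples[g.sample_id]
        if s.subject_id != participant or s.timepoint != "week6" or not analysable(g):
            continue
        present_at_baseline = any(
            samples[g2.sample_id].subject_id == participant
            and samples[g2.sample_id].timepoint == "baseline"
            and analysable(g2) and g2.cluster_id == g.cluster_id
            for g2 in bundle.genes.itertuples()
        )
        if present_at_baseline:
            continue
        discordant_donor = any(
            subj[samples[g2.sample_id].subject_id].role == "donor"
            and subj[samples[g2.sample_id].subject_id].sex == sex
            and analysable(g2) and g2.cluster_id == g.cluster_id
            and mags[g2.mag_id].species != mags[g.mag_id].species
            for g2 in bundle.genes.itertuples()
        )
        if discordant_donor:
            events.append((g.cluster_id, g.gene_id))
    return sorted(events)


def random_fixture(rng: np.random.Generator, n_genes_per_sample: int = 10) -> Bundle:
    species = [f"sp{i}" for i in range(5)]
    clusters = [f"c{i}" for i in range(10)]
    subjects = [("DF01", "donor", "none", "female"), ("DF02", "donor", "none", "female"),
                ("RF001", "recipient", "FMT", "female"), ("RF002", "recipient", "placebo", "female")]
    samples = [("D1", "DF01", "donation_1"), ("D2", "DF02", "donation_1"),
               ("B1", "RF001", "baseline"), ("W1", "RF001", "week6"),
               ("B2", "RF002", "baseline"), ("W2", "RF002", "week6")]
    mags, genes = [], []
    gid = 0
    for sid, *_ in samples:
        for _ in range(int(rng.integers(3, n_genes_per_sample + 1))):
            cluster = clusters[rng.integers(len(clusters))]
            sp = species[rng.integers(len(species))]
            hq = rng.random() < 0.85
            classified = rng.random() < 0.85
            comp = 95.0 if hq else float(rng.uniform(40, 90))
            cont = 1.0 if hq else float(rng.uniform(5, 20))
            mags.append((f"m{gid}", sid, comp, cont,
                         "P" if classified else "", sp if classified else "", classified))
            genes.append((f"g{gid}", f"m{gid}", sid, cluster))
            gid += 1
    return Bundle(
        subjects=pd.DataFrame(subjects, columns=list(COLUMNS["subjects"])),
        samples=pd.DataFrame(samples, columns=list(COLUMNS["samples"])),
        mags=pd.DataFrame(mags, columns=list(COLUMNS["mags"])),
        genes=pd.DataFrame(genes, columns=list(COLUMNS["genes"])),
    )


def test_detection_equals_bruteforce_oracle_on_random_fixtures():
    rng = np.random.default_rng(8)
    for _ in range(25):
        bundle = random_fixture(rng)
        index = build_index(bundle)
        for rid in ("RF001", "RF002"):
            found = det.detect_htgcs(rid, index)
            got = sorted((e.cluster_id, e.recipient_gene_id) for e in found.events)
            assert got == _oracle(bundle, rid)


def test_adding_donor_evidence_only_grows_the_set():
    rng = np.random.default_rng(9)
    for _ in range(10):
        bundle = random_fixture(rng)
        before = {rid: det.detect_htgcs(rid, build_index(bundle)).clusters
                  for rid in ("RF001", "RF002")}
        extra_mags, extra_genes = [], []
        bundle.samples.loc[len(bundle.samples)] = ("D3", "DF01", "donation_2")
        for i in range(5):
            extra_mags.append((f"xm{i}", "D3", 95.0, 1.0, "P", f"sp{i}", True))
            extra_genes.append((f"xg{i}", f"xm{i}", "D3", f"c{i}"))
        bundle.mags = pd.concat([bundle.mags, pd.DataFrame(extra_mags, columns=bundle.mags.columns)])
        bundle.genes = pd.concat([bundle.genes, pd.DataFrame(extra_genes, columns=bundle.genes.columns)])
        after = {rid: det.detect_htgcs(rid, build_index(bundle)).clusters
                 for rid in ("RF001", "RF002")}
        for rid in before:
            assert before[rid] <= after[rid]


# ------------------------------------------------------- frequency & stats

def test_htgc_frequency_arithmetic():
    rows = [("W", "spA", f"c{i}") for i in range(50)]
    rows += [("D1", "spB", "c0"), ("D1", "spB", "c1")]
    b = toy_bundle(rows)
    idx = build_index(b)
    s = det.detect_htgcs("RF001", idx)
    assert len(s.clusters) == 2
    assert det.htgc_frequency(s, idx) == pytest.approx(4.0)


def test_htgc_frequency_bounds_and_error():
    b = toy_bundle([("W", "spA", "c1"), ("D1", "spB", "c1")])
    idx = build_index(b)
    s = det.detect_htgcs("RF001", idx)
    assert det.htgc_frequency(s, idx) == pytest.approx(100.0)
    empty = toy_bundle([("D1", "spB", "c1")])
    idx2 = build_index(empty)
    with pytest.raises(ValueError, match="undefined"):
        det.htgc_frequency(det.detect_htgcs("RF001", idx2), idx2)


def test_rank_sum_exact_enumeration():
    assert det.rank_sum_test([1, 2, 3], [4, 5, 6])["p"] == pytest.approx(0.1)
    res = det.rank_sum_test([1, 2, 3], [1, 2, 3])
    assert res["method"] == "exact" and res["p"] == pytest.approx(1.0)


def test_rank_sum_large_samples_use_normal_approximation():
    x = list(range(10))
    y = [v + 0.5 for v in range(10)]
    res = det.rank_sum_test(x, y)
    assert res["method"] == "normal" and 0 < res["p"] <= 1
    with pytest.raises(ValueError):
        det.rank_sum_test([], [1.0])


def _mkset(pid, arm, sex, clusters, events_per_cluster=1):
    s = det.HtgcSet(pid, arm, sex)
    for c in clusters:
        for k in range(events_per_cluster):
            s.events.append(det.HgtEvent(
                cluster_id=c, recipient_id=pid, recipient_gene_id=f"{pid}_{c}_{k}",
                recipient_species="spA", recipient_phylum="P",
                donor_side=(det.DonorOccurrence("DF01", "D1", "spB", "P"),),
            ))
    return s


def test_specificity_partition():
    sets = [
        _mkset("R1", "FMT", "female", {"c1", "c2"}),
        _mkset("R2", "placebo", "female", {"c2", "c3"}),
        _mkset("R3", "FMT", "male", {"c9"}),
    ]
    part = det.classify_specificity(sets, "female")
    assert part["fmt_specific"] == {"c1"}
    assert part["placebo_specific"] == {"c3"}
    assert part["shared"] == {"c2"}
    union = part["fmt_specific"] | part["placebo_specific"] | part["shared"]
    assert union == {"c1", "c2", "c3"} and part["counts"]["shared"] == 1


def test_event_histogram_binning_and_conservation():
    sets = [_mkset("R1", "FMT", "female", {"c1"}, events_per_cluster=1),
            _mkset("R2", "FMT", "female", {"c2"}, events_per_cluster=25)]
    hist = det.event_histogram(sets)
    assert hist == {"1": 1, "20+": 1}
    assert sum(hist.values()) == 2


def test_simulator_specificity_and_histogram_against_truth(lean_trial):
    bundle, truth = lean_trial
    index = build_index(bundle)
    sets = det.detect_all(index)
    arm_of = dict(zip(bundle.subjects["subject_id"], bundle.subjects["arm"]))
    sex_of = dict(zip(bundle.subjects["subject_id"], bundle.subjects["sex"]))
    for sex in ("female", "male"):
        planted = truth.planted[truth.planted["recipient_id"].map(sex_of) == sex]
        fmt = set(planted.loc[planted["recipient_id"].map(arm_of) == "FMT", "cluster_id"])
        plc = set(planted.loc[planted["recipient_id"].map(arm_of) == "placebo", "cluster_id"])
        part = det.classify_specificity(sets.values(), sex)
        assert part["fmt_specific"] == fmt - plc
        assert part["placebo_specific"] == plc - fmt
        assert part["shared"] == fmt & plc
    hist = det.event_histogram(sets.values())
    n_clusters = len({(e.cluster_id) for s in sets.values() for e in s.events})
    assert sum(hist.values()) == n_clusters
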