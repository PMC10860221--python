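"""Generator invariants: determinism, planted-truth bookkeeping, phylum bias."""

import numpy as np
import pandas as pd
import pytest

from fmt_hgt import SimConfig, simulate, simulate_waafle_counts
from fmt_hgt.data_model import validate

from conftest import LEAN


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_donors_female=0)
    with pytest.raises(ValueError):
        SimConfig(phylum_weights={"Firmicutes": 0.5, "Bacteroidetes": 0.4})
    with pytest.raises(ValueError):
        SimConfig(background_acquisition_rate=1.5)
    with pytest.raises(ValueError):
        SimConfig(bacteroidetes_hgt_multiplier=0.5)


def test_bundle_passes_validation(lean_trial):
    bundle, truth = lean_trial
    validate(bundle)
    # every engraftment-dependent planted unit has a matching engraftment call
    dep = truth.engraftment_dependent()
    eng = set(zip(truth.engraftments["recipient_id"], truth.engraftments["species"]))
    assert all((r, s) in eng for r, s in zip(dep["recipient_id"], dep["donor_species"]))


def test_seed_determinism_byte_identical():
    b1, t1 = simulate(SimConfig(seed=5, **LEAN))
    b2, t2 = simulate(SimConfig(seed=5, **LEAN))
    for (name, left), (_, right) in zip(b1.tables(), b2.tables()):
        pd.testing.assert_frame_equal(left, right, obj=name)
    pd.testing.assert_frame_equal(t1.planted, t2.planted)
    b3, _ = simulate(SimConfig(seed=6, **LEAN))
    assert not b3.genes.equals(b1.genes)


def test_zero_transfer_rate_plants_no_dependent_events():
    _, truth = simulate(SimConfig(seed=3, transfer_rate_given_engraftment=0.0, **LEAN))
    assert truth.engraftment_dependent().empty


def test_certain_retention_keeps_every_unit_at_week12():
    _, truth = simulate(SimConfig(seed=3, retention_prob_week12=1.0, **LEAN))
    assert truth.planted["retained_week12"].all()
    assert all("week12" in tps for tps in truth.retained_at().values())


def test_bacteroidetes_bias_in_dependent_events_matches_analytic_expectation():
    """The fraction of planted engraftment-dependent events whose donor
    species is Bacteroidetes must exceed the community weight and agree with
    a brute-force expectation computed from the realized candidate pools."""
    cfg = SimConfig(seed=13, transfer_rate_given_engraftment=0.15,
                    engraftment_rate=0.3, **LEAN)
    observed_bact = observed_total = 0.0
    expected_bact = expected_total = 0.0
    for rep in range(8):
        cfg_rep = SimConfig(**{**cfg.to_dict(), "seed": 13 + rep})
        bundle, truth = simulate(cfg_rep)
        dep = truth.engraftment_dependent()
        phylum = bundle.species_phylum()
        observed_bact += (dep["donor_species"].map(phylum) == "Bacteroidetes").sum()
        observed_total += len(dep)
        # brute-force expectation from each recipient's candidate species
        merged = bundle.samples.merge(bundle.subjects, on="subject_id")
        k = cfg.n_clusters_per_species
        donors = bundle.donors()["subject_id"]
        donor_sp = bundle.mags.merge(bundle.samples, on="sample_id")
        donor_sp = donor_sp[donor_sp["subject_id"].isin(set(donors))]
        cohort = {
            sex: set(donor_sp.loc[donor_sp["subject_id"].map(
                dict(zip(bundle.subjects["subject_id"], bundle.subjects["sex"]))) == sex, "species"]) - {""}
            for sex in ("female", "male")
        }
        base = bundle.mags.merge(bundle.samples, on="sample_id")
        base = base[base["timepoint"] == "baseline"]
        residents = base.groupby("subject_id")["species"].agg(set)
        for r in bundle.recipients().itertuples():
            if r.arm != "FMT":
                continue
            for s in cohort[r.sex] - residents.get(r.subject_id, set()):
                p_eng = min(0.99, cfg.engraftment_rate * (
                    cfg.bacteroidetes_engraftment_bias if phylum[s] == "Bacteroidetes" else 1.0))
                p_tr = min(1.0, cfg.transfer_rate_given_engraftment * (
                    cfg.bacteroidetes_hgt_multiplier if phylum[s] == "Bacteroidetes" else 1.0))
                contribution = p_eng * k * p_tr
                expected_total += contribution
                if phylum[s] == "Bacteroidetes":
                    expected_bact += contribution
    assert observed_total >= 1000
    obs_frac = observed_bact / observed_total
    exp_frac = expected_bact / expected_total
    assert obs_frac > SimConfig().phylum_weights["Bacteroidetes"]
    # Monte-Carlo tolerance: 4 sigma of a binomial at the observed event count
    tol = 4 * np.sqrt(exp_frac * (1 - exp_frac) / observed_total)
    assert abs(obs_frac - exp_frac) < tol + 0.02


def test_waafle_counts_respect_contig_bound_and_drift_null(lean_trial):
    bundle, _ = lean_trial
    cfg = SimConfig(seed=11, drift_effect_week26=0.0, **LEAN)
    wf = simulate_waafle_counts(cfg, bundle, seed=99)
    assert (wf["n_hgt_contigs"] <= wf["n_contigs"]).all()
    merged = wf.merge(bundle.samples, on="sample_id").merge(bundle.subjects, on="subject_id")
    rec = merged[merged["role"] == "recipient"]
    norm = rec["n_hgt_contigs"] / rec["species_richness"]
    by_tp = norm.groupby(rec["timepoint"]).mean()
    # no drift planted: week-26 mean within sampling error of baseline mean
    spread = norm.std() / np.sqrt(len(rec) / 4)
    assert abs(by_tp["week26"] - by_tp["baseline"]) < 4 * spread


def test_arm_null_wilcoxon_rejection_rate_near_alpha():
    """Equal background acquisition across arms: the arm comparison of HTGC
    frequency should reject at roughly the nominal 5% level."""
    from fmt_hgt import mag_quality as mq
    from fmt_hgt import detection as det

    rejections = 0
    n_reps = 200
    for rep in range(n_reps):
        bundle, _ = simulate(SimConfig(seed=20_000 + rep, **LEAN))
        hq = mq.filter_high_quality(bundle.mags)
        analysable, _ = mq.analysable_genes(bundle.genes, hq)
        index = det.DetectionIndex(bundle, analysable)
        sets = det.detect_all(index)
        freq = pd.DataFrame(
            {"participant_id": rid, "arm": s.arm, "sex": s.sex,
             "frequency": det.htgc_frequency(s, index)}
            for rid, s in sets.items()
        )
        rejections += det.compare_arms(freq)["overall"]["p"] < 0.05
    rate = rejections / n_reps
    # binomial 3-sigma band around 0.05 at n=200 is roughly +/- 0.046
    assert 0.004 <= rate <= 0.096
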