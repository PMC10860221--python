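import numpy as np
import pandas as pd
import pytest

from fmt_hgt import SimConfig, simulate
from fmt_hgt.data_model import Bundle, COLUMNS
from fmt_hgt.pipeline import RunConfig, run_all

#: reduced problem sizes for replicate-heavy simulation tests; every *rate*
#: stays at its default so the study conditions are unchanged, only counts
#: shrink.
LEAN = dict(
    n_recipients_per_arm_per_sex=9,
    n_species=40,
    n_clusters_per_species=4,
    n_species_per_donor=18,
    n_resident_species=12,
    n_donations_per_donor=2,
    hq_mag_fraction=1.0,
    unclassified_gene_fraction=0.0,
)

#: engraftment-rich conditions for retention/enrichment characterisation,
#: where transfer events must be plentiful enough to study.
RICH = dict(transfer_rate_given_engraftment=0.08)


def toy_bundle(
    gene_rows,
    arm: str = "FMT",
    engraftment=None,
    abundance=None,
    second_donor: bool = False,
) -> Bundle:
    """One female donor (DF01, sample D1), optionally a second (DF02, D2),
    and one female recipient (RF001; samples B/W/T12/T26).

    ``gene_rows``: (sample_id, species, cluster_id[, hq[, classified]]);
    one MAG per gene keeps quality/classification independently tweakable.
    """
    subjects = [("DF01", "donor", "none", "female"), ("RF001", "recipient", arm, "female")]
    samples = [
        ("D1", "DF01", "donation_1"),
        ("B", "RF001", "baseline"),
        ("W", "RF001", "week6"),
        ("T12", "RF001", "week12"),
        ("T26", "RF001", "week26"),
    ]
    if second_donor:
        subjects.append(("DF02", "donor", "none", "female"))
        samples.append(("D2", "DF02", "donation_1"))
    mags, genes = [], []
    for i, row in enumerate(gene_rows):
        sample, species, cluster = row[:3]
        hq = row[3] if len(row) > 3 else True
        classified = row[4] if len(row) > 4 else True
        mag_id = f"mag{i}"
        comp, cont = (95.0, 1.0) if hq else (80.0, 10.0)
        phylum = "Bacteroidetes" if classified else ""
        mags.append((mag_id, sample, comp, cont, phylum, species if classified else "", classified))
        genes.append((f"g{i}", mag_id, sample, cluster))
    return Bundle(
        subjects=pd.DataFrame(subjects, columns=list(COLUMNS["subjects"])),
        samples=pd.DataFrame(samples, columns=list(COLUMNS["samples"])),
        mags=pd.DataFrame(mags, columns=list(COLUMNS["mags"])),
        genes=pd.DataFrame(genes, columns=list(COLUMNS["genes"])),
        engraftment=(
            pd.DataFrame(engraftment, columns=list(COLUMNS["engraftment"]))
            if engraftment is not None else pd.DataFrame(columns=list(COLUMNS["engraftment"]))
        ),
        abundance=(
            pd.DataFrame(abundance, columns=list(COLUMNS["abundance"]))
            if abundance is not None else pd.DataFrame(columns=list(COLUMNS["abundance"]))
        ),
    )


@pytest.fixture(scope="session")
def default_trial():
    """Default-condition trial: bundle, ground truth, and a full pipeline run."""
    config = SimConfig(seed=7)
    bundle, truth = simulate(config)
    result = run_all(RunConfig(seed=7, n_perm=199), bundle=bundle)
    return bundle, truth, result


@pytest.fixture(scope="session")
def lean_trial():
    bundle, truth = simulate(SimConfig(seed=11, **LEAN))
    return bundle, truth


@pytest.fixture(scope="session")
def rich_trial():
    """Engraftment-rich trial at full scale plus its detected event tables."""
    from fmt_hgt import detection as det
    from fmt_hgt import engraftment as eng
    from fmt_hgt import mag_quality as mq

    bundle, truth = simulate(SimConfig(seed=1, **RICH))
    hq = mq.filter_high_quality(bundle.mags)
    analysable, _ = mq.analysable_genes(bundle.genes, hq)
    sets = det.detect_all(det.DetectionIndex(bundle, analysable))
    events = det.events_frame(sets.values())
    filtered = eng.filter_engraftment_dependent(events, bundle.engraftment)
    return {"bundle": bundle, "truth": truth, "events": events, "filtered": filtered}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
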