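import numpy as np
import pytest

import cnacohort as cc

SMALL_CHROMS = {"1": 30_000_000, "2": 20_000_000}
SMALL_SEGMENTS = (
    cc.PlantedSegment("1", 5_000_000, 15_000_000, 3, 0.9, 0.1),
    cc.PlantedSegment("2", 4_000_000, 9_000_000, 1, 0.5, 0.5),
)


def small_model(seed=7, noise=None, **kwargs):
    """A fast two-chromosome cohort (8 exposed / 6 unexposed / 4 reference)."""
    return cc.CnaCohortModel.from_simulation(
        seed=seed,
        n_probes=300,
        chrom_lengths=SMALL_CHROMS,
        cohort_sizes={"exposed": 8, "unexposed": 6, "reference": 4},
        segments=SMALL_SEGMENTS,
        noise=noise,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_fit():
    model = small_model()
    return model, model.fit()


@pytest.fixture(scope="session")
def default_fit():
    """The full default study: 26 exposed / 17 unexposed / 14 reference,
    10,000 probes, planted gains at the default group frequencies,
    multiplicative noise sigma 0.1."""
    model = cc.CnaCohortModel.from_simulation(seed=1)
    return model, model.fit()


@pytest.fixture(scope="session")
def noisefree_fit():
    """Same cohort with every noise sigma at zero."""
    model = cc.CnaCohortModel.from_simulation(
        seed=1, noise=cc.NoiseParams(0.0, 0.0, 0.0, seed=3)
    )
    return model, model.fit()


def planted_concordance(model, results):
    """Probe-level call concordance inside planted spans covering >= min_run
    probes: truth-implied state (gain/loss/normal from true copies) vs call,
    over every tumor sample."""
    pm = model.probe_map
    tumors = model.tumor_ids
    min_run = model.calling_params.min_run
    total = matched = 0
    for seg in model.planted_segments:
        mask = (
            (pm["chrom"].to_numpy() == seg.chrom)
            & (pm["pos"].to_numpy() >= seg.start_pos)
            & (pm["pos"].to_numpy() <= seg.end_pos)
        )
        if mask.sum() < min_run:
            continue
        idx = np.flatnonzero(mask)
        truth = model.truth.iloc[idx][tumors].to_numpy()
        calls = results.calls.iloc[idx][tumors].to_numpy()
        expected = np.where(truth > 2, 1, np.where(truth < 2, -1, 0))
        total += expected.size
        matched += int((expected == calls).sum())
    assert total > 0, "no planted span covers enough probes"
    return matched / total
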