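import numpy as np
import pytest

from dnlipid import processing as proc
from dnlipid import synthetic as syn


@pytest.fixture(scope="session")
def tiny_params() -> syn.GeneratorParams:
    return syn.GeneratorParams(
        n_subjects=12,
        seed=7,
        background_species=syn.DEFAULT_BACKGROUND_SPECIES[:11],
        n_decoy_peaks=30,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return syn.generate_cohort(tiny_params)


@pytest.fixture(scope="session")
def tiny_truth(tiny_params, tiny_cohort):
    return syn.generate_lipid_profiles(tiny_cohort, tiny_params)


@pytest.fixture(scope="session")
def tiny_masslists(tiny_truth):
    return syn.simulation_mass_list(tiny_truth.columns)


@pytest.fixture(scope="session")
def tiny_peaklists(tiny_truth, tiny_masslists, tiny_params):
    samples, qcs = syn.render_spectra(tiny_truth, tiny_masslists, tiny_params)
    return samples, qcs


@pytest.fixture(scope="session")
def tiny_matrix(tiny_peaklists, tiny_masslists):
    samples, qcs = tiny_peaklists
    return proc.process_peaklists(samples + qcs, tiny_masslists)


@pytest.fixture(scope="session")
def medium_run():
    """One moderately sized spectra->matrix run shared by statistical tests."""
    params = syn.GeneratorParams(n_subjects=400, seed=42)
    cohort = syn.generate_cohort(params)
    truth = syn.generate_lipid_profiles(cohort, params)
    masslists = syn.simulation_mass_list(truth.columns)
    samples, qcs = syn.render_spectra(truth, masslists, params)
    matrix = proc.process_peaklists(samples + qcs, masslists)
    return params, cohort, truth, matrix


def random_peaklist(rng: np.random.Generator, n_peaks: int, polarity: str = "positive"):
    mz = np.sort(rng.uniform(150.0, 1200.0, n_peaks))
    intensity = rng.exponential(1000.0, n_peaks)
    return proc.PeakList("R", polarity, mz, intensity, noise_level=100.0)
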