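import numpy as np
import pytest

from revmet.conjugates import AmineHead, LipidTail, enumerate_conjugates
from revmet.library import GateConfig, build_library
from revmet.simulate import (
    GeneratorConfig,
    NoiseConfig,
    generate_heads,
    generate_tails,
    simulate_reaction_run,
)


@pytest.fixture(scope="session")
def glycine():
    return AmineHead.from_smiles("glycine", "NCC(=O)O")


@pytest.fixture(scope="session")
def ornithine():
    return AmineHead.from_smiles("ornithine", "NCCCC(N)C(=O)O")


@pytest.fixture(scope="session")
def hydroxybutyrate_tail():
    return LipidTail.from_smiles("3OH-C4:0", "CC(O)CC(=O)O")


@pytest.fixture(scope="session")
def small_world():
    """A compact simulated world reused across modules: 5 heads x 4 tails."""
    config = GeneratorConfig(seed=101, n_heads=5, n_tails=4)
    heads = generate_heads(config)
    tails = generate_tails(config)
    targets = enumerate_conjugates(heads, tails)
    run, run_truth = simulate_reaction_run(
        targets, config.noise, seed=102, adducts=("[M+H]+", "[M+Na]+")
    )
    library = build_library([run], targets, GateConfig())
    return {
        "config": config,
        "heads": heads,
        "tails": tails,
        "targets": targets,
        "run": run,
        "run_truth": run_truth,
        "library": library,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)


def random_spectrum_pair(rng, max_peaks=8, frag_tol=0.02, shared_fraction=0.5):
    """A pair of small random spectra with some near-coincident peaks.

    Half of the second spectrum's peaks sit within the matching tolerance of
    the first's (possibly shifted), so the assignment problem is non-trivial
    while the feasibility graph stays sparse enough for brute force.
    """
    from revmet.spectra import Spectrum

    n_a = int(rng.integers(1, max_peaks + 1))
    n_b = int(rng.integers(1, max_peaks + 1))
    mz_a = np.sort(rng.uniform(100.0, 500.0, size=n_a))
    mz_b = rng.uniform(100.0, 500.0, size=n_b)
    for j in range(n_b):
        if rng.uniform() < shared_fraction:
            mz_b[j] = mz_a[int(rng.integers(0, n_a))] + rng.uniform(-1.5, 1.5) * frag_tol
    int_a = rng.uniform(0.1, 1.0, size=n_a)
    int_b = rng.uniform(0.1, 1.0, size=n_b)
    prec_a = float(rng.uniform(400.0, 600.0))
    prec_b = prec_a - float(rng.uniform(0.0, 30.0))
    a = Spectrum(peaks_mz=mz_a, peaks_intensity=int_a, precursor_mz=prec_a, provenance="a:1")
    b = Spectrum(peaks_mz=mz_b, peaks_intensity=int_b, precursor_mz=prec_b, provenance="b:1")
    return a, b
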