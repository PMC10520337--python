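import numpy as np
import pytest

import sleepcrit as sc


@pytest.fixture(scope="session")
def critical_sample():
    """Critical branching-process avalanches (offspring mean 1)."""
    return sc.simulate_branching_process(
        sc.BranchingConfig(offspring_mean=1.0, n_avalanches=150_000, seed=12345)
    )


@pytest.fixture(scope="session")
def coupled_surrogate():
    """Surrogate PSG with architecture-coupled bursts and ground truth."""
    arch = sc.ArchitectureConfig(n_cycles=4, seed=21)
    hyp = sc.simulate_hypnogram(arch)
    cap = sc.simulate_cap_annotations(hyp, arch)
    coupling = sc.CouplingConfig(seed=22)
    rec, truth = sc.synthesize_recording(
        hyp, cap, coupling, n_channels=8, fs=128.0, seed=23
    )
    return {"hyp": hyp, "cap": cap, "coupling": coupling, "rec": rec,
            "truth": truth, "arch": arch}


@pytest.fixture(scope="session")
def detected_surrogate(coupled_surrogate):
    """z-scored surrogate with raster and catalog at theta = 2 SD."""
    z = sc.zscore_normalize(coupled_surrogate["rec"])
    raster = sc.detect_excursions(z)
    catalog = sc.extract_avalanches(raster, z)
    return {"z": z, "raster": raster, "catalog": catalog}
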