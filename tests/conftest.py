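import numpy as np
import pandas as pd
import pytest

from phagetx import synthetic
from phagetx.core_io import CountMatrix, StudyMetadata


@pytest.fixture(scope="session")
def small_config():
    """Reduced study: fast enough for per-module tests, same structure."""
    return synthetic.SimulationConfig(
        seed=20240517, n_donors=4, n_recipients_per_strain=4, n_controls_per_strain=3,
        n_contigs=200, n_asvs=60, depth_mean=8000, asv_depth_mean=6000,
        snp_contigs=8, snp_sites_per_contig=10)


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthetic.simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """One full-size study at generator defaults."""
    return synthetic.simulate_study(synthetic.SimulationConfig(seed=7))


@pytest.fixture()
def toy_metadata():
    """Two donors, one recipient per strain per donor, one control per strain."""
    rows = []
    for i, (d, loc) in enumerate([("W01", "Jed"), ("W02", "Nlc")]):
        rows.append((f"{d}_D0", d, "wild_donor", "wild", loc, "D0", None))
    for strain in ("BULS", "BUSNA"):
        for i, d in enumerate(["W01", "W02"]):
            m = f"{strain}_R{i + 1:02d}"
            for day in ("D-1", "D2", "D7"):
                rows.append((f"{m}_{day}", m, "recipient", strain, None, day, d))
        m = f"{strain}_C01"
        for day in ("D-1", "D2", "D7"):
            rows.append((f"{m}_{day}", m, "control", strain, None, day, None))
    return StudyMetadata(pd.DataFrame(
        rows, columns=["sample_id", "mouse_id", "group", "strain", "locality", "day",
                       "donor_id"]))


@pytest.fixture()
def toy_counts(toy_metadata):
    rng = np.random.default_rng(99)
    sample_ids = toy_metadata.sample_ids
    features = [f"c{i}" for i in range(12)]
    counts = rng.integers(0, 50, size=(12, len(sample_ids)))
    ann = pd.DataFrame({
        "lifestyle": ["temperate", "virulent", "undetermined"] * 4,
        "family": ["FamA", "FamB"] * 6,
        "host_family": ["Lachnospiraceae", None] * 6,
        "length_bp": rng.integers(1000, 50000, 12),
    }, index=pd.Index(features, name="feature_id"))
    return CountMatrix(features, sample_ids, counts, ann)
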