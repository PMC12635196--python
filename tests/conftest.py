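import numpy as np
import pytest

from crossrun_dia.data_model_io import Chromatogram, Fragment, LibraryEntry
from crossrun_dia.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, shift-free 3-run dataset: every peak exactly recoverable."""
    return generate_dataset(
        SyntheticConfig(n_runs=3, n_peptides=12, noise_sd=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def shifted_dataset():
    """Linearly shifted, moderately noisy 4-run dataset with decoys."""
    return generate_dataset(
        SyntheticConfig(
            n_runs=4,
            n_peptides=25,
            rt_shift_model="linear",
            shift_magnitude=30.0,
            noise_sd=40.0,
            decoy_fraction=1.0,
            seed=5,
        )
    )


@pytest.fixture()
def toy_entry():
    ints = [1000.0, 800.0, 500.0, 300.0, 200.0, 100.0]
    return LibraryEntry(
        precursor_id="PEP_TOY",
        peptide_sequence="ELVISLIVESK",
        charge=2,
        precursor_mz=612.3,
        irt=42.0,
        fragments=[Fragment(f"f{i}", 400.0 + 50 * i, v) for i, v in enumerate(ints)],
    )


@pytest.fixture()
def gaussian_chromatogram(toy_entry):
    """A clean co-eluting Gaussian peak group at 100 s on a 2-s grid."""
    rt = np.arange(0.0, 200.0, 2.0)
    shape = np.exp(-0.5 * ((rt - 100.0) / 8.0) ** 2)
    lib = toy_entry.library_intensities
    traces = (lib / lib.max())[:, None] * 1000.0 * shape[None, :]
    ms1 = 1500.0 * shape
    return Chromatogram("run_x", toy_entry.precursor_id, rt, traces, ms1)
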