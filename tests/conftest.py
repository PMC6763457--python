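import numpy as np
import pytest

import microdyn as md


@pytest.fixture(scope="session")
def montage19() -> md.Montage:
    return md.standard_montage(19)


@pytest.fixture(scope="session")
def montage64() -> md.Montage:
    return md.standard_montage(64)


@pytest.fixture(scope="session")
def canonical19(montage19) -> md.TemplateSet:
    return md.make_canonical_templates(montage19)


@pytest.fixture(scope="session")
def fast_synth_kwargs() -> dict:
    """A small but realistic study condition for pipeline-level tests."""
    return dict(
        n_channels=19,
        montage_name="standard_1020_19",
        sampling_rate=250.0,
        record_seconds=40.0,
        n_per_group=4,
    )


def make_label_row(run_lengths, run_classes):
    """Build one epoch row of labels from explicit runs."""
    return np.repeat(np.asarray(run_classes, dtype=np.int8),
                     np.asarray(run_lengths, dtype=np.int64))
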