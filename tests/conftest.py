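import numpy as np
import pytest

import inductionscope as isc

#: seed of the packaged synthetic study plate used across the suite
FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def sim_plate():
    """The packaged synthetic plate: 1 reference + 3 x 50 regime cultures."""
    return isc.simulate_plate(isc.default_config(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def sim_fits(sim_plate):
    """Extended-sigmoid fits of every culture on the packaged plate."""
    dataset, truths = sim_plate
    fits = [isc.fit_curve(c) for c in dataset.cultures]
    return dataset, truths, fits


def make_culture(times, scattered_light, *, well_id="A01", plate_id="P1", **meta_kwargs):
    """Minimal valid CultureRecord around a raw signal."""
    metadata = isc.CultureMetadata(plate_id=plate_id, well_id=well_id, **meta_kwargs)
    return isc.CultureRecord(
        metadata=metadata,
        times=np.asarray(times, float),
        scattered_light=np.asarray(scattered_light, float),
    )


@pytest.fixture
def toy_dataset():
    """Three wells with 5 time points each, one carrying a fluorescence channel."""
    t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    cultures = []
    for i, well in enumerate(["A01", "A02", "A03"]):
        rec = make_culture(
            t,
            10.0 + i + np.array([0.0, 1.0, 3.0, 6.0, 10.0]),
            well_id=well,
            is_reference=(well == "A01"),
            induced=(well != "A01"),
            inducer_conc=0.0 if well == "A01" else 100.0,
        )
        cultures.append(rec)
    cultures[2].fluorescence_channels["fbfp"] = np.array([0.0, 0.5, 1.5, 3.0, 5.0])
    cultures[2].final_expression = 42.0
    return isc.PlateDataset(cultures=cultures, dataset_id="toy")
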