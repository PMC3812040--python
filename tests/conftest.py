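import numpy as np
import pytest

from actomotility import mockvideo as mv
from actomotility import motorsim as ms
from actomotility import features as ft


@pytest.fixture(scope="session")
def fast_params():
    """Uncoupled, uniform-attachment parameter set for closed-form oracles."""
    return ms.MotorParams(
        k_attach=8.0, k_stroke=150.0, k_detach=150.0, c_coupling=0.0,
        d_main_nm=6.0, d_second_nm=2.0, kappa_pn_nm=1.0,
        noise_sigma_nm=0.0, sigma_attach_nm=0.0, k_reengage=8.0)


@pytest.fixture(scope="session")
def baseline_params():
    return ms.baseline_params()


@pytest.fixture(scope="session")
def small_video():
    """One clean filament rendered noise-free on a small field."""
    specs = [mv.FilamentSpec(length_um=2.0, velocity_um_s=1.0,
                             start_xy_um=(6.0, 12.0), heading_rad=0.3)]
    truth = mv.build_paths(specs, 4.0, 30.0, fov_um=(25.6, 25.6))
    optics = mv.OpticsNoiseSpec(background_sd=0.0, shape_px=(320, 320))
    stack, truth = mv.render(truth, optics, seed=1)
    return stack, truth, optics


@pytest.fixture(scope="session")
def synthetic_baseline_records():
    return ft.synthetic_records(500, seed=3, condition="baseline")


def _qc_day(seed):
    """One scripted 'recording day': mock video, tracking, QC features."""
    from actomotility import traceqc as qc
    from actomotility import videoanalysis as va

    truth = mv.crossing_scenario(10, seed, duration_s=4.0,
                                 fov_um=(40.96, 40.96))
    optics = mv.OpticsNoiseSpec(background_sd=4.0,
                                brightness_fluctuation_sd=0.15,
                                brownian_sigma_um=0.01,
                                shape_px=(512, 512))
    stack, truth = mv.render(truth, optics, seed=seed + 1)
    tracked = va.analyze_stack(stack, optics.frame_rate,
                               optics.pixel_size_um)
    ids, X = qc.featurize_all(tracked, 1 / 3)
    y = qc.label_traces_from_truth(tracked, truth, ids)
    return {"tracked": tracked, "truth": truth, "ids": ids, "X": X, "y": y}


@pytest.fixture(scope="session")
def qc_day_one():
    return _qc_day(11)


@pytest.fixture(scope="session")
def qc_day_two():
    return _qc_day(77)
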