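import numpy as np
import pandas as pd
import pytest

from fallsense.io import EventAnnotation, ImuRecording, SAMPLE_COLUMNS
from fallsense.preprocessing import Window
from fallsense.synthetic import (GeneratorSpec, generate_dataset,
                                 planted_feature_matrix)
from fallsense.training import fit


def make_recording(n=200, klass="NON_FALL", subtype="standing",
                   lob=None, impact=None, accel=None, gyro=None,
                   recording_id="rec-0"):
    """Hand-built recording on the exact 1/40 s grid."""
    t = np.arange(n) / 40.0
    if accel is None:
        accel = np.zeros((n, 3))
        accel[:, 2] = 1.0
    if gyro is None:
        gyro = np.zeros((n, 3))
    samples = pd.DataFrame(np.column_stack([t, accel, gyro]).reshape(n, 7),
                           columns=list(SAMPLE_COLUMNS))
    ann = EventAnnotation(klass=klass, subtype=subtype, active_start=0.0,
                          active_end=float(t[-1]) if n else 1.0,
                          loss_of_balance_t=lob, impact_t=impact)
    return ImuRecording(recording_id=recording_id, subject_id="s0",
                        samples=samples, annotation=ann)


def make_window(samples=None, end_time=0.975, start_index=0):
    if samples is None:
        samples = np.zeros((40, 6))
        samples[:, 2] = 1.0
    return Window(source_id="w", start_index=start_index,
                  samples=np.asarray(samples, dtype=float), end_time=end_time)


@pytest.fixture(scope="session")
def planted():
    """600-row matrix with one decisive feature, 20 noise, 1 constant."""
    return planted_feature_matrix(n=600, n_noise=20, seed=0)


@pytest.fixture(scope="session")
def planted_model(planted):
    """Small booster fitted on the planted matrix (shared across tests)."""
    params = {"n_estimators": 150, "max_depth": 4, "learning_rate": 0.2}
    return fit("xgb", planted, params=params, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic recordings, enough for stratified 5-fold work on windows.

    Fall recordings yield a critical window only when a window boundary
    lands inside the (short) critical phase, so fall classes are over-
    represented at the recording level here.
    """
    return generate_dataset(GeneratorSpec.balanced(120, 60, 40, seed=3))
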