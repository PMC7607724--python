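import numpy as np
import pytest

from pupilgaze.data import PipelineConfig, SampleTrace, TrialInfo


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def trace_factory():
    """Build a uniform-grid SampleTrace from a pupil array (gaze optional)."""

    def make(pupil, fs=500.0, t0=-3.0, gaze_x=None, gaze_y=None, blinks=()):
        pupil = np.asarray(pupil, dtype=float)
        n = pupil.size
        t = t0 + np.arange(n) / fs
        zeros = np.zeros(n)
        return SampleTrace(
            sampling_rate=fs,
            t=t,
            pupil=pupil,
            gaze_x=zeros if gaze_x is None else np.asarray(gaze_x, float),
            gaze_y=zeros if gaze_y is None else np.asarray(gaze_y, float),
            blink_intervals=list(blinks),
        )

    return make


@pytest.fixture
def trial_factory():
    def make(duration=1.4, clarity="high_snr", ambiguity="LA",
             participant="P001", response="related", probe_related=True,
             block=1, experiment=1, rt=1.0):
        return TrialInfo(
            participant_id=participant,
            experiment=experiment,
            block=block,
            clarity=clarity,
            ambiguity=ambiguity,
            sentence_duration_s=duration,
            probe_related=probe_related,
            response=response,
            response_time_s=None if response == "none" else rt,
        )

    return make
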