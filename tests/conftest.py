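import numpy as np
import pytest

from tectotune import PopulationConfig, make_protocol


@pytest.fixture(scope="session")
def default_protocol():
    return make_protocol()


@pytest.fixture(scope="session")
def tiny_protocol():
    """5-frame schedule handy for hand-checkable ΔF/F arithmetic."""
    return make_protocol({
        "sizes_deg": (10.0,), "n_repetitions": 1, "pre_session_s": 1.0,
        "pause_duration_s": 0.5, "stim_duration_s": 1.0,
        "post_session_s": 0.0, "frame_rate_hz": 2.0})


@pytest.fixture
def delta_neuron_config():
    """Noiseless neuron with instantaneous kinetics and a near-delta tuning
    curve centered on 10°: responds only during 10° stimulation."""
    return PopulationConfig(
        n_neurons=1, seed=7, noise_sd=0.0, tau_rise_s=0.0, tau_decay_s=0.0,
        mean_preferred_log_size=np.log10(10.0), preferred_sd_log10=0.0,
        ap_gradient_slope=0.0, tuning_width_log10=0.01,
        peak_dff_mean=1.0, peak_dff_sd=0.0)
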