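import numpy as np
import pytest

from segclock.presets import (DiscretePeakCount, GeneratorPreset, NormalSpec,
                              RatioLaw)


def make_preset(**overrides) -> GeneratorPreset:
    """A small, fast culture-style preset; override fields per test."""
    base = dict(
        condition_name="test",
        n_peaks_dist=DiscretePeakCount(mean=3.0, sd=1.0, lo=1, hi=6),
        p0=45.0,
        first_peak_mean=100.0,
        first_peak_sd=20.0,
        duration=600.0,
        onset_delay_dist=NormalSpec(mean=15.0, sd=20.0),
    )
    base.update(overrides)
    return GeneratorPreset(**base)


def deterministic_preset(n_peaks: int = 4, period_ratio: float = 1.0,
                         amp_ratio: float = 1.0, **overrides) -> GeneratorPreset:
    """Noise-free preset with degenerate distributions: every cell is
    identical, periods compound by exactly ``period_ratio``."""
    base = dict(
        condition_name="det",
        n_peaks_dist=DiscretePeakCount(mean=float(n_peaks), sd=0.0,
                                       lo=1, hi=max(n_peaks, 2)),
        p0=45.0,
        slow_ratio_dist=RatioLaw(p_gt_1=0.5, sigma_log=1e-9,
                                 mu_log_override=float(np.log(period_ratio))),
        amp_ratio_dist=RatioLaw(p_gt_1=0.5, sigma_log=1e-9,
                                mu_log_override=float(np.log(amp_ratio))),
        first_peak_mean=120.0,
        first_peak_sd=0.0,
        amp0_sd=0.0,
        noise_sd=0.0,
        onset_delay_dist=NormalSpec(mean=20.0, sd=0.0),
        clear_rise_prob=1.0,
        duration=700.0,
    )
    base.update(overrides)
    return GeneratorPreset(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
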