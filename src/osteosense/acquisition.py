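"""Controller-loop emulation: PWM scheduling, ADC codes, ratio, buzzer.

The microcontroller pulses the two lasers at 55 Hz (50% duty), reads the
amplifier output at 55 samples per second synchronously with the pulses —
so consecutive samples strictly alternate between the 940 nm and 1310 nm
channels — and every 200 ms averages the collected codes per channel into
the reflectance ratio

    Q = x_940 / x_1310,

where each x is the baseline-subtracted window-mean magnitude (the
inverting amplifier pulls the code *down* from the dark baseline, so the
baseline-referred magnitude is the photocurrent-proportional quantity the
threshold was designed for).  The buzzer sounds while Q strictly exceeds
the threshold Q_t = 4.75, signalling cortical bone; with the design-table
photocurrents the noiseless ratios are ~4.28 on cancellous and ~5.27 on
cortical bone.

The ADC mapping is a documented convention: single-ended, 6.144 V full
scale over the positive 15-bit code range of a 16-bit converter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "FeedbackFrame",
    "schedule_channels",
    "adc_quantize",
    "baseline_code",
    "window_ratio",
    "run_feedback_loop",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing, conversion and threshold constants of the controller loop."""

    f_pwm: float = 55.0          # laser pulse frequency, Hz
    duty: float = 0.5
    adc_bits: int = 16
    adc_full_scale: float = 6.144  # V spanning the positive code range
    sample_rate: float = 55.0    # ADC samples per second
    window: float = 0.2          # averaging period, s (user output at 1/window)
    q_threshold: float = 4.75
    baseline_counts: int | None = None  # dark-level code; None = derive from bias

    def __post_init__(self) -> None:
        if not 0 < self.duty < 1:
            raise ValueError("duty must lie in (0, 1)")
        if self.q_threshold <= 0:
            raise ValueError("q_threshold must be positive")
        if self.adc_bits < 2 or self.adc_full_scale <= 0:
            raise ValueError("invalid ADC configuration")
        if self.window * self.sample_rate < 2:
            raise ValueError("window must hold at least one sample per channel")

    @property
    def max_code(self) -> int:
        return 2 ** (self.adc_bits - 1) - 1

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window * self.sample_rate))

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.window


@dataclass(frozen=True)
class FeedbackFrame:
    """One 200 ms classifier output: window means, ratio, buzzer state.

    ``valid`` is False when a channel's baseline-subtracted signal sits
    below one LSB (quantization floor) — the ratio is then meaningless and
    the buzzer holds its previous state.
    """

    index: int
    t_end: float
    mean_940: float
    mean_1310: float
    q: float
    buzzer: bool
    valid: bool = True


def schedule_channels(cfg: AcquisitionConfig, duration: float):
    """Sample times, alternating channel labels and laser-on intervals.

    Returns a DataFrame with one row per ADC sample: ``t`` (readout time,
    s), ``channel_nm`` (940/1310, strict alternation starting at 940),
    ``on_start``/``on_end`` (the driving laser's PWM on-phase, with which
    the readout is synchronized).
    """
    import pandas as pd

    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(np.floor(duration * cfg.sample_rate + 1e-9))
    k = np.arange(n)
    t0 = k / cfg.sample_rate
    return pd.DataFrame({
        "t": t0,
        "channel_nm": np.where(k % 2 == 0, 940, 1310),
        "on_start": t0,
        "on_end": t0 + cfg.duty / cfg.f_pwm,
    })


def adc_quantize(v, cfg: AcquisitionConfig = AcquisitionConfig()):
    """Map voltages to integer ADC codes (rounded, clamped in-range).

    Scalar in, scalar out; array in, int array out.  Quantization error is
    at most half an LSB for in-range voltages.
    """
    code = np.rint(np.asarray(v, dtype=float) / cfg.adc_full_scale
                   * cfg.max_code)
    code = np.clip(code, 0, cfg.max_code).astype(np.int64)
    return int(code) if np.ndim(v) == 0 else code


def baseline_code(v_bias: float, cfg: AcquisitionConfig = AcquisitionConfig()) -> int:
    """Dark-level code: the quiescent amplifier output (the bias voltage)
    as seen by the ADC."""
    return adc_quantize(v_bias, cfg)


def window_ratio(codes_940, codes_1310, cfg: AcquisitionConfig,
                 baseline: int | None = None, prev_buzzer: bool = False,
                 index: int = 0, t_end: float | None = None) -> FeedbackFrame:
    """Fold one window's per-channel codes into a classifier frame.

    The ratio is computed on baseline-subtracted magnitudes
    ``|baseline - mean(codes)|``.  If either magnitude falls below one LSB
    the frame is flagged invalid and the buzzer keeps *prev_buzzer*.
    """
    codes_940 = np.asarray(codes_940, dtype=float)
    codes_1310 = np.asarray(codes_1310, dtype=float)
    if codes_940.size == 0 or codes_1310.size == 0:
        raise ValueError("need at least one sample per channel in a window")
    if baseline is None:
        baseline = cfg.baseline_counts
    if baseline is None:
        raise ValueError("no baseline: set cfg.baseline_counts or pass baseline=")
    m940 = float(codes_940.mean())
    m1310 = float(codes_1310.mean())
    s940 = abs(baseline - m940)
    s1310 = abs(baseline - m1310)
    t_end = float(t_end) if t_end is not None else (index + 1) * cfg.window
    if s940 < 1.0 or s1310 < 1.0:
        return FeedbackFrame(index, t_end, m940, m1310, float("nan"),
                             buzzer=prev_buzzer, valid=False)
    q = s940 / s1310
    return FeedbackFrame(index, t_end, m940, m1310, q,
                         buzzer=q > cfg.q_threshold, valid=True)


def run_feedback_loop(codes, channels_nm, cfg: AcquisitionConfig,
                      baseline: int | None = None) -> list[FeedbackFrame]:
    """Window an interleaved ADC stream into classifier frames.

    *codes* and *channels_nm* are parallel per-sample sequences (channel
    labels 940/1310).  Samples are grouped into consecutive windows of
    ``cfg.samples_per_window``; a truncated final window is dropped (and
    logged).  Frames come out at exactly ``1/window`` Hz, one per window,
    never mixing samples across windows.
    """
    codes = np.asarray(codes)
    channels_nm = np.asarray(channels_nm)
    if codes.shape != channels_nm.shape:
        raise ValueError("codes and channels_nm must have equal length")
    spw = cfg.samples_per_window
    n_windows = len(codes) // spw
    if len(codes) % spw:
        logger.debug("dropping truncated final window (%d samples)",
                     len(codes) % spw)
    frames: list[FeedbackFrame] = []
    buzzer = False
    for i in range(n_windows):
        sl = slice(i * spw, (i + 1) * spw)
        w_codes, w_ch = codes[sl], channels_nm[sl]
        frame = window_ratio(w_codes[w_ch == 940], w_codes[w_ch == 1310],
                             cfg, baseline=baseline, prev_buzzer=buzzer,
                             index=i)
        buzzer = frame.buzzer
        frames.append(frame)
    return frames
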