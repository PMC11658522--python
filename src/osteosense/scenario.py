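"""Synthetic probe-advance traces: the generator behind end-to-end tests.

A trajectory is a sequence of labelled tissue segments (cancellous, then a
cortical wall, say) swept by the probe tip.  For every ADC sample the
generator looks up the labelled tissue's collected reflectance at the
active wavelength (registry reference values by default, or fresh Monte
Carlo estimates / custom values), pushes it through the photocurrent
model, adds photocurrent-stage noise, maps it through the amplifier's
steady-state transfer and quantizes it to an ADC code — yielding exactly
the interleaved stream the controller loop consumes.

Noise model (the device's design tables carry no noise figures; these are
order-of-magnitude physical estimates, injected where the physics puts
them):

* shot noise: Gaussian with variance 2 q I B, B = sample_rate / 2;
* relative intensity noise: multiplicative Gaussian, sigma relative to I;
* quantization: the only ADC-stage noise.

Everything is deterministic per seed, and every trace can be written as a
CSV with a JSON sidecar of its generating spec for exact replay.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import circuits
from .acquisition import (AcquisitionConfig, FeedbackFrame, adc_quantize,
                          baseline_code, run_feedback_loop, schedule_channels)
from .registry import reference_reflectance
from .signal_chain import default_channel_params, incident_power, photocurrent

__all__ = [
    "TrajectorySpec",
    "ProbeTrace",
    "generate_trace",
    "breach_detection_latency",
    "classification_performance",
]

_Q_E = 1.602176634e-19


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for one synthetic probe advance.

    ``segments`` is a list of (tissue label, duration in seconds); labels
    must resolve in the registry or in ``custom_reflectance`` (keyed by
    (label, wavelength_nm)).  ``blend_ms`` linearly blends the reflectance
    across each transition over the stated time (0 = instantaneous step).
    ``eta_scale`` rescales both coupling efficiencies of every channel,
    emulating hardware whose couplings miss the design estimate.
    """

    segments: tuple = (("cancellous", 1.0), ("cortical", 1.0))
    rng_seed: int = 0
    shot_noise: bool = True
    rin_sigma: float = 0.0
    i_dark: float = 0.0
    blend_ms: float = 0.0
    eta_scale: float = 1.0
    custom_reflectance: tuple = ()   # ((label, wavelength_nm, r), ...)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        if any(d <= 0 for _, d in self.segments):
            raise ValueError("segment durations must be positive")
        if self.rin_sigma < 0 or self.blend_ms < 0:
            raise ValueError("rin_sigma and blend_ms must be >= 0")
        if self.eta_scale <= 0:
            raise ValueError("eta_scale must be positive")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    def boundaries(self) -> list[tuple[float, str]]:
        """Segment start times with labels."""
        out, t = [], 0.0
        for label, d in self.segments:
            out.append((t, label))
            t += d
        return out

    def label_at(self, t: float) -> str:
        lab = self.segments[0][0]
        for start, label in self.boundaries():
            if t >= start:
                lab = label
        return lab

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TrajectorySpec":
        d = json.loads(text)
        d["segments"] = tuple((str(l), float(x)) for l, x in d["segments"])
        d["custom_reflectance"] = tuple(
            (str(l), int(w), float(r)) for l, w, r in d["custom_reflectance"])
        return cls(**d)


@dataclass
class ProbeTrace:
    """Per-sample synthetic record plus the config that produced it."""

    df: pd.DataFrame          # t, channel_nm, tissue, i_pd_a, v_out_v, adc_code
    spec: TrajectorySpec
    acq: AcquisitionConfig
    tia: circuits.TIAParams
    baseline: int

    def frames(self) -> list[FeedbackFrame]:
        return run_feedback_loop(self.df["adc_code"].to_numpy(),
                                 self.df["channel_nm"].to_numpy(),
                                 self.acq, baseline=self.baseline)

    def frames_df(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(f) for f in self.frames()])

    def save(self, basepath) -> tuple[Path, Path]:
        """Write ``<base>.csv`` plus a ``<base>.spec.json`` sidecar holding
        the generating spec and seed for exact replay."""
        base = Path(basepath)
        csv_path = base.with_suffix(".csv")
        sidecar = base.with_suffix(".spec.json")
        self.df.to_csv(csv_path, index=False)
        sidecar.write_text(json.dumps({
            "spec": asdict(self.spec),
            "acquisition": asdict(self.acq),
            "tia": asdict(self.tia),
            "baseline": self.baseline,
        }, indent=1))
        return csv_path, sidecar

    @classmethod
    def replay(cls, sidecar_path) -> "ProbeTrace":
        """Regenerate a trace from its sidecar (bit-identical per seed)."""
        meta = json.loads(Path(sidecar_path).read_text())
        spec = TrajectorySpec.from_json(json.dumps(meta["spec"]))
        return generate_trace(spec,
                              tia=circuits.TIAParams(**meta["tia"]),
                              acq=AcquisitionConfig(**meta["acquisition"]))


def _reflectance_lookup(spec: TrajectorySpec, registry_path=None):
    table = {(l, w): r for l, w, r in spec.custom_reflectance}

    def lookup(label: str, wl: int) -> float:
        if (label, wl) in table:
            return table[(label, wl)]
        try:
            return reference_reflectance(label, wl, registry_path)
        except KeyError as exc:
            raise ValueError(
                f"tissue label {label!r} has no reflectance at {wl} nm: "
                "add it to custom_reflectance or the registry") from exc
    return lookup


def generate_trace(spec: TrajectorySpec,
                   tia: circuits.TIAParams = circuits.TIAParams(),
                   acq: AcquisitionConfig = AcquisitionConfig(),
                   registry_path: str | None = None) -> ProbeTrace:
    """Synthesize the interleaved ADC stream for one probe advance.

    Per sample: reflectance of the labelled tissue at the active
    wavelength (linearly blended across transitions if ``blend_ms`` > 0)
    -> photocurrent -> shot / relative-intensity noise -> steady-state
    amplifier output -> ADC code.  Deterministic for a fixed
    ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    lookup = _reflectance_lookup(spec, registry_path)
    sched = schedule_channels(acq, spec.duration)
    chains = {wl: default_channel_params(wl, registry_path)
              for wl in (940, 1310)}
    bounds = spec.boundaries()
    blend_s = spec.blend_ms * 1e-3
    bandwidth = acq.sample_rate / 2.0

    tissues, currents, volts = [], np.empty(len(sched)), np.empty(len(sched))
    for k, (t, wl) in enumerate(zip(sched["t"], sched["channel_nm"])):
        wl = int(wl)
        label = spec.label_at(t)
        r = lookup(label, wl)
        if blend_s > 0:
            for start, lab in bounds[1:]:
                if start <= t < start + blend_s:
                    prev = spec.label_at(start - 1e-12)
                    w = (t - start) / blend_s
                    r = (1 - w) * lookup(prev, wl) + w * lookup(lab, wl)
                    break
        ch = chains[wl]
        i_sig = photocurrent(
            incident_power(ch.p_ld, ch.eta_ld * spec.eta_scale, r,
                           ch.eta_pd * spec.eta_scale),
            ch.r_pd, spec.i_dark)
        i = i_sig
        if spec.shot_noise:
            i += rng.normal(0.0, math.sqrt(2.0 * _Q_E * max(i_sig, 0.0)
                                           * bandwidth))
        if spec.rin_sigma > 0:
            i += rng.normal(0.0, spec.rin_sigma * i_sig)
        i = max(i, 0.0)
        tissues.append(label)
        currents[k] = i
        volts[k] = circuits.steady_state_output(i, tia)[1]

    df = sched.assign(tissue=tissues, i_pd_a=currents, v_out_v=volts,
                      adc_code=adc_quantize(volts, acq))
    df = df[["t", "channel_nm", "tissue", "i_pd_a", "v_out_v", "adc_code"]]
    base = acq.baseline_counts
    if base is None:
        base = baseline_code(tia.v_bias, acq)
    return ProbeTrace(df=df, spec=spec, acq=acq, tia=tia, baseline=base)


def breach_detection_latency(trace: ProbeTrace) -> float:
    """Delay (ms) from the labelled tissue transition to the end of the
    first buzzer-on frame.

    The trace must contain exactly one transition.  With zero noise the
    latency is bounded by two windows (one possibly mixed window plus one
    window fully inside the new tissue).  Returns ``inf`` if the buzzer
    never sounds.
    """
    labels = trace.df["tissue"].to_numpy()
    change = np.flatnonzero(labels[1:] != labels[:-1])
    if len(change) != 1:
        raise ValueError(
            f"trace must contain exactly one tissue transition, found "
            f"{len(change)}")
    # the true transition happens between samples; the segment clock is
    # authoritative
    t0 = trace.spec.boundaries()[1][0]
    for frame in trace.frames():
        if frame.valid and frame.buzzer and frame.t_end > t0:
            return (frame.t_end - t0) * 1e3
    return float("inf")


def _pure_frame_labels(trace: ProbeTrace) -> list[str | None]:
    """Tissue label per frame, or None for windows that straddle tissues."""
    labels = trace.df["tissue"].to_numpy()
    spw = trace.acq.samples_per_window
    out = []
    for i in range(len(labels) // spw):
        w = labels[i * spw:(i + 1) * spw]
        out.append(w[0] if (w == w[0]).all() else None)
    return out


def classification_performance(n_runs: int, spec: TrajectorySpec,
                               noise_sigmas=(0.0,),
                               tia: circuits.TIAParams = circuits.TIAParams(),
                               acq: AcquisitionConfig = AcquisitionConfig(),
                               confidence: float = 0.95) -> pd.DataFrame:
    """Per-tissue buzzer accuracy and latency over repeated seeded runs.

    For each relative-intensity-noise level, *n_runs* traces are generated
    (seeds ``spec.rng_seed + run``), frames over windows that lie entirely
    inside one tissue are scored (buzzer on iff cortical), and accuracies
    are reported with Wilson binomial confidence intervals.  Latency
    statistics are collected when the spec holds exactly one transition.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for sigma in noise_sigmas:
        counts = {"cancellous": [0, 0], "cortical": [0, 0]}  # [correct, total]
        latencies = []
        for run in range(n_runs):
            s = TrajectorySpec(**{**asdict(spec),
                                  "rin_sigma": float(sigma),
                                  "rng_seed": spec.rng_seed + run})
            trace = generate_trace(s, tia=tia, acq=acq)
            frames = trace.frames()
            for frame, label in zip(frames, _pure_frame_labels(trace)):
                if label is None or not frame.valid or label not in counts:
                    continue
                counts[label][1] += 1
                if frame.buzzer == (label == "cortical"):
                    counts[label][0] += 1
            if len(s.segments) == 2 and s.segments[0][0] == "cancellous":
                lat = breach_detection_latency(trace)
                if math.isfinite(lat):
                    latencies.append(lat)
        row = {"rin_sigma": float(sigma)}
        for tissue, (k, n) in counts.items():
            if n:
                ci = stats.binomtest(k, n).proportion_ci(
                    confidence_level=confidence, method="wilson")
                row.update({f"accuracy_{tissue}": k / n,
                            f"ci_low_{tissue}": ci.low,
                            f"ci_high_{tissue}": ci.high,
                            f"n_frames_{tissue}": n})
        if latencies:
            row.update({"latency_mean_ms": float(np.mean(latencies)),
                        "latency_max_ms": float(np.max(latencies)),
                        "n_detected": len(latencies)})
        rows.append(row)
    return pd.DataFrame(rows)
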