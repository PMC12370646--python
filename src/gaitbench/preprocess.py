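"""Raw IMU recording model, noise filtering and orientation estimation.

A shuttle-walk assessment is captured by ten body-worn inertial sensors
(3-axis accelerometer in m/s^2, 3-axis gyroscope in deg/s) sampled
uniformly at 100 Hz.  This module holds the in-memory recording container
and the first two pipeline stages:

* zero-phase Butterworth low-pass filtering (noise suppression that keeps
  the gait band, which lives below ~10 Hz), and
* orientation estimation via a complementary filter, turning raw channels
  into sagittal/coronal tilt (degrees, relative to the gravity vertical;
  backward positive, forward negative) and an unwrapped heading angle
  (integrated vertical-axis angular rate).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate as _integrate
from scipy import signal as _sig

#: Sensor placement of the assessment, in canonical order.
SENSOR_LAYOUT = (
    "waist",
    "chest",
    "wrist_l",
    "wrist_r",
    "thigh_l",
    "thigh_r",
    "shank_l",
    "shank_r",
    "foot_l",
    "foot_r",
)

#: Channel order of every per-sensor data block.
CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

GRAVITY = 9.81  # m/s^2


class ConfigurationError(ValueError):
    """Raised for physically impossible processing parameters."""


@dataclasses.dataclass
class RawRecording:
    """One participant's synchronous multi-sensor IMU streams.

    ``data`` maps each sensor name of :data:`SENSOR_LAYOUT` to an
    ``(n_samples, 6)`` float array with columns :data:`CHANNELS`.
    """

    participant_id: str
    fs: float
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        missing = [s for s in SENSOR_LAYOUT if s not in self.data]
        if missing:
            raise ValueError(f"missing sensors: {missing}")
        lengths = {self.data[s].shape[0] for s in SENSOR_LAYOUT}
        if len(lengths) != 1:
            raise ValueError("all sensor streams must have equal length")
        for s in SENSOR_LAYOUT:
            block = np.asarray(self.data[s], dtype=float)
            if block.ndim != 2 or block.shape[1] != 6:
                raise ValueError(f"sensor {s}: expected (n, 6) array")
            if not np.all(np.isfinite(block)):
                raise ValueError(f"sensor {s}: non-finite samples")
            self.data[s] = block

    @property
    def n_samples(self) -> int:
        return int(self.data[SENSOR_LAYOUT[0]].shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def acc(self, sensor: str) -> np.ndarray:
        """(n, 3) accelerometer block of one sensor, m/s^2."""
        return self.data[sensor][:, :3]

    def gyr(self, sensor: str) -> np.ndarray:
        """(n, 3) gyroscope block of one sensor, deg/s."""
        return self.data[sensor][:, 3:]

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.participant_id, self.fs, {s: self.data[s].copy() for s in SENSOR_LAYOUT}
        )

    # -- serialization ----------------------------------------------------

    def to_frame(self, sensor: str) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        frame = pd.DataFrame(self.data[sensor], columns=list(CHANNELS))
        frame.insert(0, "t_s", t)
        return frame

    def save(self, directory: str | Path, fmt: str = "csv") -> list[Path]:
        """Write one ``{participant}_{sensor}.csv`` (or ``.parquet``) per sensor."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for sensor in SENSOR_LAYOUT:
            frame = self.to_frame(sensor)
            path = directory / f"{self.participant_id}_{sensor}.{fmt}"
            if fmt == "csv":
                frame.to_csv(path, index=False, float_format="%.6f")
            elif fmt == "parquet":
                frame.to_parquet(path, index=False)
            else:
                raise ValueError(f"unknown format {fmt!r}")
            paths.append(path)
        return paths

    @classmethod
    def load(cls, directory: str | Path, participant_id: str, fmt: str = "csv") -> "RawRecording":
        directory = Path(directory)
        data = {}
        fs = None
        for sensor in SENSOR_LAYOUT:
            path = directory / f"{participant_id}_{sensor}.{fmt}"
            frame = pd.read_csv(path) if fmt == "csv" else pd.read_parquet(path)
            if fs is None:
                dt = np.diff(frame["t_s"].to_numpy()[:50])
                fs = 1.0 / float(np.median(dt))
            data[sensor] = frame[list(CHANNELS)].to_numpy(dtype=float)
        return cls(participant_id, float(round(fs, 6)), data)


@dataclasses.dataclass
class AngleSeries:
    """Per-sensor orientation angles derived from a recording.

    ``data`` maps sensor name to an ``(n, 3)`` array with columns
    ``(sagittal_tilt_deg, coronal_tilt_deg, heading_deg)``.  Tilt uses the
    clinical sign convention backward positive / forward negative; heading
    is continuous (unwrapped) and starts at 0.
    """

    participant_id: str
    fs: float
    data: dict[str, np.ndarray]

    def sagittal(self, sensor: str) -> np.ndarray:
        return self.data[sensor][:, 0]

    def coronal(self, sensor: str) -> np.ndarray:
        return self.data[sensor][:, 1]

    def heading(self, sensor: str) -> np.ndarray:
        return self.data[sensor][:, 2]

    @property
    def n_samples(self) -> int:
        return int(self.data[SENSOR_LAYOUT[0]].shape[0])

    def to_frame(self, sensor: str) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        frame = pd.DataFrame(self.data[sensor], columns=["sag_deg", "cor_deg", "heading_deg"])
        frame.insert(0, "t_s", t)
        return frame


def lowpass(recording: RawRecording, cutoff_hz: float = 12.0, order: int = 4) -> RawRecording:
    """Zero-phase low-pass filter every channel of every sensor.

    A forward-backward (filtfilt) Butterworth filter: no phase distortion,
    output length equals input length.  ``cutoff_hz`` must lie strictly
    below the Nyquist frequency.
    """
    nyquist = recording.fs / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) for fs={recording.fs}"
        )
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=recording.fs, output="sos")
    out = {}
    for sensor in SENSOR_LAYOUT:
        out[sensor] = _sig.sosfiltfilt(sos, recording.data[sensor], axis=0)
    return RawRecording(recording.participant_id, recording.fs, out)


def _acc_tilt(acc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gravity-referenced tilt angles (deg) from an accelerometer block."""
    ax, ay, az = acc[:, 0], acc[:, 1], acc[:, 2]
    sag = np.degrees(np.arctan2(-ay, az))
    cor = np.degrees(np.arctan2(ax, np.sqrt(ay * ay + az * az)))
    return sag, cor


def _complementary(angle_acc: np.ndarray, rate: np.ndarray, fs: float, alpha: float) -> np.ndarray:
    # angle[t] = alpha * (angle[t-1] + rate[t]*dt) + (1-alpha) * angle_acc[t]
    # which is an IIR filter with input u[t] = alpha*rate[t]*dt + (1-alpha)*angle_acc[t].
    dt = 1.0 / fs
    u = alpha * rate * dt + (1.0 - alpha) * angle_acc
    zi = _sig.lfiltic([1.0], [1.0, -alpha], [angle_acc[0]])
    out, _ = _sig.lfilter([1.0], [1.0, -alpha], u, zi=zi)
    return out


def estimate_orientation(recording: RawRecording, gyro_weight: float = 0.98) -> AngleSeries:
    """Estimate per-sensor tilt and heading series.

    Tilt blends accelerometer-derived gravity angles with integrated
    gyroscope rates (complementary filter, ``gyro_weight`` to the gyro
    path); heading is the cumulative integral of the vertical-axis angular
    rate.  A static sensor aligned with gravity yields tilt ~ 0.
    """
    out = {}
    for sensor in SENSOR_LAYOUT:
        acc = recording.acc(sensor)
        gyr = recording.gyr(sensor)
        norm = np.linalg.norm(acc, axis=1)
        if np.std(norm) < 1e-9 and abs(np.mean(norm) - GRAVITY) > 0.2 * GRAVITY:
            warnings.warn(
                f"sensor {sensor}: accelerometer magnitude {np.mean(norm):.2f} m/s^2 "
                "with zero variance; sensor may be detached",
                stacklevel=2,
            )
        sag_acc, cor_acc = _acc_tilt(acc)
        sag = _complementary(sag_acc, gyr[:, 1], recording.fs, gyro_weight)
        cor = _complementary(cor_acc, gyr[:, 0], recording.fs, gyro_weight)
        heading = np.concatenate(
            [[0.0], _integrate.cumulative_trapezoid(gyr[:, 2], dx=1.0 / recording.fs)]
        )
        out[sensor] = np.column_stack([sag, cor, heading])
    return AngleSeries(recording.participant_id, recording.fs, out)


def detrend_heading(heading: np.ndarray, period_deg: float = 180.0) -> np.ndarray:
    """Remove linear gyro-integration drift from a heading series.

    Assumes the assessment starts and ends at rest with a net rotation
    that is a whole multiple of ``period_deg`` (each 180-degree turn of
    the shuttle protocol adds one period).  Only the linear ramp between
    the true and measured end heading is removed, preserving the peak
    structure the turn segmentation relies on.
    """
    heading = np.asarray(heading, dtype=float)
    n = heading.size
    if n < 2:
        return heading.copy()
    residual = heading[-1] - np.round(heading[-1] / period_deg) * period_deg
    return heading - residual * np.arange(n) / (n - 1)
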