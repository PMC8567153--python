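"""Frequency-domain harmonic features for movement classification.

Each of the 18 raw channels (two sensors x 9 axes) is Fourier-transformed
over the whole trial, so the fundamental frequency is 1/t_total.  From
each channel's one-sided spectrum the five dominant non-DC harmonics are
kept, and their amplitude ``A`` (channel units), phase shift ``P``
(radians) and peak frequency ``F`` (Hz) form the trial's feature vector:

    18 channels x 5 harmonics x {A, P, F} = 270 features.

The canonical ordering is block-major — amplitudes occupy (1-based)
positions 1-90, phases 91-180, frequencies 181-270 — and within a block
channel-major (hand ax..mz, then forearm ax..mz) with the five harmonics
innermost.  ``feature_index``/``FEATURE_NAMES`` expose the map; position
91 is the phase of the leading harmonic of the hand accelerometer X
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io import RawTrial
from .synth import CHANNELS

QUANTITIES = ("A", "P", "F")
SENSORS = ("hand", "forearm")
N_HARMONICS = 5
N_FEATURES = len(SENSORS) * len(CHANNELS) * N_HARMONICS * len(QUANTITIES)

_MIN_SAMPLES = 16


@dataclass
class Spectrum:
    """One-sided amplitude spectrum of a single channel.

    Amplitudes are normalized so a pure sinusoid of amplitude ``a`` at a
    bin frequency yields a peak of ``a``; ``coeffs`` keeps the raw
    complex DFT coefficients for phase extraction.  ``f0 = 1/t_total``
    is both the fundamental frequency and the bin spacing.
    """

    t_total: float
    f0: float
    freqs: np.ndarray
    coeffs: np.ndarray
    amps: np.ndarray


@dataclass
class HarmonicSet:
    """Amplitude, phase and frequency of the selected harmonics.

    Entries follow selection order: descending amplitude, ties broken by
    the lower frequency.  Phases lie in (-pi, pi].
    """

    A: np.ndarray
    P: np.ndarray
    F: np.ndarray


@dataclass
class FeatureVector:
    """The canonical 270-value representation of one trial."""

    values: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise InvalidParameterError(f"feature vector must have length {N_FEATURES}")
        if not np.isfinite(self.values).all():
            raise InvalidParameterError("feature values must be finite")


@dataclass
class LabeledDataset:
    """A labeled feature matrix: X is (n, 270), y holds 0/1 labels."""

    X: np.ndarray
    y: np.ndarray
    class_names: dict = field(default_factory=lambda: {0: "typical", 1: "CP"})

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise InvalidParameterError("X must be 2-D with one row per label")

    def __len__(self) -> int:
        return len(self.y)

    def to_dataframe(self) -> pd.DataFrame:
        cols = (FEATURE_NAMES if self.X.shape[1] == N_FEATURES
                else [f"f{i}" for i in range(self.X.shape[1])])
        frame = pd.DataFrame(self.X, columns=cols)
        frame["label"] = self.y
        return frame


def feature_index(quantity: str, sensor: str, channel: str, harmonic: int,
                  one_based: bool = False) -> int:
    """Position of a feature in the canonical ordering.

    ``quantity`` is 'A', 'P' or 'F'; ``sensor`` 'hand' or 'forearm';
    ``channel`` one of ``ax..mz``; ``harmonic`` 1-5 in selection order.
    """
    if quantity not in QUANTITIES:
        raise InvalidParameterError(f"unknown quantity {quantity!r}")
    if sensor not in SENSORS:
        raise InvalidParameterError(f"unknown sensor {sensor!r}")
    if channel not in CHANNELS:
        raise InvalidParameterError(f"unknown channel {channel!r}")
    if not 1 <= harmonic <= N_HARMONICS:
        raise InvalidParameterError("harmonic must be in 1..5")
    block = QUANTITIES.index(quantity)
    chan = SENSORS.index(sensor) * len(CHANNELS) + CHANNELS.index(channel)
    idx = (block * len(SENSORS) * len(CHANNELS) + chan) * N_HARMONICS + harmonic - 1
    return idx + 1 if one_based else idx


FEATURE_NAMES = [
    f"{q}_{s}_{c}_h{k}"
    for q in QUANTITIES
    for s in SENSORS
    for c in CHANNELS
    for k in range(1, N_HARMONICS + 1)
]


def channel_spectrum(series: np.ndarray, fs: float) -> Spectrum:
    """One-sided DFT of one channel, mean-detrended, amplitude-normalized."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < _MIN_SAMPLES:
        raise InvalidParameterError(
            f"series must be 1-D with at least {_MIN_SAMPLES} samples"
        )
    n = len(series)
    coeffs = np.fft.rfft(series - series.mean())
    amps = np.abs(coeffs) * 2.0 / n
    amps[0] = np.abs(coeffs[0]) / n
    if n % 2 == 0:
        amps[-1] = np.abs(coeffs[-1]) / n
    t_total = n / fs
    return Spectrum(
        t_total=t_total,
        f0=1.0 / t_total,
        freqs=np.fft.rfftfreq(n, 1.0 / fs),
        coeffs=coeffs,
        amps=amps,
    )


def extract_harmonics(spec: Spectrum, k: int = N_HARMONICS,
                      mode: str = "peaks") -> HarmonicSet:
    """Pick the k dominant harmonics from a channel spectrum.

    ``mode='peaks'`` (default) keeps the k largest-amplitude non-DC
    bins, descending amplitude with ties broken by lower frequency, so
    the recorded peak frequencies carry information.  ``mode='fundamental'``
    instead reads the bins at 1..k times the fundamental, making F
    degenerate; it is kept for comparability with that alternative
    definition.
    """
    non_dc = len(spec.amps) - 1
    if non_dc < k:
        raise InvalidParameterError(f"spectrum has {non_dc} non-DC bins, need {k}")
    if mode == "peaks":
        amps = spec.amps[1:]
        freqs = spec.freqs[1:]
        order = np.lexsort((freqs, -amps))[:k]
        idx = order + 1
    elif mode == "fundamental":
        idx = np.arange(1, k + 1)
    else:
        raise InvalidParameterError(f"unknown harmonic mode {mode!r}")
    phases = np.angle(spec.coeffs[idx])
    phases = np.where(phases <= -np.pi, phases + 2 * np.pi, phases)
    return HarmonicSet(A=spec.amps[idx], P=phases, F=spec.freqs[idx])


def build_feature_vector(trial: RawTrial, k: int = N_HARMONICS,
                         mode: str = "peaks") -> FeatureVector:
    """The 270-feature frequency-domain representation of one trial."""
    blocks = {"A": [], "P": [], "F": []}
    for stream in (trial.hand, trial.forearm):
        for c in range(len(CHANNELS)):
            harm = extract_harmonics(channel_spectrum(stream[:, c], trial.fs), k, mode)
            blocks["A"].append(harm.A)
            blocks["P"].append(harm.P)
            blocks["F"].append(harm.F)
    values = np.concatenate([np.concatenate(blocks[q]) for q in QUANTITIES])
    return FeatureVector(values=values, label=trial.label)


def build_dataset(trials, k: int = N_HARMONICS, mode: str = "peaks") -> LabeledDataset:
    """Feature vectors for a list of labeled trials, order preserved."""
    vectors = []
    labels = []
    for i, trial in enumerate(trials):
        if trial.label is None:
            raise InvalidParameterError(f"trial {i} has no label")
        fv = build_feature_vector(trial, k, mode)
        vectors.append(fv.values)
        labels.append(trial.label)
    X = (np.asarray(vectors, dtype=float) if vectors
         else np.empty((0, N_FEATURES)))
    return LabeledDataset(X=X, y=np.asarray(labels, dtype=int))


def write_csv(dataset: LabeledDataset, path) -> None:
    """Feature matrix as CSV: one row per trial, 270 columns plus label."""
    dataset.to_dataframe().to_csv(path, index=False)


def read_csv(path) -> LabeledDataset:
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise InvalidParameterError(f"{path}: missing 'label' column")
    y = frame.pop("label").to_numpy(dtype=int)
    return LabeledDataset(X=frame.to_numpy(dtype=float), y=y)


def write_arff(dataset: LabeledDataset, path, relation: str = "imuwrist") -> None:
    """Feature matrix in the attribute-relation text format (ARFF)."""
    names = (FEATURE_NAMES if dataset.X.shape[1] == N_FEATURES
             else [f"f{i}" for i in range(dataset.X.shape[1])])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@RELATION {relation}\n\n")
        for name in names:
            fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
        fh.write("@ATTRIBUTE class {0,1}\n\n@DATA\n")
        for row, label in zip(dataset.X, dataset.y):
            fh.write(",".join(f"{v:.10g}" for v in row) + f",{label}\n")
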