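"""Preprocessing: decimation, windowing, metadata discretization, one-hot.

The pipeline mirrors a standard single-lead reconstruction setup: 10-s
records sampled at 500 Hz are decimated by 5 (every 5th sample, no
anti-aliasing filter — the source signals are already denoised and the QRS
sharpness is to be preserved), a centered 512-sample window (5.12 s at
100 Hz) is cut from every lead, and the five clinical metadata fields are
discretized with guideline thresholds before one-hot encoding.

Category conventions
--------------------
* Axes (RAxis and TAxis share thresholds):
  Normal -30<=theta<=90, Left -90<theta<-30, Right 90<theta<=180,
  Extreme -180<theta<=-90 (degrees).
* QRS duration: Normal <120 ms, Prolonged >=120 ms.
* Ventricular rate: Bradycardia <60, Normal 60-100 (inclusive both ends),
  Tachycardia >100 bpm.
* QRS count per 10 s: Low <10, Normal 10-16, High >=17; the rate and count
  scales correspond through rate = 6 x count.

One-hot vectors concatenate the features in the fixed order RAxis, TAxis,
QRSDuration, VentricularRate, QRSCount, each feature's categories in the
order listed above, giving D = 4+4+2+3+3 = 16 for the full set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synth import EcgRecord, ParameterError, TARGET_LEADS


class QualityError(RuntimeError):
    """Signal too degenerate for the requested measurement."""


AXIS_CATEGORIES = ("Normal", "Left Deviation", "Right Deviation", "Extreme Deviation")
QRS_DURATION_CATEGORIES = ("Normal", "Prolonged")
RATE_CATEGORIES = ("Bradycardia", "Normal", "Tachycardia")
COUNT_CATEGORIES = ("Low", "Normal", "High")

FEATURE_ORDER = ("RAxis", "TAxis", "QRSDuration", "VentricularRate", "QRSCount")
FEATURE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "RAxis": AXIS_CATEGORIES,
    "TAxis": AXIS_CATEGORIES,
    "QRSDuration": QRS_DURATION_CATEGORIES,
    "VentricularRate": RATE_CATEGORIES,
    "QRSCount": COUNT_CATEGORIES,
}


@dataclass(frozen=True)
class MetadataRaw:
    """Continuous per-record metadata; axes may be absent (None)."""

    ventricular_rate: float
    qrs_count: float
    qrs_duration: float
    r_axis: float | None = None
    t_axis: float | None = None

    def __post_init__(self) -> None:
        for name, theta in (("r_axis", self.r_axis), ("t_axis", self.t_axis)):
            if theta is not None and not (-180.0 < theta <= 180.0):
                raise ParameterError(f"{name}={theta} outside (-180, 180]")
        for name, v in (("ventricular_rate", self.ventricular_rate),
                        ("qrs_count", self.qrs_count),
                        ("qrs_duration", self.qrs_duration)):
            if v < 0 or not np.isfinite(v):
                raise ParameterError(f"{name}={v} must be finite and >= 0")


@dataclass(frozen=True)
class MetadataCategories:
    r_axis_cat: str
    t_axis_cat: str
    qrs_duration_cat: str
    ventricular_rate_cat: str
    qrs_count_cat: str

    def as_dict(self) -> dict[str, str]:
        return {
            "RAxis": self.r_axis_cat,
            "TAxis": self.t_axis_cat,
            "QRSDuration": self.qrs_duration_cat,
            "VentricularRate": self.ventricular_rate_cat,
            "QRSCount": self.qrs_count_cat,
        }


@dataclass(frozen=True)
class WindowedPair:
    """One training example: Lead I window, 11-lead target, metadata."""

    lead1: np.ndarray  # (512,) mV at 100 Hz
    target: np.ndarray  # (11, 512) mV, leads II,III,aVR,aVL,aVF,V1..V6
    onehot: np.ndarray  # (D,) float
    record_id: str
    split: str


def decimate(signal: np.ndarray, factor: int) -> np.ndarray:
    """Direct decimation: keep every ``factor``-th sample starting at index 0.

    Deliberately applies no anti-aliasing filter (the upstream signals are
    denoised and filtering would smear the QRS).
    """
    if not float(factor).is_integer() or factor < 1:
        raise ParameterError("decimation factor must be an integer >= 1")
    factor = int(factor)
    signal = np.asarray(signal)
    if signal.shape[-1] < factor:
        raise ParameterError("signal shorter than the decimation factor")
    return signal[..., ::factor]


def extract_window(signal: np.ndarray, length: int = 512) -> np.ndarray:
    """Centered window: start = floor((T - length) / 2), same for all leads."""
    signal = np.asarray(signal)
    t = signal.shape[-1]
    if t < length:
        raise ParameterError(f"signal length {t} < window length {length}")
    start = (t - length) // 2
    return signal[..., start:start + length]


def axis_category(theta: float) -> str:
    if not (-180.0 < theta <= 180.0):
        raise ParameterError(f"axis {theta} outside (-180, 180]")
    if -30.0 <= theta <= 90.0:
        return "Normal"
    if -90.0 < theta < -30.0:
        return "Left Deviation"
    if 90.0 < theta <= 180.0:
        return "Right Deviation"
    return "Extreme Deviation"  # -180 < theta <= -90


def discretize_metadata(raw: MetadataRaw) -> MetadataCategories:
    """Map continuous metadata onto the guideline categories (total map)."""
    if raw.r_axis is None or raw.t_axis is None:
        raise ParameterError("axis fields required for discretization")
    dur = "Prolonged" if raw.qrs_duration >= 120.0 else "Normal"
    if raw.ventricular_rate < 60.0:
        rate = "Bradycardia"
    elif raw.ventricular_rate <= 100.0:
        rate = "Normal"
    else:
        rate = "Tachycardia"
    if raw.qrs_count < 10:
        count = "Low"
    elif raw.qrs_count <= 16:
        count = "Normal"
    else:
        count = "High"
    return MetadataCategories(
        r_axis_cat=axis_category(raw.r_axis),
        t_axis_cat=axis_category(raw.t_axis),
        qrs_duration_cat=dur,
        ventricular_rate_cat=rate,
        qrs_count_cat=count,
    )


def one_hot(cats: MetadataCategories,
            selected_features: Sequence[str] = FEATURE_ORDER) -> np.ndarray:
    """Concatenated one-hot encoding of the selected features.

    Feature order and within-feature category order are fixed (module
    docstring) so trained models are portable across runs.
    """
    if not selected_features:
        raise ParameterError("selected_features must be non-empty")
    unknown = set(selected_features) - set(FEATURE_ORDER)
    if unknown:
        raise ParameterError(f"unknown features: {sorted(unknown)}")
    values = cats.as_dict()
    chunks = []
    for feat in FEATURE_ORDER:
        if feat not in selected_features:
            continue
        options = FEATURE_CATEGORIES[feat]
        vec = np.zeros(len(options))
        vec[options.index(values[feat])] = 1.0
        chunks.append(vec)
    return np.concatenate(chunks)


def onehot_dim(selected_features: Sequence[str]) -> int:
    return sum(len(FEATURE_CATEGORIES[f]) for f in FEATURE_ORDER
               if f in selected_features)


def estimate_metadata_from_lead1(lead1: np.ndarray, fs: float,
                                 qrs_fraction: float = 0.25) -> MetadataRaw:
    """Estimate rate / count / QRS duration from a Lead I strip.

    R peaks come from the derivative-energy detector; the count is scaled to
    a 10-s equivalent and converted to bpm via rate = 6 x count.  The QRS
    duration is the median per-beat width of |signal| above ``qrs_fraction``
    of the R amplitude.  Frontal axes cannot be measured from a single lead
    and are returned as absent.
    """
    from .evaluate import detect_r_peaks

    lead1 = np.asarray(lead1, dtype=float)
    if lead1.size < 2 * fs:
        raise ParameterError("need at least 2 s of signal")
    peaks = detect_r_peaks(lead1, fs)
    if len(peaks) == 0:
        raise QualityError("no R peaks found in Lead I")
    duration = lead1.size / fs
    qrs_count = int(round(len(peaks) * 10.0 / duration))

    widths = []
    absx = np.abs(lead1 - np.median(lead1))
    for p in peaks:
        thr = qrs_fraction * absx[p]
        lo = p
        while lo > 0 and absx[lo - 1] >= thr:
            lo -= 1
        hi = p
        while hi < lead1.size - 1 and absx[hi + 1] >= thr:
            hi += 1
        widths.append((hi - lo + 1) * 1000.0 / fs)
    return MetadataRaw(
        ventricular_rate=6.0 * qrs_count,
        qrs_count=qrs_count,
        qrs_duration=float(np.median(widths)),
    )


def split_dataset(record_ids: Sequence[str],
                  fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> dict[str, str]:
    """Record-level random split (one record per subject: no leakage)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("split fractions must sum to 1")
    n = len(record_ids)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ParameterError(f"n={n} too small for non-empty splits")
    order = np.random.default_rng(seed).permutation(n)
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            tag = "train"
        elif rank < n_train + n_val:
            tag = "val"
        else:
            tag = "test"
        assignment[record_ids[idx]] = tag
    return assignment


def make_pairs(records: Iterable[EcgRecord], split: dict[str, str],
               selected_features: Sequence[str] = FEATURE_ORDER,
               decimation_factor: int = 5, window: int = 512,
               ) -> list[WindowedPair]:
    """Full preprocessing of records into model-ready (input, target) pairs.

    An empty ``selected_features`` sequence yields zero-length one-hot
    vectors — the time-series-only condition.
    """
    pairs = []
    for rec in records:
        sig = rec.signal_matrix()
        if rec.fs == 500:
            sig = decimate(sig, decimation_factor)
        elif rec.fs != 100:
            raise ParameterError(f"unsupported sampling rate {rec.fs}")
        sig = extract_window(sig, window)
        lead_index = {name: i for i, name in
                      enumerate(("I",) + TARGET_LEADS)}
        # signal_matrix order is I,II,III,aVR,aVL,aVF,V1..V6 == (I,)+TARGET_LEADS
        lead1 = sig[lead_index["I"]]
        target = sig[1:, :]
        if selected_features:
            cats = discretize_metadata(rec.metadata)
            vec = one_hot(cats, selected_features)
        else:
            vec = np.zeros(0)
        pairs.append(WindowedPair(lead1=lead1, target=target, onehot=vec,
                                  record_id=rec.record_id,
                                  split=split.get(rec.record_id, "train")))
    return pairs


def stack_pairs(pairs: Sequence[WindowedPair]
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack pairs into (X (n,1,512), M (n,D), Y (n,11,512)) arrays."""
    x = np.stack([p.lead1 for p in pairs])[:, None, :]
    m = np.stack([p.onehot for p in pairs]) if pairs[0].onehot.size else \
        np.zeros((len(pairs), 0))
    y = np.stack([p.target for p in pairs])
    return x, m, y
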