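"""Synthetic 12-lead ECG generator.

Each record is built from a 3-component cardiac pseudo-dipole ``(dx, dy, dz)``:
``(dx, dy)`` live in the frontal plane of the hexaxial reference system and
``dz`` is an anterior-posterior component used only for the chest leads.  A
beat is a sum of five Gaussian bumps (P, Q, R, S, T); the QRS bumps point
along the frontal QRS axis ``theta_r``, the T bump along the T axis
``theta_t``.  Limb leads are plane projections (Lead I at 0 deg, Lead II at
60 deg, angles increasing clockwise in the frontal plane as in the clinical
convention), with III and the augmented leads derived through the Einthoven /
Goldberger identities so those identities hold exactly by construction.  The
chest leads V1-V6 are a fixed full-rank linear mixture of the three dipole
components.

Because Lead I only sees ``dx = m(t) * cos(theta)``, the frontal axis is
fundamentally ambiguous from Lead I alone; the axis categories carried in the
metadata resolve that ambiguity, which is what makes metadata informative for
reconstruction here.

Noise (white Gaussian, plus an optional baseline-wander sine) is injected at
the dipole level, never per lead, so the lead identities survive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")
CHEST_LEADS = ("V1", "V2", "V3", "V4", "V5", "V6")
LEAD_NAMES = LIMB_LEADS + CHEST_LEADS
#: reconstruction targets, in fixed order
TARGET_LEADS = ("II", "III", "aVR", "aVL", "aVF") + CHEST_LEADS

WAVE_ORDER = ("P", "Q", "R", "S", "T")

# anterior-posterior weight of each wave in the dz component (unitless,
# relative to the wave amplitude); fixed so chest-lead morphology is not a
# pure copy of the frontal leads
_DZ_WEIGHTS = {"P": 0.25, "Q": -0.50, "R": 1.00, "S": 0.80, "T": 0.40}

# (dx, dy, dz) -> V1..V6 mixing matrix; full rank, graded from right-sided
# (V1, dominated by -dz) to left-sided (V6, dominated by dx) so that chest
# leads depend on the frontal axis through dx and dy
PRECORDIAL_WEIGHTS = np.array(
    [
        [0.10, -0.20, -0.90],
        [0.25, -0.10, -0.60],
        [0.45, 0.05, -0.20],
        [0.65, 0.20, 0.20],
        [0.80, 0.35, 0.45],
        [0.90, 0.45, 0.60],
    ]
)


class ParameterError(ValueError):
    """Invalid generator parameter."""


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: center offset from the R peak, amplitude, sigma."""

    center_ms: float
    amp_mv: float
    width_ms: float


@dataclass(frozen=True)
class BeatMorphology:
    """Per-wave parameters of a single heartbeat (P, Q, R, S, T)."""

    p: Wave = Wave(-180.0, 0.12, 22.0)
    q: Wave = Wave(-20.0, -0.15, 10.0)
    r: Wave = Wave(0.0, 1.00, 10.0)
    s: Wave = Wave(20.0, -0.25, 10.0)
    t: Wave = Wave(320.0, 0.35, 55.0)

    def waves(self) -> dict[str, Wave]:
        return {"P": self.p, "Q": self.q, "R": self.r, "S": self.s, "T": self.t}

    def __post_init__(self) -> None:
        w = self.waves()
        if any(w[name].width_ms <= 0 for name in WAVE_ORDER):
            raise ParameterError("wave widths must be positive")
        centers = [w[name].center_ms for name in WAVE_ORDER]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ParameterError("wave centers must be strictly ordered P<Q<R<S<T")
        if self.r.amp_mv <= 0:
            raise ParameterError("R amplitude must be positive")

    @classmethod
    def for_qrs_duration(cls, qrs_duration_ms: float, **overrides) -> "BeatMorphology":
        """Morphology whose Q/R/S placement scales with the QRS duration.

        The Q and S bumps sit at -+0.22*d around the R peak and the three QRS
        sigmas are 0.11*d, so a duration of 90 ms reproduces the default
        morphology and prolonged complexes (>=120 ms) come out visibly wide.
        """
        if qrs_duration_ms <= 0:
            raise ParameterError("qrs_duration_ms must be positive")
        d = float(qrs_duration_ms)
        off, sig = 0.22 * d, 0.11 * d
        base = cls(
            q=Wave(-off, -0.15, sig),
            r=Wave(0.0, 1.00, sig),
            s=Wave(off, -0.25, sig),
        )
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth physiological parameters of one synthetic subject."""

    theta_r: float = 45.0  # frontal QRS axis, degrees, (-180, 180]
    theta_t: float = 40.0  # frontal T axis, degrees
    heart_rate_bpm: float = 72.0
    qrs_duration_ms: float = 90.0
    rr_jitter: float = 0.02  # fractional SD of the RR interval
    noise_mv: float = 0.01  # white-noise SD injected on each dipole component
    baseline_wander_mv: float = 0.0  # amplitude of an optional 0.3 Hz sine
    precordial_weights: np.ndarray = field(
        default_factory=lambda: PRECORDIAL_WEIGHTS.copy()
    )
    duration_s: float = 10.0
    fs: float = 500.0

    def __post_init__(self) -> None:
        for name, theta in (("theta_r", self.theta_r), ("theta_t", self.theta_t)):
            if not (-180.0 < theta <= 180.0):
                raise ParameterError(f"{name}={theta} outside (-180, 180]")
        if self.heart_rate_bpm <= 0:
            raise ParameterError("heart_rate_bpm must be positive")
        if self.qrs_duration_ms <= 0:
            raise ParameterError("qrs_duration_ms must be positive")
        if self.fs not in (500.0, 500, 100.0, 100):
            raise ParameterError("sampling rate must be 500 or 100 Hz")
        w = np.asarray(self.precordial_weights, dtype=float)
        if w.shape != (6, 3):
            raise ParameterError("precordial_weights must be a 6x3 matrix")


@dataclass
class EcgRecord:
    """One 12-lead record: named signals in mV plus its metadata."""

    record_id: str
    leads: dict[str, np.ndarray]
    fs: float
    metadata: "object | None" = None  # preprocess.MetadataRaw
    params: SubjectParams | None = None
    beat_times: np.ndarray | None = None  # ground-truth R-peak times, s

    def __post_init__(self) -> None:
        if tuple(self.leads.keys()) != LEAD_NAMES:
            raise ParameterError(
                f"leads must be exactly {LEAD_NAMES} in order, got {tuple(self.leads)}"
            )
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) != 1:
            raise ParameterError("all 12 leads must have identical length")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.leads["I"])

    def signal_matrix(self) -> np.ndarray:
        """12 x T matrix in the canonical lead order."""
        return np.stack([self.leads[name] for name in LEAD_NAMES])

    def target_matrix(self) -> np.ndarray:
        """11 x T matrix of the reconstruction targets (II..V6)."""
        return np.stack([self.leads[name] for name in TARGET_LEADS])


def generate_beat(morph: BeatMorphology, fs: float) -> np.ndarray:
    """Evaluate one beat (sum of five Gaussian bumps) on its own time grid.

    The grid spans +-3 sigma beyond the outermost wave centers; outside that
    support the beat is zero by construction.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    waves = morph.waves()
    lo = min(w.center_ms - 3 * w.width_ms for w in waves.values())
    hi = max(w.center_ms + 3 * w.width_ms for w in waves.values())
    t_ms = np.arange(np.floor(lo * fs / 1000), np.ceil(hi * fs / 1000) + 1) * 1000 / fs
    out = np.zeros_like(t_ms)
    for w in waves.values():
        out += w.amp_mv * np.exp(-0.5 * ((t_ms - w.center_ms) / w.width_ms) ** 2)
    return out


def project_frontal_leads(dipole: np.ndarray, theta_unused: float | None = None
                          ) -> dict[str, np.ndarray]:
    """Project a frontal (dx, dy) dipole onto the six limb leads.

    Lead I is the projection onto 0 deg, Lead II onto 60 deg; III and the
    augmented leads are computed from the Einthoven / Goldberger identities
    (III = II - I, aVR = -(I+II)/2, aVL = I - II/2, aVF = II - I/2) so the
    identities hold exactly.  ``dipole`` has shape (2, T).
    """
    dipole = np.asarray(dipole, dtype=float)
    if not np.all(np.isfinite(dipole)):
        raise ParameterError("dipole signal must be finite")
    dx, dy = dipole
    lead_i = dx
    lead_ii = np.cos(np.deg2rad(60.0)) * dx + np.sin(np.deg2rad(60.0)) * dy
    return {
        "I": lead_i,
        "II": lead_ii,
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }


def _beat_times(params: SubjectParams, rng: np.random.Generator) -> np.ndarray:
    """R-peak times: first beat at RR/2, then RR with truncated jitter."""
    rr = 60.0 / params.heart_rate_bpm
    times = []
    t = rr / 2.0
    while t < params.duration_s:
        times.append(t)
        jitter = 0.0
        if params.rr_jitter > 0:
            jitter = float(np.clip(rng.normal(0.0, params.rr_jitter), -3 * params.rr_jitter,
                                   3 * params.rr_jitter))
        t += rr * (1.0 + jitter)
    return np.asarray(times)


def _wave_train(t: np.ndarray, beat_times: np.ndarray, wave: Wave) -> np.ndarray:
    """Sum of one wave's Gaussian over all beats (amplitude included)."""
    out = np.zeros_like(t)
    c_s = wave.center_ms / 1000.0
    sig_s = wave.width_ms / 1000.0
    for tb in beat_times:
        mu = tb + c_s
        lo = np.searchsorted(t, mu - 5 * sig_s)
        hi = np.searchsorted(t, mu + 5 * sig_s)
        if hi > lo:
            out[lo:hi] += wave.amp_mv * np.exp(-0.5 * ((t[lo:hi] - mu) / sig_s) ** 2)
    return out


def generate_record(params: SubjectParams, morph: BeatMorphology | None = None,
                    seed: int | None = None, record_id: str = "synth") -> EcgRecord:
    """Generate one 12-lead record with ground-truth metadata.

    ``seed`` is mandatory: every record is reproducible by construction.
    The emitted metadata are the generating ground truth — QRSCount is the
    number of placed beats, VentricularRate is 6 x QRSCount (the 10-s count
    to bpm conversion), and the axes / QRS duration are copied from params.
    """
    from .preprocess import MetadataRaw  # local import to avoid a cycle

    if seed is None:
        raise ParameterError("generate_record requires an explicit seed")
    if morph is None:
        morph = BeatMorphology.for_qrs_duration(params.qrs_duration_ms)
    rr = 60.0 / params.heart_rate_bpm
    if params.duration_s < rr:
        raise ParameterError("duration must cover at least one beat interval")

    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    beat_times = _beat_times(params, rng)

    waves = morph.waves()
    theta = {
        "P": params.theta_r, "Q": params.theta_r, "R": params.theta_r,
        "S": params.theta_r, "T": params.theta_t,
    }
    dx = np.zeros(n)
    dy = np.zeros(n)
    dz = np.zeros(n)
    for name in WAVE_ORDER:
        s_w = _wave_train(t, beat_times, waves[name])
        ang = np.deg2rad(theta[name])
        dx += s_w * np.cos(ang)
        dy += s_w * np.sin(ang)
        dz += s_w * _DZ_WEIGHTS[name]

    if params.baseline_wander_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        wander = params.baseline_wander_mv * np.sin(2 * np.pi * 0.3 * t + phase)
        dx = dx + wander
        dy = dy + 0.5 * wander
    if params.noise_mv > 0:
        dx = dx + rng.normal(0.0, params.noise_mv, n)
        dy = dy + rng.normal(0.0, params.noise_mv, n)
        dz = dz + rng.normal(0.0, params.noise_mv, n)

    leads = project_frontal_leads(np.stack([dx, dy]))
    w = np.asarray(params.precordial_weights, dtype=float)
    chest = w @ np.stack([dx, dy, dz])
    for j, name in enumerate(CHEST_LEADS):
        leads[name] = chest[j]
    leads = {name: leads[name] for name in LEAD_NAMES}

    qrs_count = int(len(beat_times))
    meta = MetadataRaw(
        r_axis=params.theta_r,
        t_axis=params.theta_t,
        ventricular_rate=6.0 * qrs_count,
        qrs_count=qrs_count,
        qrs_duration=params.qrs_duration_ms,
    )
    return EcgRecord(record_id=record_id, leads=leads, fs=params.fs,
                     metadata=meta, params=params, beat_times=beat_times)


def estimate_qrs_axis(record: EcgRecord, qrs_half_width_s: float = 0.06,
                      beat_times: np.ndarray | None = None) -> float:
    """Net frontal QRS angle from leads I and aVF (degrees).

    Integrates both leads over a window around each R peak and takes
    atan2 of the resulting (x, y) vector; the aVF area is rescaled by
    2/sqrt(3) because the augmented leads of a pure frontal dipole carry
    that geometric gain.  Uses the record's ground-truth beat times unless
    peak times are supplied.
    """
    times = beat_times if beat_times is not None else record.beat_times
    if times is None or len(times) == 0:
        raise ParameterError("no beat times available for axis estimation")
    lead_i = record.leads["I"]
    lead_avf = record.leads["aVF"]
    n = len(lead_i)
    w = int(round(qrs_half_width_s * record.fs))
    area_x = area_y = 0.0
    for tb in times:
        c = int(round(tb * record.fs))
        lo, hi = max(c - w, 0), min(c + w + 1, n)
        area_x += float(np.sum(lead_i[lo:hi]))
        area_y += float(np.sum(lead_avf[lo:hi])) * 2.0 / np.sqrt(3.0)
    return float(np.rad2deg(np.arctan2(area_y, area_x)))


# ---------------------------------------------------------------------------
# population sampling

_AXIS_RANGES = {
    "Normal": (-30.0, 90.0),
    "Left Deviation": (-89.0, -31.0),
    "Right Deviation": (91.0, 180.0),
    "Extreme Deviation": (-179.0, -91.0),
}
# heart-rate windows that land the beat count safely inside each count
# category (count = floor(hr/6 + 1/2) with the first beat at RR/2)
_RATE_RANGES = {"Low": (42.0, 54.0), "Normal": (63.0, 93.0), "High": (105.0, 125.0)}
_DUR_RANGES = {"Normal": (70.0, 110.0), "Prolonged": (120.0, 150.0)}


def default_param_sampler(rng: np.random.Generator) -> SubjectParams:
    """Draw one subject from the study-population mixture.

    Axis categories are drawn with probabilities (0.55, 0.20, 0.15, 0.10) for
    Normal / Left / Right / Extreme — an arrhythmia-database-like skew that
    still puts substantial mass on every category, so chest-lead morphology
    varies strongly with the axes across the population.
    """
    cats = list(_AXIS_RANGES)
    probs = [0.55, 0.20, 0.15, 0.10]
    th_r = rng.uniform(*_AXIS_RANGES[cats[rng.choice(4, p=probs)]])
    th_t = rng.uniform(*_AXIS_RANGES[cats[rng.choice(4, p=probs)]])
    hr_cat = ["Low", "Normal", "High"][rng.choice(3, p=[0.15, 0.70, 0.15])]
    hr = rng.uniform(*_RATE_RANGES[hr_cat])
    dur_cat = "Prolonged" if rng.random() < 0.25 else "Normal"
    dur = rng.uniform(*_DUR_RANGES[dur_cat])
    return SubjectParams(theta_r=float(th_r), theta_t=float(th_t),
                         heart_rate_bpm=float(hr), qrs_duration_ms=float(dur))


def stratified_param_sampler() -> Callable[[np.random.Generator], SubjectParams]:
    """Sampler that cycles every Table-style category of every feature.

    Round-robins independently over the 4 axis categories (for both axes),
    the 2 duration categories and the 3 rate/count categories, so any run of
    >= 12 draws covers every category of every feature at least once.
    """
    state = {"i": 0}
    axis_cats = list(_AXIS_RANGES)
    rate_cats = list(_RATE_RANGES)
    dur_cats = list(_DUR_RANGES)

    def sample(rng: np.random.Generator) -> SubjectParams:
        i = state["i"]
        state["i"] += 1
        th_r = rng.uniform(*_AXIS_RANGES[axis_cats[i % 4]])
        th_t = rng.uniform(*_AXIS_RANGES[axis_cats[(i // 4) % 4]])
        hr = rng.uniform(*_RATE_RANGES[rate_cats[i % 3]])
        dur = rng.uniform(*_DUR_RANGES[dur_cats[i % 2]])
        return SubjectParams(theta_r=float(th_r), theta_t=float(th_t),
                             heart_rate_bpm=float(hr), qrs_duration_ms=float(dur))

    return sample


def generate_dataset(
    n: int,
    seed: int,
    param_sampler: Callable[[np.random.Generator], SubjectParams] | None = None,
    stratified: bool = False,
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
) -> tuple[list[EcgRecord], dict[str, str]]:
    """Generate ``n`` records plus a 70/15/15 record-level split.

    Per-record seeds are derived deterministically from the master seed, so
    the same master seed reproduces the dataset bit for bit.  Returns the
    record list and a mapping record_id -> 'train'|'val'|'test'.
    """
    from .preprocess import split_dataset

    if n < 10:
        raise ParameterError("need at least 10 records for a meaningful split")
    if param_sampler is None:
        param_sampler = stratified_param_sampler() if stratified else default_param_sampler
    master = np.random.default_rng(seed)
    record_seeds = master.integers(0, 2**31 - 1, size=n)
    records = []
    for i in range(n):
        sampler_rng = np.random.default_rng(int(record_seeds[i]))
        params = param_sampler(sampler_rng)
        rec = generate_record(params, seed=int(record_seeds[i]) + 1,
                              record_id=f"synth{i:05d}")
        records.append(rec)
    split = split_dataset([r.record_id for r in records], fractions=tuple(fractions),
                          seed=seed)
    return records, split
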