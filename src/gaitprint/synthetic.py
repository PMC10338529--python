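"""Synthetic tri-axial ground-reaction-force (GRF) cohorts.

Generates raw running stance-phase recordings with the statistical structure
the downstream analysis assumes: every subject carries an individual
"movement signature" (a small set of curve-shape parameters), every footwear
condition adds a systematic offset to those parameters, and every trial adds
noise on top. A default cohort mirrors a 30-subject x 4-condition x 10-trial
running study recorded at 1 kHz on a force plate.

Axis/sign conventions (the raw data carry no convention of their own, so one
is fixed here): vertical (V) force is non-negative; anteroposterior (AP)
force is negative during braking and positive during propulsion; mediolateral
(ML) force is a low-amplitude oscillation with a positive (lateral) mean.
Channel order everywhere is (ML, AP, V).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SubjectParams",
    "FootwearEffect",
    "CohortConfig",
    "ForceRecording",
    "SIGNATURE_PARAMS",
    "FOOTWEAR_PROFILES",
    "generate_cohort",
    "generate_recording",
    "generate_dataset",
    "stance_template",
    "write_dataset",
    "read_recording",
    "read_dataset",
]

#: Names of the nine signature parameters, in storage order.
SIGNATURE_PARAMS = (
    "impact_peak_bw",     # vertical impact-peak magnitude, %BW
    "impact_time_pct",    # impact-peak timing, %stance
    "active_peak_bw",     # vertical active-peak magnitude, %BW
    "active_time_pct",    # active-peak timing, %stance
    "ap_braking_bw",      # AP braking-peak magnitude (unsigned), %BW
    "ap_propulsion_bw",   # AP propulsion-peak magnitude, %BW
    "ml_amplitude_bw",    # ML oscillation amplitude, %BW
    "ml_phase_rad",       # ML oscillation phase offset, rad
    "stance_ms",          # stance duration, ms
)

# Population means and between-subject SDs for the signature parameters.
# Magnitudes/timings follow typical rearfoot running GRFs: impact peak
# ~1.6 BW at ~15% stance, active peak ~2.5 BW at ~45% stance, AP peaks
# ~0.25 BW, ML ~0.08 BW, stance ~250 ms.
_POP_MEAN = np.array([160.0, 15.0, 250.0, 45.0, 25.0, 25.0, 8.0, 0.0, 250.0])
_POP_SD = np.array([20.0, 2.5, 20.0, 3.0, 5.0, 5.0, 3.0, 0.6, 25.0])

# Trial-to-trial SDs at trial_noise_scale = 1.
_TRIAL_SD = np.array([5.0, 1.0, 4.0, 1.2, 2.0, 2.0, 1.0, 0.15, 8.0])

# Hard physical bounds applied after all offsets/noise. Timing windows keep
# the impact peak strictly before the active peak.
_SIG_LO = np.array([40.0, 5.0, 120.0, 35.0, 5.0, 5.0, 0.5, -np.inf, 150.0])
_SIG_HI = np.array([300.0, 30.0, 400.0, 70.0, 60.0, 60.0, 25.0, np.inf, 400.0])

_CONDITION_NAMES = ("barefoot", "shoe_A", "shoe_B", "shoe_C")

#: Additive signature offsets (order of SIGNATURE_PARAMS) and measured-weight
#: delta in N for each footwear condition, at between_footwear_scale = 1.
#: "default" spreads the effect over impact/active/AP/stance parameters
#: (barefoot: harder impact, shorter stance; cushioned shoe_B: the reverse);
#: "ap_only" confines the footwear effect to the anteroposterior channel.
FOOTWEAR_PROFILES: dict[str, dict[str, tuple[tuple[float, ...], float]]] = {
    "default": {
        "barefoot": ((30.0, -4.0, 8.0, -2.0, 4.0, 2.0, -1.0, 0.0, -25.0), 0.0),
        "shoe_A": ((12.0, -2.0, 3.0, -1.0, 2.0, 1.0, 0.0, 0.0, -10.0), 4.0),
        "shoe_B": ((-18.0, 3.0, -6.0, 1.0, -3.0, -2.0, 1.0, 0.0, 15.0), 7.0),
        "shoe_C": ((-5.0, 1.0, -2.0, 0.0, 5.0, 4.0, 3.0, 0.0, 5.0), 6.0),
    },
    "ap_only": {
        "barefoot": ((0.0,) * 4 + (8.0, 6.0) + (0.0,) * 3, 0.0),
        "shoe_A": ((0.0,) * 4 + (-4.0, -2.0) + (0.0,) * 3, 0.0),
        "shoe_B": ((0.0,) * 4 + (2.0, -6.0) + (0.0,) * 3, 0.0),
        "shoe_C": ((0.0,) * 4 + (-6.0, 4.0) + (0.0,) * 3, 0.0),
    },
}

_G = 9.81  # m/s^2

# Template shape constants (fractions of stance / of the active peak).
_IMPACT_WIDTH = 0.045      # SD of the impact lobe
_ACTIVE_WIDTH = 0.13       # SD of the active lobe
_FLOOR_FRAC = 0.09         # plateau amplitude as a fraction of the active peak
_FLOOR_WIDTH = 0.45        # half-width of the flat-top plateau
_AP_CENTERS = (0.25, 0.75)  # braking / propulsion lobe centres
_AP_WIDTH = 0.09
_ML_CYCLES = 1.5
_ML_MEAN_FRAC = 0.3        # lateral-mean offset as a fraction of ML amplitude
_EDGE_FRAC = 0.03          # boundary taper width (fraction of stance)
_PAD_S = 0.15              # lead-in / lead-out length, s


@dataclass(frozen=True)
class SubjectParams:
    """One subject: body mass and the nine-parameter movement signature."""

    subject_id: int
    body_mass_kg: float
    signature: np.ndarray  # length 9, order SIGNATURE_PARAMS

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be positive")
        sig = np.asarray(self.signature, dtype=float)
        if sig.shape != (len(SIGNATURE_PARAMS),):
            raise ValueError(f"signature must have {len(SIGNATURE_PARAMS)} entries")
        object.__setattr__(self, "signature", sig)


@dataclass(frozen=True)
class FootwearEffect:
    """One footwear condition: signature offsets and measured-weight delta."""

    footwear_id: str
    condition_index: int
    offsets: np.ndarray  # length 9, additive on the signature
    body_weight_delta_n: float = 0.0

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float)
        if off.shape != (len(SIGNATURE_PARAMS),):
            raise ValueError(f"offsets must have {len(SIGNATURE_PARAMS)} entries")
        if not np.all(np.isfinite(off)):
            raise ValueError("offsets must be finite")
        object.__setattr__(self, "offsets", off)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design and effect/noise scales.

    ``between_subject_scale`` multiplies the between-subject SD of the
    signature parameters (0 = every subject identical),
    ``between_footwear_scale`` multiplies the footwear offsets (0 = no
    condition effect) and ``trial_noise_scale`` multiplies all trial-level
    noise (parameter jitter, smooth shape residual, sensor noise).
    """

    n_subjects: int = 30
    n_conditions: int = 4
    n_trials: int = 10
    sampling_rate: float = 1000.0
    trial_noise_scale: float = 1.0
    between_subject_scale: float = 1.0
    between_footwear_scale: float = 1.0
    rng_seed: int = 0
    footwear_profile: str = "default"

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_conditions, self.n_trials) < 1:
            raise ValueError("n_subjects, n_conditions and n_trials must be >= 1")
        if self.n_conditions > len(_CONDITION_NAMES):
            raise ValueError(f"at most {len(_CONDITION_NAMES)} footwear conditions are defined")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("trial_noise_scale", "between_subject_scale", "between_footwear_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.footwear_profile not in FOOTWEAR_PROFILES:
            raise ValueError(f"unknown footwear_profile {self.footwear_profile!r}")

    @property
    def n_recordings(self) -> int:
        return self.n_subjects * self.n_conditions * self.n_trials


@dataclass(frozen=True)
class ForceRecording:
    """Raw force-plate trace (columns ML, AP, V in newtons) plus metadata."""

    samples: np.ndarray  # (T, 3) in N
    sampling_rate: float
    subject_id: int
    footwear_id: str
    trial_id: int
    body_weight_n: float  # measured for this footwear condition

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError("samples must be a (T, 3) array (ML, AP, V)")
        if self.body_weight_n <= 0:
            raise ValueError("body_weight_n must be positive")
        object.__setattr__(self, "samples", s)


def _clip_signature(sig: np.ndarray) -> np.ndarray:
    return np.clip(sig, _SIG_LO, _SIG_HI)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectParams], list[FootwearEffect]]:
    """Draw subject signatures and footwear effects for one cohort.

    Subjects are drawn from the population distribution (means ``_POP_MEAN``,
    SDs ``_POP_SD`` scaled by ``between_subject_scale``); body mass is uniform
    on 71.4-100.0 kg. Footwear offsets come from the named profile scaled by
    ``between_footwear_scale``. Fully reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    subjects = []
    for sid in range(1, config.n_subjects + 1):
        # Body mass is a subject property, so the between-subject scale
        # governs it too: at scale 1 the cohort spans 71.4-100.0 kg, at
        # scale 0 every subject weighs the same (and the absolute 10 N
        # stance threshold then cuts every recording identically).
        mass = 85.7 + config.between_subject_scale * rng.uniform(-14.3, 14.3)
        mass = float(np.clip(mass, 45.0, 150.0))
        z = rng.standard_normal(len(SIGNATURE_PARAMS))
        sig = _clip_signature(_POP_MEAN + config.between_subject_scale * _POP_SD * z)
        subjects.append(SubjectParams(subject_id=sid, body_mass_kg=mass, signature=sig))

    profile = FOOTWEAR_PROFILES[config.footwear_profile]
    effects = []
    for idx, name in enumerate(_CONDITION_NAMES[: config.n_conditions]):
        base, bw_delta = profile[name]
        effects.append(
            FootwearEffect(
                footwear_id=name,
                condition_index=idx,
                offsets=np.asarray(base) * config.between_footwear_scale,
                # The shoe-mass weight delta is itself a condition effect
                # (it shifts the absolute 10 N threshold relative to %BW),
                # so the footwear scale governs it as well.
                body_weight_delta_n=bw_delta * config.between_footwear_scale,
            )
        )
    return subjects, effects


def _edge_window(t: np.ndarray, frac: float = _EDGE_FRAC) -> np.ndarray:
    """Cosine taper forcing the stance curves to zero at foot strike/toe-off."""
    w = np.ones_like(t)
    lo = t < frac
    hi = t > 1.0 - frac
    w[lo] = 0.5 * (1.0 - np.cos(np.pi * t[lo] / frac))
    w[hi] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - t[hi]) / frac))
    return w


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def stance_template(signature: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Noise-free stance curves in %BW at stance fractions ``t`` in [0, 1].

    Returns a (len(t), 3) array in channel order (ML, AP, V).

    V is two Gaussian lobes (impact + active peak) over a broad flat-top
    plateau (so the vertical force stays supra-threshold until just before
    toe-off, as on a force plate); lobe amplitudes are corrected for overlap
    so the curve attains the configured peak magnitudes at the configured
    times. AP is a negative braking lobe and a positive propulsion lobe of
    equal width placed symmetrically about mid-stance; ML is a slow
    oscillation with a lateral mean. All channels are edge-tapered to zero.
    """
    sig = dict(zip(SIGNATURE_PARAMS, np.asarray(signature, dtype=float)))
    t = np.asarray(t, dtype=float)
    t_imp = sig["impact_time_pct"] / 100.0
    t_act = sig["active_time_pct"] / 100.0

    floor_amp = _FLOOR_FRAC * sig["active_peak_bw"]

    def _plateau(x: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-(((np.asarray(x) - 0.5) / _FLOOR_WIDTH) ** 8))

    # Overlap-corrected lobe amplitudes: template equals the configured peak
    # values at the configured peak times.
    a_act = sig["active_peak_bw"] - floor_amp * _plateau(t_act)
    a_imp = (
        sig["impact_peak_bw"]
        - floor_amp * _plateau(t_imp)
        - a_act * _gauss(np.array([t_imp]), t_act, _ACTIVE_WIDTH)[0]
    )
    v = (
        a_imp * _gauss(t, t_imp, _IMPACT_WIDTH)
        + a_act * _gauss(t, t_act, _ACTIVE_WIDTH)
        + floor_amp * _plateau(t)
    )

    ap = -sig["ap_braking_bw"] * _gauss(t, _AP_CENTERS[0], _AP_WIDTH) + sig[
        "ap_propulsion_bw"
    ] * _gauss(t, _AP_CENTERS[1], _AP_WIDTH)

    ml = sig["ml_amplitude_bw"] * (
        np.sin(2.0 * np.pi * _ML_CYCLES * t + sig["ml_phase_rad"]) + _ML_MEAN_FRAC
    )

    w = _edge_window(t)
    return np.column_stack([ml * w, ap * w, v * w])


def _smooth_residual(t: np.ndarray, rng: np.random.Generator, noise_scale: float) -> np.ndarray:
    """Low-frequency per-trial shape perturbation in %BW, edge-tapered."""
    amps = np.array([0.5, 0.8, 1.5]) * noise_scale  # ML, AP, V
    out = np.zeros((t.size, 3))
    for c in range(3):
        for h in (1, 2, 3):
            a = rng.normal(0.0, amps[c] / h)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            out[:, c] += a * np.sin(2.0 * np.pi * h * t + phi)
    return out * _edge_window(t)[:, None]


def generate_recording(
    subject: SubjectParams,
    footwear: FootwearEffect,
    trial_id: int,
    noise_scale: float = 1.0,
    seed: int = 0,
    sampling_rate: float = 1000.0,
) -> ForceRecording:
    """Simulate one raw force-plate trace for (subject, footwear, trial).

    The trial RNG stream is derived deterministically from
    (seed, subject, condition, trial), so any single trial can be regenerated
    without replaying the cohort. Trial noise perturbs the signature
    parameters (including stance duration), adds a smooth low-frequency shape
    residual, and white sensor noise; lead-in/lead-out segments carry only
    sub-threshold sensor noise.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng([seed, subject.subject_id, footwear.condition_index, trial_id])

    sig = _clip_signature(
        subject.signature
        + footwear.offsets
        + noise_scale * _TRIAL_SD * rng.standard_normal(len(SIGNATURE_PARAMS))
    )
    body_weight = subject.body_mass_kg * _G + footwear.body_weight_delta_n

    n_stance = int(round(sig[SIGNATURE_PARAMS.index("stance_ms")] / 1000.0 * sampling_rate))
    t = (np.arange(n_stance) + 0.5) / n_stance
    curves_bw = stance_template(sig, t) + _smooth_residual(t, rng, noise_scale)
    # Sensor noise is specified in %BW (~0.4-0.5 N for this cohort) so that
    # body-weight normalisation cancels it identically across subjects: with
    # all effect scales at zero, recordings are statistically exchangeable
    # between subjects and conditions.
    curves_bw = curves_bw + rng.normal(0.0, 0.05 * noise_scale, curves_bw.shape)
    stance_n = curves_bw / 100.0 * body_weight

    n_pad = int(round(_PAD_S * sampling_rate))
    # Baseline (unloaded plate) noise, clipped well below the 10 N stance
    # threshold so detection stays unambiguous.
    pad_bw = rng.normal(0.0, 0.05 * noise_scale, (2 * n_pad, 3))
    pads_n = np.clip(pad_bw / 100.0 * body_weight, -8.0, 8.0)

    samples = np.vstack([pads_n[:n_pad], stance_n, pads_n[n_pad:]])
    return ForceRecording(
        samples=samples,
        sampling_rate=sampling_rate,
        subject_id=subject.subject_id,
        footwear_id=footwear.footwear_id,
        trial_id=trial_id,
        body_weight_n=body_weight,
    )


def generate_dataset(
    config: CohortConfig,
) -> tuple[list[ForceRecording], pd.DataFrame]:
    """Generate the full cohort: one recording per subject x condition x trial.

    Returns the recordings and a metadata table with one row per recording
    (subject_id, footwear_id, trial_id, body_weight_n).
    """
    subjects, effects = generate_cohort(config)
    recordings: list[ForceRecording] = []
    rows = []
    for subject in subjects:
        for effect in effects:
            for trial in range(1, config.n_trials + 1):
                rec = generate_recording(
                    subject,
                    effect,
                    trial_id=trial,
                    noise_scale=config.trial_noise_scale,
                    seed=config.rng_seed,
                    sampling_rate=config.sampling_rate,
                )
                recordings.append(rec)
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "footwear_id": rec.footwear_id,
                        "trial_id": rec.trial_id,
                        "body_weight_n": rec.body_weight_n,
                    }
                )
    return recordings, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plain-text I/O: one CSV per recording plus a metadata table.

def write_dataset(
    recordings: list[ForceRecording], metadata: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write one CSV per recording and a ``metadata.csv`` index to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        name = f"s{rec.subject_id:03d}_{rec.footwear_id}_t{rec.trial_id:02d}.csv"
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# sampling_rate_hz={rec.sampling_rate}\n")
            fh.write("ml_n,ap_n,v_n\n")
            np.savetxt(fh, rec.samples, delimiter=",", fmt="%.6f")
        paths.append(name)
    meta = metadata.copy()
    meta.insert(0, "path", paths)
    meta.to_csv(out / "metadata.csv", index=False)
    return out / "metadata.csv"


def read_recording(path: str | Path, *, subject_id: int, footwear_id: str,
                   trial_id: int, body_weight_n: float) -> ForceRecording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sampling_rate_hz="):
            raise ValueError(f"{path}: missing sampling-rate header")
        fs = float(header.split("=", 1)[1])
        samples = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
    return ForceRecording(
        samples=samples,
        sampling_rate=fs,
        subject_id=subject_id,
        footwear_id=footwear_id,
        trial_id=trial_id,
        body_weight_n=body_weight_n,
    )


def read_dataset(in_dir: str | Path) -> tuple[list[ForceRecording], pd.DataFrame]:
    """Read a dataset written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    meta_path = in_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata table not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    recordings = [
        read_recording(
            in_dir / row.path,
            subject_id=int(row.subject_id),
            footwear_id=str(row.footwear_id),
            trial_id=int(row.trial_id),
            body_weight_n=float(row.body_weight_n),
        )
        for row in meta.itertuples()
    ]
    return recordings, meta.drop(columns=["path"])
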