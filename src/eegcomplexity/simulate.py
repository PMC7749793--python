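"""Synthetic resting-EEG cohort with planted complexity -> decline coupling.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without patient data:

* **EEG**: per subject and condition (eyes closed EC / eyes open EO), each
  scalp region of interest carries one narrowband rhythm per frequency band
  plus a bank of independent bursting theta oscillators, shared across that
  region's channels with channel-specific gains, on top of independent
  1/f^beta background noise per channel.  Signal complexity is controlled
  by the *number* of theta pacemakers: the more independent bursting
  sources superpose, the closer the amplitude distribution is to Gaussian
  and the higher its Tsallis entropy.  In the EO
  condition the alpha oscillator amplitudes are multiplied by
  ``berger_factor`` < 1 (alpha suppression on eye opening).
* **Cognition**: sixteen standardized test scores (mean 100, sd 15) in four
  domains at baseline, 6 months and 3 years.  The latent 3-year decline (in
  overall-RCI units, decline-positive) couples to the standardized EO-linked
  theta-complexity latent; the EC-linked pathway is a planted null by
  default.  Observed scores carry measurement error sized so each test's
  test-retest reliability equals its configured RS; entries go missing at
  random with a rate that may depend on (observed) disease duration only.

Defaults mirror the study design this package targets: 42 patients
(Parkinson's disease, PD) and 24 matched healthy controls (HC), 213
electrodes at 1000 Hz with 180 s per condition, 16 tests with ~5.5 %
missing entries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .cognition import DOMAINS, ScorePanel, TIMEPOINTS
from .io import (
    CONDITIONS,
    EEGRecording,
    ROI_LABELS,
    synthetic_montage,
    write_manifest,
    write_recording,
)

# Per-band component amplitudes in uV; these set realistic relative band
# powers (delta-dominant, alpha a modest share so its EO suppression
# perturbs the five-band denominator only mildly).
_BAND_AMPLITUDE = {"delta": 6.0, "theta": 4.5, "alpha": 3.5, "beta": 4.5, "gamma": 3.5}
_BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Default per-test reliability coefficients (16 tests, fixed order).
DEFAULT_RELIABILITIES: tuple[float, ...] = (
    0.84, 0.78, 0.81, 0.74,  # attention
    0.82, 0.86, 0.79, 0.75,  # executive
    0.80, 0.77, 0.83, 0.72,  # working memory
    0.85, 0.76, 0.80, 0.78,  # visuo-constructive
)


@dataclass(frozen=True)
class SubjectSpec:
    """Latent description of one simulated participant."""

    subject_id: str
    group: str  # "PD" or "HC"
    age: float
    education: float
    sex: str  # "f" or "m"
    sleepiness: float  # Karolinska scale, 1-10
    disease_duration: float | None = None  # years, PD only
    led: float | None = None  # levodopa equivalent dose, mg, PD only
    theta_complexity: dict[str, float] = field(default_factory=dict)
    decline_slope: float = 0.0  # overall-RCI units per 3 years

    def __post_init__(self) -> None:
        for c, v in self.theta_complexity.items():
            if v <= 0:
                raise ValueError(f"theta_complexity[{c}] must be > 0")
        if not 1 <= self.sleepiness <= 10:
            raise ValueError("sleepiness must lie in [1, 10]")


@dataclass(frozen=True)
class Coupling:
    """Planted links from latent complexity (and age) to 3-year decline.

    ``decline = slope_eo * z_eo + slope_ec * z_ec + age_effect * z_age
    + noise_sd * eps`` in overall-RCI units, where z_eo / z_ec are the
    standardized condition-linked complexity latents.  The default couples
    decline to the EO pathway only (slope_ec = 0, a planted null), with the
    negative sign encoding "lower complexity -> stronger decline".
    """

    slope_eo: float = -0.8
    slope_ec: float = 0.0
    noise_sd: float = 0.5
    age_effect: float = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings (defaults = the emulated study)."""

    n_pd: int = 42
    n_hc: int = 24
    n_channels: int = 213
    fs: float = 1000.0
    duration_s: float = 180.0
    noise_exponent: float = 1.0  # spectral slope beta of 1/f^beta noise
    noise_scale: float = 3.0  # total background-noise sd, uV
    berger_factor: float = 0.3  # EO alpha amplitude multiplier
    missing_rate: float = 0.055
    n_tests: int = 16
    reliabilities: tuple[float, ...] = DEFAULT_RELIABILITIES
    seed: int = 0
    # complexity latent: group means / sd on the oscillator-count scale
    complexity_mean_pd: float = 5.0
    complexity_mean_hc: float = 8.0
    complexity_sd: float = 2.0
    #: weight lambda of the latent shared between EC and EO complexity;
    #: corr(c_ec, c_eo) = lambda**2.  No study-prescribed value exists.
    shared_latent_weight: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 < self.berger_factor < 1:
            raise ValueError("berger_factor must lie in (0, 1)")
        if self.fs < 2 * 45.0:
            raise ValueError("fs must be at least twice the 45 Hz top band edge")
        if len(self.reliabilities) != self.n_tests:
            raise ValueError(
                f"{len(self.reliabilities)} reliabilities for "
                f"{self.n_tests} tests"
            )
        if any(not 0 < r < 1 for r in self.reliabilities):
            raise ValueError("reliabilities must lie strictly in (0, 1)")


def _subject_stream(seed: int, subject_id: str, purpose: int) -> np.random.Generator:
    """Deterministic RNG stream for one subject and purpose code."""
    digest = hashlib.blake2s(subject_id.encode(), digest_size=4).digest()
    sid = int.from_bytes(digest, "little")
    return np.random.default_rng([seed & 0x7FFFFFFF, sid, purpose])


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _pink_noise(
    rng: np.random.Generator, n_channels: int, n: int, fs: float, beta: float
) -> np.ndarray:
    """1/f^beta background noise, unit variance per channel."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _narrowband_noise(
    rng: np.random.Generator,
    rows: int,
    n: int,
    fs: float,
    lo: float,
    hi: float,
    amplitude: float,
) -> np.ndarray:
    """Band-limited Gaussian activity, sd = amplitude per row.

    Built in the frequency domain with a raised-cosine edge taper (10 % of
    the band width) so the rhythm has soft spectral shoulders rather than a
    brick-wall band.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    width = hi - lo
    taper = 0.1 * width
    shape = np.zeros_like(freqs)
    core = (freqs >= lo + taper) & (freqs <= hi - taper)
    shape[core] = 1.0
    for edge, sign in ((lo, 1.0), (hi, -1.0)):
        ramp = (freqs - edge) * sign
        sel = (ramp >= 0) & (ramp < taper)
        shape[sel] = 0.5 * (1 - np.cos(np.pi * ramp[sel] / taper))
    spec = (
        rng.standard_normal((rows, freqs.size))
        + 1j * rng.standard_normal((rows, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return amplitude * x / np.where(sd > 0, sd, 1.0)


def _smooth_noise(
    rng: np.random.Generator, k: int, n: int, t_max: float, knot_s: float
) -> np.ndarray:
    """k rows of slowly-varying ~unit-variance noise (linear knot interp)."""
    n_knots = max(3, int(np.ceil(t_max / knot_s)) + 1)
    knots = rng.standard_normal((k, n_knots))
    pos = np.linspace(0.0, n_knots - 1.0, n)
    i0 = np.clip(np.floor(pos).astype(np.intp), 0, n_knots - 2)
    w = pos - i0
    return knots[:, i0] * (1.0 - w) + knots[:, i0 + 1] * w


def _burst_oscillator_bank(
    rng: np.random.Generator, k: int, lo: float, hi: float, amplitude: float,
    t: np.ndarray, knot_s: float = 1.5,
) -> np.ndarray:
    """Sum of k independent *bursting* oscillators with total sd ~= amplitude.

    Each pacemaker's carrier is gated by a squared slowly-varying Gaussian
    envelope (knots every ``knot_s`` seconds, linearly interpolated), so a
    single oscillator produces heavy-tailed, intermittent activity — a
    peaked amplitude density with low Tsallis entropy.  Superposing k
    independent such sources Gaussianizes the sum (excess kurtosis falls
    off as 1/k), so the band's entropy increases monotonically with the
    number of pacemakers while total band power stays fixed.
    """
    n = t.size
    f = rng.uniform(lo, hi, size=k)
    phase = rng.uniform(0, 2 * np.pi, size=k)
    env = _smooth_noise(rng, k, n, t[-1], knot_s) ** 2
    # E[env] = 1, E[env^2] = 3 for unit-variance smooth noise
    a = amplitude * np.sqrt(2.0 / (3.0 * k))
    return a * env * np.sin(2 * np.pi * f[:, None] * t + phase[:, None])


def simulate_eeg(
    spec: SubjectSpec, condition: str, cfg: SimulationConfig
) -> EEGRecording:
    """Synthesize one subject x condition recording.

    Deterministic given ``cfg.seed``: repeated calls with the same arguments
    return bit-identical signals.  The theta oscillator count is
    ``round(theta_complexity[condition])`` (at least 2); in the EO condition
    alpha amplitudes are scaled by ``cfg.berger_factor``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if cfg.duration_s < 2.0:
        raise ValueError(
            "duration_s < 2 s cannot represent the 1 Hz band edge"
        )
    c = spec.theta_complexity.get(condition)
    if c is None:
        raise ValueError(
            f"subject {spec.subject_id} has no theta_complexity for "
            f"{condition}"
        )
    rng = _subject_stream(cfg.seed, spec.subject_id, {"EC": 1, "EO": 2}[condition])
    gain_rng = _subject_stream(cfg.seed, spec.subject_id, 0)  # seed-fixed gains

    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    names, roi_map = synthetic_montage(cfg.n_channels)
    channels_of = {
        roi: [i for i, name in enumerate(names) if roi_map[name] == roi]
        for roi in ROI_LABELS
    }

    data = cfg.noise_scale * _pink_noise(
        rng, cfg.n_channels, n, cfg.fs, cfg.noise_exponent
    )
    k_theta = max(2, int(round(c)))
    rois = [roi for roi in ROI_LABELS if channels_of[roi]]
    for band, (lo, hi) in _BAND_EDGES.items():
        amp = _BAND_AMPLITUDE[band]
        if band == "alpha" and condition == "EO":
            amp *= cfg.berger_factor
        if band == "theta":
            # complexity-bearing band: bursting pacemakers whose count
            # sets the entropy of the superposition
            banks = _burst_oscillator_bank(
                rng, k_theta * len(rois), lo, hi, amp, t
            )
            banks = banks.reshape(len(rois), k_theta, n) * np.sqrt(len(rois))
            for ri, roi in enumerate(rois):
                idx = channels_of[roi]
                gains = 1.0 + 0.15 * gain_rng.standard_normal(
                    (len(idx), k_theta)
                )
                data[idx] += gains @ banks[ri]
        else:
            # non-complexity bands: one narrowband rhythm per ROI, shared
            # across the ROI's channels with channel-specific gains
            rhythms = _narrowband_noise(
                rng, len(rois), n, cfg.fs, lo, hi, amp
            )
            for ri, roi in enumerate(rois):
                idx = channels_of[roi]
                gains = 1.0 + 0.15 * gain_rng.standard_normal((len(idx), 1))
                data[idx] += gains * rhythms[ri]

    return EEGRecording(
        subject_id=spec.subject_id,
        condition=condition,
        data=data,
        fs=cfg.fs,
        channel_names=names,
        roi_map=roi_map,
    )


# ---------------------------------------------------------------------------
# Cohort: covariates, latents, scores
# ---------------------------------------------------------------------------

def default_test_metadata(
    reliabilities: Sequence[float] = DEFAULT_RELIABILITIES,
) -> pd.DataFrame:
    """The 16-test panel: name, domain, orientation, reliability.

    Attention tests are latency/omission counts (higher = worse); one
    working-memory test counts omissions; the rest score accuracy or span
    (higher = better).
    """
    rows = [
        ("alertness_rt", "attention", False),
        ("alertness_rt_cue", "attention", False),
        ("divided_attention_rt", "attention", False),
        ("trail_making_a_time", "attention", False),
        ("phonemic_fluency", "executive", True),
        ("semantic_fluency", "executive", True),
        ("stroop_interference", "executive", True),
        ("planning_score", "executive", True),
        ("wm_omissions", "working_memory", False),
        ("digit_span_forward", "working_memory", True),
        ("digit_span_backward", "working_memory", True),
        ("corsi_block_span", "working_memory", True),
        ("block_design", "visuoconstructive", True),
        ("figure_copy", "visuoconstructive", True),
        ("clock_drawing", "visuoconstructive", True),
        ("visual_puzzles", "visuoconstructive", True),
    ]
    if len(reliabilities) != len(rows):
        raise ValueError("need one reliability per test")
    return pd.DataFrame(
        {
            "test": [r[0] for r in rows],
            "domain": [r[1] for r in rows],
            "higher_is_better": [r[2] for r in rows],
            "reliability": list(reliabilities),
        }
    )


@dataclass
class Cohort:
    """A simulated cohort: specs, covariates, latents and the score panel.

    EEG is synthesized lazily (deterministically from the config seed) via
    :meth:`iter_recordings`, so a full cohort never has to fit in memory.
    """

    cfg: SimulationConfig
    coupling: Coupling
    specs: list[SubjectSpec]
    subjects: pd.DataFrame
    latents: pd.DataFrame
    panel: ScorePanel

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.subjects["subject_id"], self.subjects["group"]))

    def spec_for(self, subject_id: str) -> SubjectSpec:
        for s in self.specs:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def iter_recordings(
        self,
        conditions: Sequence[str] = CONDITIONS,
        groups: Sequence[str] = ("PD", "HC"),
        cfg: SimulationConfig | None = None,
    ) -> Iterator[EEGRecording]:
        """Yield recordings one at a time (optionally under an overridden cfg)."""
        cfg = cfg or self.cfg
        for spec in self.specs:
            if spec.group not in groups:
                continue
            for condition in conditions:
                yield simulate_eeg(spec, condition, cfg)


def simulate_cohort(
    cfg: SimulationConfig | None = None, coupling: Coupling | None = None
) -> Cohort:
    """Generate the full synthetic cohort (covariates, latents, scores).

    Deterministic given ``cfg.seed``.  The score panel covers the PD group
    (the group followed longitudinally); EEG for both groups is available
    through :meth:`Cohort.iter_recordings`.
    """
    cfg = cfg or SimulationConfig()
    coupling = coupling or Coupling()
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xC0C0])

    ids = [f"PD{i + 1:02d}" for i in range(cfg.n_pd)] + [
        f"HC{i + 1:02d}" for i in range(cfg.n_hc)
    ]
    groups = ["PD"] * cfg.n_pd + ["HC"] * cfg.n_hc
    n = len(ids)

    age = np.clip(rng.normal(66.5, 6.0, n), 45, 88)
    education = np.clip(rng.normal(14.0, 3.0, n), 7, 22)
    sex = np.where(rng.random(n) < 0.42, "f", "m")
    sleepiness = np.clip(rng.normal(3.0, 0.8, n), 1, 10)
    duration = np.exp(rng.normal(np.log(2.5), 0.8, n))  # median 2.5 y
    led = np.exp(rng.normal(np.log(543.0), 0.6, n))  # median 543 mg

    lam = cfg.shared_latent_weight
    s = rng.standard_normal(n)
    u_ec = rng.standard_normal(n)
    u_eo = rng.standard_normal(n)
    z_ec = lam * s + np.sqrt(1 - lam**2) * u_ec
    z_eo = lam * s + np.sqrt(1 - lam**2) * u_eo
    mu = np.where(
        np.array(groups) == "PD", cfg.complexity_mean_pd, cfg.complexity_mean_hc
    )
    c_ec = np.clip(mu + cfg.complexity_sd * z_ec, 1.5, 40.0)
    c_eo = np.clip(mu + cfg.complexity_sd * z_eo, 1.5, 40.0)

    z_age = (age - age.mean()) / age.std()
    decline = (
        coupling.slope_eo * z_eo
        + coupling.slope_ec * z_ec
        + coupling.age_effect * z_age
        + coupling.noise_sd * rng.standard_normal(n)
    )

    specs = []
    for i, (sid, grp) in enumerate(zip(ids, groups)):
        specs.append(
            SubjectSpec(
                subject_id=sid,
                group=grp,
                age=float(age[i]),
                education=float(education[i]),
                sex=str(sex[i]),
                sleepiness=float(sleepiness[i]),
                disease_duration=float(duration[i]) if grp == "PD" else None,
                led=float(led[i]) if grp == "PD" else None,
                theta_complexity={"EC": float(c_ec[i]), "EO": float(c_eo[i])},
                decline_slope=float(decline[i]),
            )
        )

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "age": age,
            "education": education,
            "sex": sex,
            "sleepiness": sleepiness,
            "disease_duration": [
                d if g == "PD" else np.nan for d, g in zip(duration, groups)
            ],
            "led": [d if g == "PD" else np.nan for d, g in zip(led, groups)],
        }
    )
    latents = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "z_shared": s,
            "z_ec": z_ec,
            "z_eo": z_eo,
            "theta_complexity_ec": c_ec,
            "theta_complexity_eo": c_eo,
            "decline_slope": decline,
        }
    )

    pd_mask = np.array(groups) == "PD"
    panel = _simulate_panel(
        rng,
        cfg,
        subject_ids=[sid for sid, m in zip(ids, pd_mask) if m],
        decline=decline[pd_mask],
        duration=duration[pd_mask],
    )
    return Cohort(
        cfg=cfg,
        coupling=coupling,
        specs=specs,
        subjects=subjects,
        latents=latents,
        panel=panel,
    )


_HORIZON_YEARS = {"baseline": 0.0, "m6": 0.5, "y3": 3.0}


def _simulate_panel(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    subject_ids: list[str],
    decline: np.ndarray,
    duration: np.ndarray,
) -> ScorePanel:
    """Longitudinal standardized scores with planted decline and MAR holes."""
    tests = default_test_metadata(cfg.reliabilities)
    n = len(subject_ids)
    if n == 0:
        empty = pd.DataFrame(
            {"subject": [], "test": [], "timepoint": [], "value": []}
        )
        return ScorePanel(scores=empty, tests=tests)
    domain_idx = {d: i for i, d in enumerate(DOMAINS)}
    ability = rng.standard_normal((n, len(DOMAINS)))  # true per-domain level

    rows = []
    for ti, trow in enumerate(tests.itertuples()):
        rs = float(trow.reliability)
        sd_true = 15.0 * np.sqrt(rs)
        sd_err = 15.0 * np.sqrt(1.0 - rs)
        s_diff = 15.0 * np.sqrt(2.0 * (1.0 - rs))
        base_true = 100.0 + sd_true * ability[:, domain_idx[trow.domain]]
        orient = 1.0 if bool(trow.higher_is_better) else -1.0
        for tp in TIMEPOINTS:
            # decline-positive RCI units -> score units via S_diff; a
            # higher-is-better test loses points when the subject declines
            change = -orient * decline * (_HORIZON_YEARS[tp] / 3.0) * s_diff
            observed = base_true + change + sd_err * rng.standard_normal(n)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject_ids,
                        "test": trow.test,
                        "timepoint": tp,
                        "value": observed,
                    }
                )
            )
    scores = pd.concat(rows, ignore_index=True)

    if cfg.missing_rate > 0:
        # MAR: the missingness probability depends on observed disease
        # duration only, normalized so the expected rate is missing_rate
        w = np.exp(0.5 * (np.log(duration) - np.log(duration).mean()))
        w = w / w.mean()
        p_subject = np.clip(
            cfg.missing_rate * w, 0.0, 0.95
        )
        p_map = dict(zip(subject_ids, p_subject))
        p_cell = scores["subject"].map(p_map).to_numpy()
        mask = rng.random(len(scores)) < p_cell
        scores.loc[mask, "value"] = np.nan

    return ScorePanel(scores=scores, tests=tests)


def simulate_test_retest(
    cfg: SimulationConfig, n_subjects: int, seed: int | None = None
) -> pd.DataFrame:
    """Two parallel administrations of each test at fixed true ability.

    Used to verify the reliability calibration: the empirical correlation
    between the two administrations of test t estimates its configured RS.
    Returns a tidy frame (test, administration, subject, value).
    """
    rng = np.random.default_rng(
        (cfg.seed if seed is None else seed) & 0x7FFFFFFF
    )
    tests = default_test_metadata(cfg.reliabilities)
    ability = rng.standard_normal((n_subjects, len(DOMAINS)))
    domain_idx = {d: i for i, d in enumerate(DOMAINS)}
    frames = []
    for trow in tests.itertuples():
        rs = float(trow.reliability)
        true = 100.0 + 15.0 * np.sqrt(rs) * ability[:, domain_idx[trow.domain]]
        for admin in (1, 2):
            obs = true + 15.0 * np.sqrt(1 - rs) * rng.standard_normal(n_subjects)
            frames.append(
                pd.DataFrame(
                    {
                        "test": trow.test,
                        "administration": admin,
                        "subject": np.arange(n_subjects),
                        "value": obs,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    format: str = "delimited",
    conditions: Sequence[str] = CONDITIONS,
) -> Path:
    """Write recordings, subject table, score panel and manifest to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "edf" if format == "edf" else "tsv"
    manifest: dict[str, dict[str, str]] = {}
    for rec in cohort.iter_recordings(conditions=conditions):
        fname = f"{rec.subject_id}_{rec.condition}.{ext}"
        write_recording(rec, out_dir / fname, format=format)
        manifest.setdefault(rec.subject_id, {})[rec.condition] = fname
    write_manifest(manifest, out_dir / "manifest.json")
    cohort.subjects.to_csv(out_dir / "subjects.csv", index=False)
    cohort.panel.scores.to_csv(out_dir / "scores.csv", index=False)
    cohort.panel.tests.to_csv(out_dir / "tests.csv", index=False)
    cohort.latents.to_csv(out_dir / "latents.csv", index=False)
    return out_dir


def reduced_config(
    cfg: SimulationConfig | None = None,
    n_channels: int = 10,
    fs: float = 100.0,
    duration_s: float = 172.0,
    **overrides,
) -> SimulationConfig:
    """A cheaper configuration preserving the study's statistical structure.

    Keeps all band content (Nyquist 50 Hz > 45 Hz top edge) and stays above
    the 170 s validity floor while cutting channel count and sampling rate;
    intended for tests and replicated simulations.
    """
    cfg = cfg or SimulationConfig()
    return replace(
        cfg, n_channels=n_channels, fs=fs, duration_s=duration_s, **overrides
    )
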