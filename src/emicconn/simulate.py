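"""Synthetic two-group cohorts with controlled linear/non-linear couplings.

Base signals are independent band-limited Gaussian processes: white noise
band-passed to 0.01–0.08 Hz (the resting-state band at TR = 2 s) and
z-scored.  A coupling of strength ``s`` mixes a transform of the source
region into the target region,

    target = sqrt(1 - s**2) * own + s * f(source),       f z-scored,

with f = identity (linear), the centered square (quadratic), or a sine
transform (sinusoidal); white observation noise of sd ``noise_sd`` is added
last.  The quadratic transform is mean-centered and, for a symmetric
band-limited Gaussian source, nearly uncorrelated with the source — planted
quadratic edges have near-zero PCC by construction, isolating what eMIC
must detect.

The "paper-like" preset encodes the qualitative clinical contrast the
pipeline is meant to recover: linear couplings weaken from controls to
patients (0.6 -> 0.3) while quadratic couplings strengthen (0.2 -> 0.6),
so linear edges are found by PCC with positive tau (decreased in patients)
and quadratic edges by eMIC with negative tau (increased in patients).

Cohorts are reproducible bit-for-bit from the master seed; each subject
draws from a stream seeded by (master seed, subject position), so existing
subjects are stable when more are appended.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .preprocess import MotionParameters, RegionalTimeSeries

__all__ = [
    "CouplingSpec",
    "CohortConfig",
    "paper_like_config",
    "null_config",
    "band_limited_noise",
    "coupled_pair",
    "generate_subject",
    "generate_motion",
    "generate_cohort",
    "association_battery",
]

COUPLING_FORMS = ("linear", "quadratic", "sinusoidal")


@dataclass(frozen=True)
class CouplingSpec:
    """One directed coupling: region ``target`` receives f(``source``)."""

    source: int
    target: int
    form: str
    strength_control: float
    strength_patient: float

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError("source and target must differ")
        if self.form not in COUPLING_FORMS:
            raise ValueError(f"unknown form {self.form!r}; use {COUPLING_FORMS}")
        for s in (self.strength_control, self.strength_patient):
            if not 0.0 <= s <= 1.0:
                raise ValueError("strengths must lie in [0, 1]")

    @property
    def edge(self) -> tuple[int, int]:
        i, j = sorted((self.source, self.target))
        return (i, j)

    def strength(self, group: int) -> float:
        return self.strength_control if group == 1 else self.strength_patient


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults: 116 regions, 175 volumes at TR = 2 s,
    32 controls + 32 patients, signals band-limited to 0.01–0.08 Hz."""

    n_regions: int = 116
    n_timepoints: int = 175
    tr_seconds: float = 2.0
    n_controls: int = 32
    n_patients: int = 32
    couplings: tuple[CouplingSpec, ...] = ()
    noise_sd: float = 0.3
    band: tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self):
        for c in self.couplings:
            if not (0 <= c.source < self.n_regions and 0 <= c.target < self.n_regions):
                raise ValueError(
                    f"coupling {c.source}->{c.target} references a region "
                    f">= n_regions ({self.n_regions})"
                )
        object.__setattr__(self, "couplings", tuple(self.couplings))
        object.__setattr__(self, "band", tuple(self.band))

    @property
    def region_labels(self) -> tuple[str, ...]:
        return tuple(f"R{r + 1:03d}" for r in range(self.n_regions))


def _disjoint_pairs(n_regions: int, count: int, rng: np.random.Generator):
    regions = rng.permutation(n_regions)
    if 2 * count > n_regions:
        raise ValueError("not enough regions for disjoint coupled pairs")
    return [(int(regions[2 * i]), int(regions[2 * i + 1])) for i in range(count)]


def paper_like_config(n_regions: int = 116, n_timepoints: int = 175,
                      n_controls: int = 32, n_patients: int = 32,
                      n_linear: int = 5, n_quadratic: int = 5,
                      linear_strengths: tuple[float, float] = (0.6, 0.3),
                      quadratic_strengths: tuple[float, float] = (0.2, 0.6),
                      noise_sd: float = 0.3, seed: int = 0) -> CohortConfig:
    """Two-group cohort with weakened-linear / strengthened-non-linear
    patient couplings on disjoint region pairs."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    pairs = _disjoint_pairs(n_regions, n_linear + n_quadratic, rng)
    couplings = [
        CouplingSpec(i, j, "linear", *linear_strengths)
        for i, j in pairs[:n_linear]
    ] + [
        CouplingSpec(i, j, "quadratic", *quadratic_strengths)
        for i, j in pairs[n_linear:]
    ]
    return CohortConfig(
        n_regions=n_regions, n_timepoints=n_timepoints, n_controls=n_controls,
        n_patients=n_patients, couplings=tuple(couplings), noise_sd=noise_sd,
        seed=seed,
    )


def null_config(n_regions: int = 116, n_timepoints: int = 175,
                n_controls: int = 32, n_patients: int = 32,
                noise_sd: float = 0.3, seed: int = 0) -> CohortConfig:
    """No couplings at all: both groups are pure band-limited noise."""
    return CohortConfig(
        n_regions=n_regions, n_timepoints=n_timepoints, n_controls=n_controls,
        n_patients=n_patients, couplings=(), noise_sd=noise_sd, seed=seed,
    )


def band_limited_noise(shape, rng: np.random.Generator,
                       band=(0.01, 0.08), tr_seconds: float = 2.0) -> np.ndarray:
    """White Gaussian noise band-passed (zero-phase Chebyshev I) and z-scored.

    A padding margin is simulated and trimmed so filter edge transients do
    not distort the retained window.
    """
    shape = (shape,) if np.isscalar(shape) else tuple(shape)
    pad = 64
    raw = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    sos = signal.cheby1(4, 0.5, list(band), btype="bandpass",
                        fs=1.0 / tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, raw, axis=-1)[..., pad:-pad]
    filtered = filtered - filtered.mean(axis=-1, keepdims=True)
    sd = filtered.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filtered / sd


def _zscore(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    return v / sd if sd > 0 else v


def _transform(source: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        return source
    if form == "quadratic":
        return _zscore(source**2 - (source**2).mean())
    return _zscore(np.sin(np.pi * source))


def generate_subject(config: CohortConfig, group: int,
                     rng: np.random.Generator) -> RegionalTimeSeries:
    """One subject's regional time series; ``group`` is +1 control / -1 patient."""
    if group not in (1, -1):
        raise ValueError("group must be +1 (control) or -1 (patient)")
    base = band_limited_noise(
        (config.n_regions, config.n_timepoints), rng, config.band,
        config.tr_seconds,
    )
    data = base.copy()
    for c in config.couplings:
        s = c.strength(group)
        mixed = _transform(base[c.source], c.form)
        data[c.target] = np.sqrt(1.0 - s * s) * base[c.target] + s * mixed
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal(data.shape)
    return RegionalTimeSeries(data, config.region_labels, config.tr_seconds)


def generate_motion(config: CohortConfig, rng: np.random.Generator,
                    amplitude: float = 0.05) -> MotionParameters:
    """Smooth low-amplitude random walks for the 6 rigid-body parameters."""
    steps = rng.standard_normal((6, config.n_timepoints))
    walk = np.cumsum(steps, axis=1)
    if config.n_timepoints >= 9:
        kernel = np.ones(9) / 9.0
        walk = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), 1, walk
        )
    return MotionParameters(amplitude * walk)


@dataclass(frozen=True)
class Cohort:
    """In-memory cohort: subjects, labels, ids, and the generating config."""

    subjects: tuple[RegionalTimeSeries, ...]
    labels: np.ndarray
    subject_ids: tuple[str, ...]
    config: CohortConfig
    motions: tuple[MotionParameters, ...] = ()


def _subject_rng(config: CohortConfig, position: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, position]))


def generate_cohort(config: CohortConfig, out_dir=None,
                    with_motion: bool = False) -> Cohort:
    """Generate the full two-group cohort (controls first, then patients).

    With ``out_dir`` set, per-subject TSVs, the manifest, and the
    ground-truth coupling table are written there (reproducible
    byte-for-byte from the seed); existing files raise.
    """
    subjects, labels, ids, motions = [], [], [], []
    plan = [(1, i) for i in range(config.n_controls)] + [
        (-1, i) for i in range(config.n_patients)
    ]
    for position, (group, within) in enumerate(plan):
        rng = _subject_rng(config, position)
        subjects.append(generate_subject(config, group, rng))
        if with_motion:
            motions.append(generate_motion(config, rng))
        labels.append(group)
        ids.append(
            f"control_{within + 1:02d}" if group == 1 else f"patient_{within + 1:02d}"
        )
    cohort = Cohort(
        subjects=tuple(subjects), labels=np.asarray(labels, dtype=int),
        subject_ids=tuple(ids), config=config, motions=tuple(motions),
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    from . import io as eio  # deferred: io imports simulate types

    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (sid, sub) in enumerate(zip(cohort.subject_ids, cohort.subjects)):
        path = out_dir / f"{sid}.tsv"
        if path.exists():
            raise FileExistsError(f"refusing to overwrite {path}")
        eio.write_timeseries(path, sub)
        row = {
            "subject_id": sid,
            "path": path.name,
            "label": int(cohort.labels[i]),
        }
        if cohort.motions:
            mpath = out_dir / f"{sid}_motion.tsv"
            eio.write_motion(mpath, cohort.motions[i])
            row["motion_path"] = mpath.name
        rows.append(row)
    eio.write_manifest(out_dir / "manifest.tsv", rows)
    truth = [
        {
            "region_i": c.edge[0] + 1, "region_j": c.edge[1] + 1,
            "form": c.form, "strength_control": c.strength_control,
            "strength_patient": c.strength_patient,
        }
        for c in cohort.config.couplings
    ]
    (out_dir / "ground_truth.json").write_text(
        json.dumps({"couplings": truth, "config": _config_dict(cohort.config)},
                   indent=2, sort_keys=True) + "\n"
    )


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["couplings"] = [asdict(c) for c in config.couplings]
    d["band"] = list(config.band)
    return d


def association_battery(n_pairs: int = 500, n: int = 175, seed: int = 0,
                        tr_seconds: float = 2.0):
    """Paired samples spanning all coupling forms, strengths, and noise levels.

    Cycles deterministically through linear / quadratic / sinusoidal /
    independent relationships, strengths {0.2 .. 1.0} and observation-noise
    sds {0 .. 1}; used for range checks on the association measures.
    Yields (x, y) arrays of length ``n``.
    """
    forms = ("linear", "quadratic", "sinusoidal", "independent")
    strengths = (0.2, 0.4, 0.6, 0.8, 1.0)
    noises = (0.0, 0.1, 0.3, 0.6, 1.0)
    for i in range(n_pairs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, i]))
        form = forms[i % len(forms)]
        s = strengths[(i // len(forms)) % len(strengths)]
        noise = noises[(i // (len(forms) * len(strengths))) % len(noises)]
        yield coupled_pair(form, s, noise, n, rng, tr_seconds=tr_seconds)


def coupled_pair(form: str, strength: float, noise_sd: float, n: int,
                 rng: np.random.Generator, tr_seconds: float = 2.0):
    """A single (source, target) pair under one coupling form."""
    base = band_limited_noise((2, n), rng, tr_seconds=tr_seconds)
    x = base[0]
    if form == "independent":
        y = base[1]
    else:
        s = strength
        y = np.sqrt(1.0 - s * s) * base[1] + s * _transform(x, form)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
        y = y + noise_sd * rng.standard_normal(n)
    return x, y
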