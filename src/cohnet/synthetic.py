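"""Synthetic study data: ROI atlas, coupled band-limited sources, behavior.

This module generates everything the downstream connectivity pipeline
consumes, emulating a within-subject isometric arm-exertion study:
12 subjects hold an arm flexion at five predefined exertion levels
(extremely light ... extremely hard), three trials per level, while
source-space activity in 84 Brodmann-area regions of interest is recorded
at 250 Hz in 3 s epochs.

Sources are linear mixtures of band-limited latent components plus white
sensor noise,

    x_i(t) = sum_k a_ik s_k(t) + sigma_i n_i(t),

where each s_k is unit-variance white noise band-pass filtered to its band
(zero-phase order-4 Butterworth) and n_i is unit-variance white noise.
Because the mixing is known, the magnitude-squared coherence between any
two ROIs sharing a single component has a closed form
(:func:`expected_band_coherence`), which the estimation pipeline is tested
against.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

# ---------------------------------------------------------------------------
# Experiment constants
# ---------------------------------------------------------------------------

#: Exertion levels in increasing order of demanded force.
LEVELS = (
    "extremely_light",
    "light",
    "somewhat_hard",
    "hard",
    "extremely_hard",
)

#: Published mean isometric arm force (N) per exertion level in the
#: motivating study; used as the generator's default level means.
DEFAULT_FORCE_MEANS = {
    "extremely_light": 8.04,
    "light": 13.61,
    "somewhat_hard": 34.58,
    "hard": 41.83,
    "extremely_hard": 67.35,
}

#: Published mean rate of perceived physical comfort (0-10) per level
#: (descriptive table); comfort decreases as exertion increases.
DEFAULT_RPPC_MEANS = {
    "extremely_light": 8.80,
    "light": 8.16,
    "somewhat_hard": 5.47,
    "hard": 5.00,
    "extremely_hard": 3.90,
}

#: Maximum voluntary contraction across subjects (N): mean and SD.
MVC_MEAN_N = 115.0
MVC_SD_N = 47.6


# ---------------------------------------------------------------------------
# ROI atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiEntry:
    ba_id: int
    hemisphere: str  # "left" | "right"
    lobe: str
    name: str
    # nominal centroid, approximate MNI-like mm; sign of x encodes hemisphere
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered node definitions for the 84-region Brodmann-area network.

    Ordering is fixed: Brodmann areas ascending, left hemisphere before
    right within each area.
    """

    entries: tuple[RoiEntry, ...]

    @property
    def size(self) -> int:
        return len(self.entries)

    def lookup(self, ba: int, hemisphere: str) -> RoiEntry:
        for e in self.entries:
            if e.ba_id == ba and e.hemisphere == hemisphere:
                return e
        raise KeyError(f"no ROI with BA {ba} ({hemisphere})")

    def index(self, ba: int, hemisphere: str) -> int:
        for i, e in enumerate(self.entries):
            if e.ba_id == ba and e.hemisphere == hemisphere:
                return i
        raise KeyError(f"no ROI with BA {ba} ({hemisphere})")

    def labels(self) -> list[str]:
        return [f"BA{e.ba_id}_{'L' if e.hemisphere == 'left' else 'R'}"
                for e in self.entries]

    def indices_by_lobe(self, lobe: str) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.lobe == lobe]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.size),
                "ba_id": [e.ba_id for e in self.entries],
                "hemisphere": [e.hemisphere for e in self.entries],
                "lobe": [e.lobe for e in self.entries],
                "name": [e.name for e in self.entries],
                "x": [e.x for e in self.entries],
                "y": [e.y for e in self.entries],
                "z": [e.z for e in self.entries],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RoiAtlas":
        entries = tuple(
            RoiEntry(int(r.ba_id), str(r.hemisphere), str(r.lobe),
                     str(r.name), float(getattr(r, "x", 0.0)),
                     float(getattr(r, "y", 0.0)), float(getattr(r, "z", 0.0)))
            for r in df.itertuples(index=False)
        )
        return cls(entries)


# 42 Brodmann areas x 2 hemispheres. Lobe assignments follow common
# Talairach-daemon usage. Names and centroid coordinates are nominal
# stand-ins (synthetic, approximate): nodes are labels only -- no
# computation in this package depends on anatomy.
_BA_TABLE = [
    # ba, lobe, name, (x, y, z) right-hemisphere nominal centroid
    (1, "parietal", "postcentral gyrus (primary somatosensory)", (45, -26, 52)),
    (2, "parietal", "postcentral gyrus (primary somatosensory)", (42, -30, 48)),
    (3, "parietal", "postcentral gyrus (primary somatosensory)", (38, -24, 50)),
    (4, "frontal", "precentral gyrus (primary motor)", (36, -20, 54)),
    (5, "parietal", "superior parietal lobule", (14, -44, 58)),
    (6, "frontal", "middle frontal gyrus (premotor)", (28, -4, 52)),
    (7, "parietal", "precuneus / superior parietal", (12, -62, 50)),
    (8, "frontal", "superior frontal gyrus (frontal eye field)", (22, 26, 46)),
    (9, "frontal", "middle frontal gyrus (dorsolateral prefrontal)", (32, 34, 32)),
    (10, "frontal", "superior frontal gyrus (frontopolar)", (22, 56, 8)),
    (11, "frontal", "middle frontal gyrus (orbitofrontal)", (20, 40, -16)),
    (13, "sub-lobar", "insula", (38, -4, 8)),
    (17, "occipital", "lingual gyrus (primary visual)", (10, -84, 2)),
    (18, "occipital", "cuneus (secondary visual)", (14, -82, 18)),
    (19, "occipital", "middle occipital gyrus", (32, -80, 14)),
    (20, "temporal", "inferior temporal gyrus", (48, -18, -28)),
    (21, "temporal", "middle temporal gyrus", (54, -22, -10)),
    (22, "temporal", "superior temporal gyrus", (54, -18, 4)),
    (23, "limbic", "posterior cingulate", (4, -40, 26)),
    (24, "limbic", "anterior cingulate (ventral)", (4, 16, 26)),
    (25, "limbic", "subgenual cingulate", (4, 16, -10)),
    (27, "limbic", "parahippocampal gyrus (presubiculum)", (18, -30, -8)),
    (28, "limbic", "entorhinal cortex", (20, -10, -26)),
    (29, "limbic", "posterior cingulate (retrosplenial)", (6, -46, 10)),
    (30, "limbic", "retrosplenial cingulate", (12, -52, 8)),
    (31, "parietal", "precuneus / posterior cingulate", (8, -56, 30)),
    (32, "limbic", "anterior cingulate (dorsal)", (6, 32, 20)),
    (33, "limbic", "anterior cingulate (rostral)", (4, 10, 20)),
    (34, "limbic", "parahippocampal gyrus (uncus)", (20, 2, -22)),
    (35, "limbic", "perirhinal cortex", (22, -24, -14)),
    (36, "limbic", "parahippocampal gyrus", (30, -30, -18)),
    (37, "temporal", "fusiform gyrus", (42, -52, -14)),
    (38, "temporal", "temporal pole", (40, 14, -28)),
    (39, "parietal", "angular gyrus", (44, -60, 32)),
    (40, "parietal", "supramarginal gyrus", (52, -40, 36)),
    (41, "temporal", "transverse temporal gyrus (primary auditory)", (46, -26, 10)),
    (42, "temporal", "transverse temporal gyrus (auditory association)", (60, -22, 10)),
    (43, "parietal", "postcentral gyrus (subcentral)", (56, -10, 18)),
    (44, "frontal", "precentral gyrus (pars opercularis)", (50, 12, 12)),
    (45, "frontal", "inferior frontal gyrus (pars triangularis)", (50, 26, 8)),
    (46, "frontal", "middle frontal gyrus (dorsolateral prefrontal)", (44, 40, 16)),
    (47, "frontal", "inferior frontal gyrus (pars orbitalis)", (40, 30, -12)),
]


def default_roi_atlas() -> RoiAtlas:
    """The fixed 84-entry atlas: 42 Brodmann areas x 2 hemispheres.

    The area list, lobe assignments and nominal centroids are this
    module's documented defaults (a synthetic stand-in for an anatomical
    parcellation); a user-supplied atlas CSV can override it everywhere
    an atlas is accepted.
    """
    entries = []
    for ba, lobe, name, (x, y, z) in _BA_TABLE:
        entries.append(RoiEntry(ba, "left", lobe, name, -x, y, z))
        entries.append(RoiEntry(ba, "right", lobe, name, x, y, z))
    atlas = RoiAtlas(tuple(entries))
    assert atlas.size == 84
    return atlas


# ---------------------------------------------------------------------------
# Experiment design and coupling specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    n_subjects: int = 12
    levels: tuple[str, ...] = LEVELS
    n_trials: int = 3
    epoch_seconds: float = 3.0
    sample_rate: float = 250.0

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.sample_rate))

    @property
    def n_task_epochs(self) -> int:
        return self.n_subjects * len(self.levels) * self.n_trials

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1 or not self.levels:
            raise ValueError("empty design")
        if self.epoch_seconds <= 0 or self.sample_rate <= 0:
            raise ValueError("non-positive epoch length or sample rate")


@dataclass(frozen=True)
class Component:
    """One latent band-limited source shared by a set of ROIs."""

    band: tuple[float, float]           # (f_lo, f_hi) Hz
    members: tuple[int, ...]            # node indices
    weights: tuple[float, ...]          # a_i per member, same length

    def __post_init__(self):
        if len(self.members) != len(self.weights):
            raise ValueError("members and weights must have equal length")

    def weight_of(self, node: int) -> float:
        try:
            return self.weights[self.members.index(node)]
        except ValueError:
            return 0.0


@dataclass(frozen=True)
class CouplingSpec:
    """Mixing structure for the coupled-oscillator source generator.

    ``level_gain`` multiplies the weights of the components listed in
    ``effect_components`` (indices into ``components``) depending on the
    exertion level being simulated, which is how a condition effect on
    coherence is injected.
    """

    n_roi: int
    components: tuple[Component, ...]
    noise_sd: tuple[float, ...]         # sigma_i per ROI
    level_gain: dict = field(default_factory=dict)   # level -> multiplier
    effect_components: tuple[int, ...] = ()

    def validate(self, sample_rate: float) -> None:
        if len(self.noise_sd) != self.n_roi:
            raise ValueError("noise_sd must have one entry per ROI")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise sd must be >= 0")
        nyq = sample_rate / 2.0
        for c in self.components:
            lo, hi = c.band
            if not (0.0 < lo < hi < nyq):
                raise ValueError(f"invalid band edges {c.band} for fs={sample_rate}")
            if any(m < 0 or m >= self.n_roi for m in c.members):
                raise ValueError("component references invalid node index")
        covered = set()
        for c in self.components:
            covered.update(m for m, w in zip(c.members, c.weights) if w != 0)
        for i in range(self.n_roi):
            if self.noise_sd[i] == 0 and i not in covered:
                raise ValueError(f"ROI {i} has neither signal nor noise")

    def gains_at(self, level: str | None) -> np.ndarray:
        """Per-component weight multiplier at the given exertion level."""
        g = np.ones(len(self.components))
        if level is not None and level in self.level_gain:
            for k in self.effect_components:
                g[k] = self.level_gain[level]
        return g


@dataclass
class EpochedSourceSeries:
    subject: int
    level: str
    trial: int
    sample_rate: float
    data: np.ndarray                    # (n_roi, n_samples)


# ---------------------------------------------------------------------------
# Band-limited component synthesis and its spectral oracle
# ---------------------------------------------------------------------------

_FILTER_ORDER = 4  # Butterworth band-pass, applied zero-phase (filtfilt)


def _band_sos(band: tuple[float, float], fs: float) -> np.ndarray:
    return signal.butter(_FILTER_ORDER, band, btype="bandpass",
                         fs=fs, output="sos")


def _filtered_noise(rng: np.random.Generator, n: int,
                    band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-variance white noise, zero-phase band-pass filtered."""
    white = rng.standard_normal(n)
    return signal.sosfiltfilt(_band_sos(band, fs), white)


def filtfilt_power_gain(band: tuple[float, float], freqs: np.ndarray,
                        fs: float) -> np.ndarray:
    """Power gain |H(f)|^4 of the zero-phase band-pass at given frequencies.

    Forward-backward filtering squares the amplitude response, so the
    power transfer is the fourth power of the single-pass magnitude.
    """
    _, h = signal.sosfreqz(_band_sos(band, fs), worN=freqs, fs=fs)
    return np.abs(h) ** 4


def generate_coupled_series(spec: CouplingSpec, n_samples: int,
                            sample_rate: float, rng: np.random.Generator,
                            level: str | None = None) -> np.ndarray:
    """One (n_roi, n_samples) realization of the mixing model."""
    gains = spec.gains_at(level)
    x = np.zeros((spec.n_roi, n_samples))
    for k, comp in enumerate(spec.components):
        s = _filtered_noise(rng, n_samples, comp.band, sample_rate)
        for m, w in zip(comp.members, comp.weights):
            x[m] += gains[k] * w * s
    for i, sd in enumerate(spec.noise_sd):
        if sd > 0:
            x[i] += sd * rng.standard_normal(n_samples)
    return x


def generate_sources(design: ExperimentDesign, spec: CouplingSpec,
                     seed: int) -> list[EpochedSourceSeries]:
    """Generate every task epoch of the design; bit-reproducible per seed.

    Epoch order is subject-major, then level (design order), then trial;
    each epoch draws from its own child stream of ``seed`` so the output
    is invariant to how many epochs precede it.
    """
    design.validate()
    spec.validate(design.sample_rate)
    n = design.n_samples
    root = np.random.SeedSequence(seed)
    children = root.spawn(design.n_task_epochs)
    epochs = []
    it = itertools.product(range(design.n_subjects), design.levels,
                           range(design.n_trials))
    for child, (subj, level, trial) in zip(children, it):
        rng = np.random.default_rng(child)
        data = generate_coupled_series(spec, n, design.sample_rate, rng,
                                       level=level)
        epochs.append(EpochedSourceSeries(subj, level, trial,
                                          design.sample_rate, data))
    return epochs


def expected_band_coherence(spec: CouplingSpec, i: int, j: int,
                            band: tuple[float, float],
                            sample_rate: float = 250.0,
                            level: str | None = None,
                            n_freq: int = 513) -> float:
    """Closed-form band-averaged coherence between ROIs i and j.

    Supported configurations: i and j share at most one component (each
    may additionally carry private components and noise). Per frequency,
    with P_k(f) the realized power gain of component k's zero-phase
    filter,

        S_i(f) = sum_k (g_k a_ik)^2 P_k(f) + sigma_i^2
        C_ij(f) = (g a_i a_j P_s(f))^2 / (S_i(f) S_j(f))

    for the shared component s; the band value is the unweighted mean
    over an in-band frequency grid, matching how the estimator averages
    per-bin coherence. Flat white noise spectra cancel, so only relative
    powers matter.
    """
    if i == j:
        raise ValueError("expected coherence is defined for i != j")
    shared = [k for k, c in enumerate(spec.components)
              if c.weight_of(i) != 0 and c.weight_of(j) != 0]
    if len(shared) > 1:
        raise ValueError("closed form supports at most one shared component")
    freqs = np.linspace(band[0], band[1], n_freq, endpoint=False)
    gains = spec.gains_at(level)
    s_i = np.full(n_freq, float(spec.noise_sd[i]) ** 2)
    s_j = np.full(n_freq, float(spec.noise_sd[j]) ** 2)
    cross = np.zeros(n_freq)
    for k, comp in enumerate(spec.components):
        a_i, a_j = comp.weight_of(i), comp.weight_of(j)
        if a_i == 0 and a_j == 0:
            continue
        p = filtfilt_power_gain(comp.band, freqs, sample_rate)
        s_i += (gains[k] * a_i) ** 2 * p
        s_j += (gains[k] * a_j) ** 2 * p
        if k in shared:
            cross = gains[k] ** 2 * a_i * a_j * p
    denom = s_i * s_j
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cross ** 2 / denom, 0.0)
    return float(np.mean(c))


def in_band_component_power(band: tuple[float, float],
                            component_band: tuple[float, float],
                            sample_rate: float = 250.0,
                            n_freq: int = 513) -> float:
    """Mean in-band power gain of a component's realized filter."""
    freqs = np.linspace(band[0], band[1], n_freq, endpoint=False)
    return float(np.mean(filtfilt_power_gain(component_band, freqs,
                                             sample_rate)))


def noise_sd_for_target(target: float, band: tuple[float, float],
                        component_band: tuple[float, float] | None = None,
                        sample_rate: float = 250.0) -> float:
    """Noise sd giving approximately ``target`` coherence for two ROIs
    sharing one unit-weight component (symmetric noise).

    From the closed form with equal powers, c = (S/(S+sigma^2))^2, so
    sigma^2 = S (1/sqrt(c) - 1) with S the mean in-band power gain.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target must be in (0, 1]")
    cb = component_band if component_band is not None else band
    s = in_band_component_power(band, cb, sample_rate)
    return math.sqrt(s * (1.0 / math.sqrt(target) - 1.0))


# ---------------------------------------------------------------------------
# Built-in coupling scenarios
# ---------------------------------------------------------------------------

ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 30.0)


def scenario_strong_alpha_frontoparietal(
        atlas: RoiAtlas | None = None,
        base_weight: float = 1.0,
        noise_sd: float = 1.0,
        level_gains: dict | None = None) -> CouplingSpec:
    """Built-in scenario: an alpha-band component over frontal and parietal
    ROIs whose coupling strength rises with exertion level.

    All ROIs carry unit white noise; frontal+parietal ROIs additionally
    share one alpha component with a level-dependent gain, so alpha-band
    coherence -- and hence clustering among those nodes -- increases from
    the lightest to the hardest exertion level.
    """
    atlas = atlas or default_roi_atlas()
    members = tuple(sorted(atlas.indices_by_lobe("frontal")
                           + atlas.indices_by_lobe("parietal")))
    if level_gains is None:
        level_gains = {
            "extremely_light": 0.55,
            "light": 0.7,
            "somewhat_hard": 0.9,
            "hard": 1.2,
            "extremely_hard": 1.6,
        }
    comp = Component(ALPHA_BAND, members,
                     tuple(base_weight for _ in members))
    return CouplingSpec(
        n_roi=atlas.size,
        components=(comp,),
        noise_sd=tuple(noise_sd for _ in range(atlas.size)),
        level_gain=dict(level_gains),
        effect_components=(0,),
    )


def scenario_null(n_roi: int = 84, noise_sd: float = 1.0) -> CouplingSpec:
    """All ROIs independent white noise: no true coupling anywhere."""
    return CouplingSpec(n_roi=n_roi, components=(),
                        noise_sd=tuple(noise_sd for _ in range(n_roi)))


# ---------------------------------------------------------------------------
# Behavioral data
# ---------------------------------------------------------------------------

@dataclass
class BehavioralRecord:
    subject: int
    level: str
    trial: int
    force: float        # N
    mvc: float          # N, the subject's maximum voluntary contraction
    rppc: float         # perceived physical comfort, 0-10


# Defaults for the additive noise model, chosen so the randomized-block
# decomposition of the generated data has participant and error variance
# components on the scale the published behavioral ANOVA tables imply,
# while keeping truncation at the physical bounds a rare event.
DEFAULT_SUBJECT_SD_FORCE = 10.0
DEFAULT_RESIDUAL_SD_FORCE = 12.0
DEFAULT_SUBJECT_SD_RPPC = 0.99
DEFAULT_RESIDUAL_SD_RPPC = 1.28


def _truncated_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float, max_tries: int = 1000) -> float:
    """Normal draw re-drawn until it lands in [lo, hi]."""
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def generate_behavior(design: ExperimentDesign,
                      level_means_force: dict | None = None,
                      level_means_rppc: dict | None = None,
                      subject_sd: float = DEFAULT_SUBJECT_SD_FORCE,
                      residual_sd: float = DEFAULT_RESIDUAL_SD_FORCE,
                      subject_sd_rppc: float = DEFAULT_SUBJECT_SD_RPPC,
                      residual_sd_rppc: float = DEFAULT_RESIDUAL_SD_RPPC,
                      seed: int = 0) -> list[BehavioralRecord]:
    """Behavioral force / comfort records with a subject block effect.

    force_slt = mu_level + b_s + eps_slt, b_s ~ N(0, subject_sd^2),
    eps ~ N(0, residual_sd^2), re-drawn below 0 N; rppc analogous on the
    0-10 comfort scale. MVC is drawn once per subject (three maximal
    trials, the largest kept) and attached to every record.
    """
    design.validate()
    means_f = dict(DEFAULT_FORCE_MEANS if level_means_force is None
                   else level_means_force)
    means_r = dict(DEFAULT_RPPC_MEANS if level_means_rppc is None
                   else level_means_rppc)
    for lv in design.levels:
        if lv not in means_f:
            raise KeyError(f"missing force mean for level {lv!r}")
        if lv not in means_r:
            raise KeyError(f"missing rppc mean for level {lv!r}")
    if min(subject_sd, residual_sd, subject_sd_rppc, residual_sd_rppc) < 0:
        raise ValueError("standard deviations must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for s in range(design.n_subjects):
        b_force = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
        b_rppc = rng.normal(0.0, subject_sd_rppc) if subject_sd_rppc > 0 else 0.0
        mvc_base = _truncated_draw(rng, MVC_MEAN_N, MVC_SD_N, 20.0, math.inf)
        mvc = max(_truncated_draw(rng, mvc_base, 0.05 * mvc_base, 0.0,
                                  math.inf) for _ in range(3))
        for lv in design.levels:
            for t in range(design.n_trials):
                force = _truncated_draw(rng, means_f[lv] + b_force,
                                        residual_sd, 0.0, math.inf)
                rppc = _truncated_draw(rng, means_r[lv] + b_rppc,
                                       residual_sd_rppc, 0.0, 10.0)
                records.append(BehavioralRecord(s, lv, t, force, mvc, rppc))
    return records


def behavior_to_frame(records: list[BehavioralRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "level": [r.level for r in records],
            "trial": [r.trial for r in records],
            "force_N": [r.force for r in records],
            "mvc_N": [r.mvc for r in records],
            "rppc": [r.rppc for r in records],
        }
    )
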