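"""Synthetic paired source/target data with run/trial/volume structure.

The generator emulates a two-class perception-to-imagery decoding problem:
each sample is one volume, volumes come in trials of a single class, trials
share a class-independent random deviation (within-trial correlation), and a
compact spatial subregion carries the class information.

Generative model per sample:

    x = class_sign * pattern_domain + u_trial + eps,
    u_trial ~ N(0, sigma_trial^2 I)  shared by all volumes of a trial,
    eps     ~ N(0, sigma_noise^2 I)  independent per volume,

with class_sign = -1 for class 0 and +1 for class 1.  The source pattern is
beta (norm = ``effect``, supported on the informative voxels).  The target
pattern is s * R_phi(beta), a rotation of beta by the concept angle phi
(degrees) within the plane spanned by beta and a fixed orthogonal nuisance
direction eta, scaled by the covariate scale s; a covariate offset b shifts
all target samples regardless of class.  phi = 0 means no concept shift and
phi = 180 is a full label flip.  The nuisance direction is supported on a
spatially DISJOINT nuisance region, so under partial concept shift the
target-specific signal occupies different voxels than the source signal and
a source-trained decoder carries no information about the rotated component.

Under this equal-covariance Gaussian model, the optimal (Bayes) balanced
accuracy in a domain is Phi(||pattern|| / sqrt(sigma_trial^2 +
sigma_noise^2)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .data_model import BrainMask, LabeledDataset

__all__ = ["SynthConfig", "GroundTruth", "generate_pair",
           "generate_matrix_pair", "default_mask"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real study's structure at desk scale: a 12 voxel
    cube at 3 mm resolution with an inscribed spherical 'brain', two
    informative spheres of 6 mm radius, 4 source runs and 2 target runs with
    7 trials per run per class and 7 volumes per trial (392 source and 196
    target samples).
    """

    grid_shape: tuple = (12, 12, 12)
    voxel_size_mm: float = 3.0
    informative_spheres: tuple = (((3, 3, 4), 9.0), ((9, 8, 5), 9.0))
    nuisance_spheres: tuple = (((4, 8, 9), 9.0),)
    n_runs_source: int = 4
    n_runs_target: int = 2
    trials_per_run_per_class: int = 7
    volumes_per_trial: int = 7
    effect: float = 2.5
    sigma_trial: float = 0.5
    sigma_noise: float = 1.0
    covariate_scale: float = 0.5
    covariate_offset: float = 0.0
    concept_angle_deg: float = 0.0
    n_features: int = 30          # matrix mode only
    n_informative: int = 10       # matrix mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volumes_per_trial < 1:
            raise ValueError("volumes_per_trial must be >= 1")
        if not 0 <= self.concept_angle_deg <= 180:
            raise ValueError("concept_angle_deg must lie in [0, 180]")
        if self.effect < 0 or self.sigma_trial < 0:
            raise ValueError("effect and sigma_trial must be nonnegative")
        if not self.sigma_noise > 0:
            raise ValueError("sigma_noise must be positive")
        if not self.covariate_scale > 0:
            raise ValueError("covariate_scale must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SynthConfig":
        d = json.loads(s)
        d["grid_shape"] = tuple(d["grid_shape"])
        for key in ("informative_spheres", "nuisance_spheres"):
            d[key] = tuple((tuple(c), r) for c, r in d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted: patterns, shift and Bayes ceilings.

    ``source_support`` / ``target_support`` mark the voxels carrying class
    signal in each domain (they differ under partial concept shift, where
    the rotated component lives on the nuisance region);
    ``informative_mask`` is their union.
    """

    beta_source: np.ndarray
    beta_target: np.ndarray
    covariate_offset: float
    sigma_total: float
    source_support: np.ndarray = field(init=False)
    target_support: np.ndarray = field(init=False)
    informative_mask: np.ndarray = field(init=False)
    bayes_accuracy_source: float = field(init=False)
    bayes_accuracy_target: float = field(init=False)

    def __post_init__(self) -> None:
        tol = 1e-12
        self.source_support = np.abs(self.beta_source) > tol
        self.target_support = np.abs(self.beta_target) > tol
        self.informative_mask = self.source_support | self.target_support
        self.bayes_accuracy_source = float(
            norm.cdf(np.linalg.norm(self.beta_source) / self.sigma_total))
        self.bayes_accuracy_target = float(
            norm.cdf(np.linalg.norm(self.beta_target) / self.sigma_total))


def default_mask(config: SynthConfig) -> BrainMask:
    """Spherical 'brain' inscribed in the grid (brains are not boxes)."""
    shape = np.array(config.grid_shape)
    center = (shape - 1) / 2.0
    gx, gy, gz = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = ((gx - center[0]) ** 2 + (gy - center[1]) ** 2
          + (gz - center[2]) ** 2)
    radius = shape.min() / 2.0
    return BrainMask(inside=d2 <= radius ** 2,
                     voxel_size_mm=config.voxel_size_mm)


def _sphere_feature_mask(spheres, config: SynthConfig,
                         mask: BrainMask, what: str) -> np.ndarray:
    coords = mask.coords
    out = np.zeros(len(coords), dtype=bool)
    for center, r_mm in spheres:
        center = np.asarray(center, dtype=float)
        if ((center < 0) | (center >= np.array(config.grid_shape))).any():
            raise ValueError(f"{what} sphere center {tuple(center)} off-grid")
        d2 = ((coords - center) ** 2).sum(axis=1) * config.voxel_size_mm ** 2
        out |= d2 <= r_mm ** 2
    if len(spheres) and not out.any():
        raise ValueError(f"{what} spheres miss the mask entirely")
    return out


def _make_patterns(config: SynthConfig, informative: np.ndarray,
                   nuisance: np.ndarray):
    """Source pattern beta and target pattern s * R_phi(beta).

    beta is uniform over the informative support with norm ``effect``; the
    nuisance direction eta is the unit-norm uniform pattern over the
    (disjoint) nuisance support.  The target pattern rotates beta by phi in
    the (beta, eta) plane and scales by the covariate scale.
    """
    if (informative & nuisance).any():
        raise ValueError("informative and nuisance supports must be disjoint")
    phi = np.deg2rad(config.concept_angle_deg)
    needs_eta = abs(np.sin(phi)) > 1e-9
    if needs_eta and not nuisance.any():
        raise ValueError(
            "a nonzero concept angle needs a nonempty nuisance region")
    beta = np.where(informative, 1.0, 0.0)
    beta *= config.effect / np.linalg.norm(beta)
    if nuisance.any():
        eta = np.where(nuisance, 1.0, 0.0)
        eta /= np.linalg.norm(eta)
    else:
        eta = np.zeros_like(beta)
    beta_t = config.covariate_scale * (
        np.cos(phi) * beta + np.sin(phi) * np.linalg.norm(beta) * eta)
    # exact zeros at the quadrant angles (cos/sin of pi/2, pi are O(1e-16))
    beta_t[np.abs(beta_t) < 1e-12 * max(config.effect, 1.0)] = 0.0
    return beta, beta_t


def _sample_domain(config: SynthConfig, pattern: np.ndarray, offset: float,
                   n_runs: int, rng: np.random.Generator, domain: str,
                   trial_id_start: int, voxel_index) -> LabeledDataset:
    tpr, vpt = config.trials_per_run_per_class, config.volumes_per_trial
    n_feat = len(pattern)
    rows, labels, trials, runs = [], [], [], []
    trial_id = trial_id_start
    for run in range(n_runs):
        # class order shuffled within each run
        classes = rng.permutation(np.repeat([0, 1], tpr))
        for cls in classes:
            sign = 2 * cls - 1
            u = rng.normal(0.0, config.sigma_trial, size=n_feat)
            eps = rng.normal(0.0, config.sigma_noise, size=(vpt, n_feat))
            rows.append(sign * pattern + offset + u + eps)
            labels.extend([cls] * vpt)
            trials.extend([trial_id] * vpt)
            runs.extend([run] * vpt)
            trial_id += 1
    return LabeledDataset(
        X=np.vstack(rows), y=np.array(labels), trial_id=np.array(trials),
        run_id=np.array(runs), domain=domain, voxel_index=voxel_index)


def generate_pair(config: SynthConfig,
                  mask: BrainMask | None = None):
    """Volumetric source/target pair on a brain mask.

    Returns (source, target, ground_truth, mask); features follow the mask's
    C-order voxel ordering so the datasets plug straight into the searchlight.
    """
    mask = mask or default_mask(config)
    rng = np.random.default_rng(config.seed)
    informative = _sphere_feature_mask(config.informative_spheres, config,
                                       mask, "informative")
    nuisance = _sphere_feature_mask(config.nuisance_spheres, config,
                                    mask, "nuisance")
    beta, beta_t = _make_patterns(config, informative, nuisance)
    coords = mask.coords
    source = _sample_domain(config, beta, 0.0, config.n_runs_source, rng,
                            "source", 0, coords)
    n_src_trials = config.n_runs_source * 2 * config.trials_per_run_per_class
    target = _sample_domain(config, beta_t, config.covariate_offset,
                            config.n_runs_target, rng, "target",
                            n_src_trials, coords)
    truth = GroundTruth(
        beta_source=beta, beta_target=beta_t,
        covariate_offset=config.covariate_offset,
        sigma_total=float(np.hypot(config.sigma_trial, config.sigma_noise)))
    return source, target, truth, mask


def generate_matrix_pair(config: SynthConfig):
    """Non-spatial (ROI-style) source/target pair: plain feature matrices.

    The first ``n_informative`` of ``n_features`` features carry the class
    pattern; the next block of equal size is the nuisance support for the
    concept-shift rotation (so ``2 * n_informative <= n_features`` is needed
    whenever the concept angle is strictly between 0 and 180 degrees);
    otherwise identical to :func:`generate_pair`.
    """
    if not 0 < config.n_informative <= config.n_features:
        raise ValueError("need 0 < n_informative <= n_features")
    rng = np.random.default_rng(config.seed)
    informative = np.zeros(config.n_features, dtype=bool)
    informative[:config.n_informative] = True
    nuisance = np.zeros(config.n_features, dtype=bool)
    n_nuis = min(config.n_informative, config.n_features - config.n_informative)
    nuisance[config.n_informative:config.n_informative + n_nuis] = True
    beta, beta_t = _make_patterns(config, informative, nuisance)
    source = _sample_domain(config, beta, 0.0, config.n_runs_source, rng,
                            "source", 0, None)
    n_src_trials = config.n_runs_source * 2 * config.trials_per_run_per_class
    target = _sample_domain(config, beta_t, config.covariate_offset,
                            config.n_runs_target, rng, "target",
                            n_src_trials, None)
    truth = GroundTruth(
        beta_source=beta, beta_target=beta_t,
        covariate_offset=config.covariate_offset,
        sigma_total=float(np.hypot(config.sigma_trial, config.sigma_noise)))
    return source, target, truth
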