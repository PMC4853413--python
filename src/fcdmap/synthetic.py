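"""Synthetic resting-state phantoms with known connectivity structure.

The generator plants latent *networks* in a rectangular grid.  A voxel v
belonging to network k with coupling weight w has time series

    x_v(t) = sqrt(w) * z_k(t) + sqrt(1 - w) * eps_v(t),

with z_k and eps_v independent unit-variance white noise, so the expected
Pearson correlation between any two voxels of the same network is exactly
w.  That closed form makes the expected degree of every voxel computable
by hand: with a connection threshold of 0.6, a network voxel connects to
(nearly) all of its partners when w is well above 0.6 and to (nearly)
none when well below, while off-network voxels are pure noise and stay
near degree zero.

Networks are *unilateral* (one hemisphere) or *homotopic*: a homotopic
network's voxel set is the given seed set plus its mirror image across
the mid-sagittal plane, all sharing one latent signal — the synthetic
analogue of bilateral resting-state networks, and the lever that plants
contralateral (inter-hemispheric) degree.

Group structure enters through ``group_effect``: for subjects labelled
"case" a network's coupling weight is multiplied by it, emulating reduced
network coupling in a patient group.  Cohorts additionally draw a
per-subject, per-network coupling multiplier, and a clinical severity
score linearly tied (negatively, by default) to the multiplier of a
designated network — so regional connectivity strength and symptom
severity co-vary across subjects the way the downstream partial
correlation analysis assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import NuisanceSet, TimeSeriesVolume
from .errors import ConfigurationError
from .grids import LEFT, RIGHT, VoxelGrid

LATERALITIES = ("unilateral-left", "unilateral-right", "homotopic")


def _mirror_x(ijk: np.ndarray, nx: int) -> np.ndarray:
    """Reflect voxel indices across the mid-sagittal plane of the grid."""
    out = ijk.copy()
    out[:, 0] = nx - 1 - out[:, 0]
    return out


@dataclass
class NetworkSpec:
    """One latent network.

    ``seed_voxels`` are (i, j, k) grid indices; for a homotopic network
    they must lie in the left hemisphere and the member set is the seed
    plus its mirror image.  ``coupling_weight`` is the fraction of each
    member's variance carried by the shared latent signal, hence the
    expected within-network pairwise correlation.  ``group_effect``
    multiplies the coupling weight for subjects in group "case".
    """

    name: str
    seed_voxels: np.ndarray
    coupling_weight: float
    laterality: str = "unilateral-left"
    group_effect: float = 1.0

    def __post_init__(self):
        self.seed_voxels = np.atleast_2d(np.asarray(self.seed_voxels, dtype=int))
        if self.seed_voxels.shape[1] != 3:
            raise ConfigurationError(f"network {self.name}: seed_voxels must be (n, 3)")
        if not 0 <= self.coupling_weight < 1:
            raise ConfigurationError(
                f"network {self.name}: coupling_weight must be in [0, 1)"
            )
        if self.laterality not in LATERALITIES:
            raise ConfigurationError(
                f"network {self.name}: laterality must be one of {LATERALITIES}"
            )
        if self.group_effect < 0:
            raise ConfigurationError(f"network {self.name}: group_effect must be >= 0")

    def member_voxels(self, grid_shape) -> np.ndarray:
        """All member voxel indices (seed plus mirror for homotopic)."""
        if self.laterality == "homotopic":
            mirrored = _mirror_x(self.seed_voxels, grid_shape[0])
            return np.vstack([self.seed_voxels, mirrored])
        return self.seed_voxels

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seed_voxels"] = self.seed_voxels.tolist()
        return d


@dataclass
class NuisanceModel:
    """How many synthetic nuisance signals to draw and how strongly they
    contaminate every voxel.  Amplitude 0 still writes the regressor table
    (so the regression stage always has something to regress) but leaves
    the voxel data clean."""

    n_regressors: int = 9
    amplitude: float = 0.0

    def regressor_names(self) -> list[str]:
        if self.n_regressors == 9:
            return [f"motion_{i}" for i in range(1, 7)] + ["wm", "csf", "global_signal"]
        return [f"reg_{i}" for i in range(1, self.n_regressors + 1)]


@dataclass
class PhantomSpec:
    """Full description of a phantom study's data-generating process."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float = 2.0
    networks: list[NetworkSpec] = field(default_factory=list)
    n_timepoints: int = 200
    tr_s: float = 2.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    nuisance: NuisanceModel = field(default_factory=NuisanceModel)
    ar1: float = 0.0  # lag-1 autocorrelation of latent/noise processes; off by default
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 integers, each >= 4")
        if not self.voxel_size_mm > 0:
            raise ConfigurationError("voxel_size_mm must be positive")
        if self.n_timepoints < 50:
            raise ConfigurationError("n_timepoints must be >= 50")
        if not self.tr_s > 0:
            raise ConfigurationError("tr_s must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 <= self.ar1 < 1:
            raise ConfigurationError("ar1 must be in [0, 1)")

    # ------------------------------------------------------------ serialization

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "networks": [n.to_dict() for n in self.networks],
            "n_timepoints": self.n_timepoints,
            "tr_s": self.tr_s,
            "noise_sd": self.noise_sd,
            "baseline": self.baseline,
            "nuisance": asdict(self.nuisance),
            "ar1": self.ar1,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["networks"] = [NetworkSpec(**n) for n in d.get("networks", [])]
        d["nuisance"] = NuisanceModel(**d.get("nuisance", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------- grid


def make_phantom_grid(spec: PhantomSpec) -> VoxelGrid:
    """Build the grid for a phantom: centered affine, full gray-matter mask.

    The affine is diagonal with the world origin at the grid center, so
    the central sagittal plane of an odd-width grid sits exactly at
    world x = 0 (labelled midline) and an even-width grid has equal left
    and right halves with no midline voxels.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = [-vs * (nx - 1) / 2, -vs * (ny - 1) / 2, -vs * (nz - 1) / 2]
    grid = VoxelGrid(mask=np.ones(spec.grid_shape, dtype=bool), affine=affine)
    _validate_networks(spec, grid)
    return grid


def _validate_networks(spec: PhantomSpec, grid: VoxelGrid) -> None:
    shape = np.array(spec.grid_shape)
    seen: set[tuple[int, int, int]] = set()
    for net in spec.networks:
        members = net.member_voxels(spec.grid_shape)
        if (members < 0).any() or (members >= shape).any():
            raise ConfigurationError(
                f"network {net.name}: voxels fall outside grid {spec.grid_shape}"
            )
        if not grid.mask[tuple(members.T)].all():
            raise ConfigurationError(
                f"network {net.name}: voxels fall outside the gray-matter mask"
            )
        hemi = grid.hemisphere[tuple(net.seed_voxels.T)]
        if net.laterality == "unilateral-left" and not (hemi == LEFT).all():
            raise ConfigurationError(f"network {net.name}: seed not entirely left")
        if net.laterality == "unilateral-right" and not (hemi == RIGHT).all():
            raise ConfigurationError(f"network {net.name}: seed not entirely right")
        if net.laterality == "homotopic" and not (hemi == LEFT).all():
            raise ConfigurationError(
                f"network {net.name}: homotopic seed must lie in the left hemisphere"
            )
        tuples = set(map(tuple, members))
        if len(tuples) < len(members):
            raise ConfigurationError(
                f"network {net.name}: duplicate members (seed touches the midline?)"
            )
        if tuples & seen:
            raise ConfigurationError(f"network {net.name}: overlaps another network")
        seen |= tuples


# ------------------------------------------------------------------- subjects


def _unit_noise(rng: np.random.Generator, shape, ar1: float) -> np.ndarray:
    """White (or AR(1), rescaled to unit variance) noise, time on axis 0."""
    x = rng.standard_normal(shape)
    if ar1 > 0:
        from scipy.signal import lfilter

        x = lfilter([1.0], [1.0, -ar1], x, axis=0) * np.sqrt(1 - ar1**2)
    return x


def simulate_subject(
    grid: VoxelGrid,
    spec: PhantomSpec,
    group: str = "control",
    seed: int | np.random.SeedSequence = 0,
    multipliers: dict[str, float] | None = None,
) -> tuple[TimeSeriesVolume, NuisanceSet]:
    """Simulate one subject's 4D volume and nuisance table.

    ``multipliers`` optionally scales each network's coupling weight for
    this subject (used by cohorts to plant inter-subject variability);
    subjects in group "case" additionally apply each network's
    ``group_effect``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    T = spec.n_timepoints
    n_total = int(np.prod(spec.grid_shape))

    data = _unit_noise(rng, (T, n_total), spec.ar1)  # eps for every voxel
    for net in spec.networks:
        w = net.coupling_weight
        if group == "case":
            w *= net.group_effect
        if multipliers is not None:
            w *= multipliers.get(net.name, 1.0)
        w = min(max(w, 0.0), 0.999)
        z = _unit_noise(rng, (T,), spec.ar1)
        flat = np.ravel_multi_index(tuple(net.member_voxels(spec.grid_shape).T), spec.grid_shape)
        data[:, flat] = np.sqrt(w) * z[:, None] + np.sqrt(1.0 - w) * data[:, flat]

    data *= spec.noise_sd

    names = spec.nuisance.regressor_names()
    regressors = _unit_noise(rng, (T, len(names)), spec.ar1)
    if spec.nuisance.amplitude != 0.0:
        data += spec.nuisance.amplitude * regressors.sum(axis=1, keepdims=True)
    data += spec.baseline

    vol = TimeSeriesVolume(
        data=data.T.reshape(*spec.grid_shape, T), tr_s=spec.tr_s, affine=grid.affine
    )
    nuis = NuisanceSet(pd.DataFrame(regressors, columns=names))
    return vol, nuis


# -------------------------------------------------------------------- cohorts


@dataclass
class ScoreModel:
    """Clinical severity score: alpha + beta * m + noise, where m is the
    subject's coupling multiplier for the designated network.  beta < 0
    plants severity rising as regional connectivity falls."""

    alpha: float = 10.0
    beta: float = -20.0
    noise_sd: float = 10.0
    network: str | None = None  # defaults to the first network


@dataclass
class CohortStudy:
    """A simulated cohort.  Subject volumes are regenerated on demand from
    per-subject seeds rather than held in memory."""

    grid: VoxelGrid
    spec: PhantomSpec
    cohort: pd.DataFrame
    multipliers: pd.DataFrame  # subject x network ground-truth couplings
    _subject_seeds: list[np.random.SeedSequence]

    def subject(self, index: int) -> tuple[TimeSeriesVolume, NuisanceSet]:
        row = self.cohort.iloc[index]
        mult = self.multipliers.iloc[index].to_dict()
        return simulate_subject(
            self.grid, self.spec, group=row["group"],
            seed=self._subject_seeds[index], multipliers=mult,
        )

    def iter_subjects(self):
        for i in range(len(self.cohort)):
            yield self.cohort.iloc[i], *self.subject(i)

    def save(self, outdir) -> None:
        """Write mask, hemisphere labels, per-subject 4D NIfTI + nuisance
        TSV, and the cohort CSV into ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.grid.save(out / "mask.nii.gz", out / "hemisphere.nii.gz")
        self.spec.to_yaml(out / "phantom.yaml")
        for row, vol, nuis in self.iter_subjects():
            vol.save(out / f"{row['subject_id']}_bold.nii.gz")
            nuis.save(out / f"{row['subject_id']}_nuisance.tsv")
        self.cohort.to_csv(out / "cohort.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(
                {"multipliers": self.multipliers.to_dict(orient="list")}, fh, indent=2
            )


def simulate_cohort(
    grid: VoxelGrid,
    spec: PhantomSpec,
    n_case: int,
    n_control: int,
    score_model: ScoreModel | None = None,
    seed: int = 0,
    coupling_jitter: tuple[float, float] | dict[str, tuple[float, float]] = (0.6, 1.0),
) -> CohortStudy:
    """Simulate a case/control cohort with ages, sexes and severity scores.

    Each subject draws an independent coupling multiplier per network,
    uniform over ``coupling_jitter`` (a single (lo, hi) range, or a dict
    mapping network names to ranges — e.g. a wide range on the network
    that drives the clinical score and a narrow one elsewhere); cases
    additionally carry each network's ``group_effect``.  Ages are uniform
    on [8, 30] years and sex is male with probability 0.85, so covariate
    adjustment downstream has something to adjust for.  Deterministic
    given the seed.
    """
    if n_case < 3 or n_control < 3:
        raise ConfigurationError("need at least 3 subjects per group")
    if not spec.networks:
        raise ConfigurationError("cohort simulation needs at least one network")
    if isinstance(coupling_jitter, dict):
        jitter_for = lambda name: coupling_jitter.get(name, (0.6, 1.0))  # noqa: E731
    else:
        jitter_for = lambda name: coupling_jitter  # noqa: E731
    for net in spec.networks:
        lo, hi = jitter_for(net.name)
        if not 0 <= lo <= hi:
            raise ConfigurationError(
                f"coupling_jitter for network {net.name!r} must satisfy 0 <= lo <= hi"
            )
    score_model = score_model or ScoreModel()
    designated = score_model.network or spec.networks[0].name
    if designated not in {n.name for n in spec.networks}:
        raise ConfigurationError(f"score network {designated!r} not in phantom spec")

    root = np.random.SeedSequence(seed)
    demo_ss, subj_root = root.spawn(2)
    demo_rng = np.random.default_rng(demo_ss)
    n = n_case + n_control
    groups = ["case"] * n_case + ["control"] * n_control
    net_names = [net.name for net in spec.networks]

    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": groups,
            "age": demo_rng.uniform(8.0, 30.0, size=n).round(1),
            "sex": np.where(demo_rng.random(n) < 0.85, "M", "F"),
        }
    )
    multipliers = pd.DataFrame(
        {
            name: demo_rng.uniform(*jitter_for(name), size=n)
            for name in net_names
        }
    )
    cohort["score"] = (
        score_model.alpha
        + score_model.beta * multipliers[designated].to_numpy()
        + score_model.noise_sd * demo_rng.standard_normal(n)
    ).round(2)

    return CohortStudy(
        grid=grid,
        spec=spec,
        cohort=cohort,
        multipliers=multipliers,
        _subject_seeds=list(subj_root.spawn(n)),
    )


# ------------------------------------------------------- canned study designs


def _block(x0, y0, z0, dx=3, dy=3, dz=3) -> np.ndarray:
    """Voxel indices of a solid rectangular block."""
    return np.array(
        [(i, j, k)
         for i in range(x0, x0 + dx)
         for j in range(y0, y0 + dy)
         for k in range(z0, z0 + dz)]
    )


def group_study_spec(
    group_effect: float = 0.5,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    n_timepoints: int = 200,
) -> PhantomSpec:
    """Phantom for case/control comparisons on a 16^3 grid: a homotopic
    network whose coupling drops in cases ("affected"), a homotopic
    network common to both groups ("stable", which keeps each subject's
    overall connectivity — the normalization denominator — away from
    zero), and a left-only network ("unilateral")."""
    return PhantomSpec(
        grid_shape=grid_shape,
        networks=[
            NetworkSpec("affected", _block(2, 3, 3), 0.8, "homotopic", group_effect),
            NetworkSpec("stable", _block(2, 10, 9), 0.8, "homotopic", 1.0),
            NetworkSpec("unilateral", _block(2, 10, 3), 0.8, "unilateral-left", 1.0),
        ],
        n_timepoints=n_timepoints,
    )


def clinical_study_spec(
    grid_shape: tuple[int, int, int] = (10, 10, 10),
    n_timepoints: int = 200,
) -> PhantomSpec:
    """Smaller phantom for severity-correlation studies: an "affected"
    homotopic network whose per-subject coupling drives the clinical
    score, plus a "stable" homotopic network."""
    return PhantomSpec(
        grid_shape=grid_shape,
        networks=[
            NetworkSpec("affected", _block(1, 2, 2, 2, 2, 2), 0.8, "homotopic", 1.0),
            NetworkSpec("stable", _block(1, 6, 6, 2, 2, 2), 0.8, "homotopic", 1.0),
        ],
        n_timepoints=n_timepoints,
    )
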