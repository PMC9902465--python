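"""Seeded synthetic two-group cohorts with planted, known group differences.

The generator stands in for a real case/control resting-state cohort: each
group has its own ROI-signal covariance, the groups differ only at a known
list of "effect" edges (correlation-scale shift ``effect_delta``), and signals
are stationary Gaussian AR(1) processes mapped through the Cholesky factor of
the target covariance.  An optional state-switching variant draws
piecewise-stationary segments from several covariance states with geometric
dwell times, which is what the dynamic (windowed) connectivity measures are
sensitive to.  Small 4D voxel grids with planted amplitude or homogeneity
effects exercise the voxel measures, and a covariate table (sex, scanner
manufacturer, site, head motion) with configurable group imbalance exercises
the residualization stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from brainfc.connectivity import RoiTimeSeries
from brainfc.voxel import VoxelSeries

_BAND = (0.01, 0.1)  # Hz, the low-frequency band the voxel measures target


def nearest_spd_corr(a: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping at ``eig_floor`` then re-normalization to unit diagonal."""
    a = (a + a.T) / 2
    vals, vecs = np.linalg.eigh(a)
    vals = np.clip(vals, eig_floor, None)
    spd = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(spd))
    spd = spd / np.outer(d, d)
    np.fill_diagonal(spd, 1.0)
    return (spd + spd.T) / 2


def _check_spd(a: np.ndarray, name: str) -> None:
    vals = np.linalg.eigvalsh((a + a.T) / 2)
    if vals.min() <= 0:
        raise ValueError(f"{name} is not positive definite after repair "
                         f"(min eigenvalue {vals.min():.3e})")


@dataclass
class GroupModel:
    """Generative model for one group's ROI signals."""

    n_rois: int
    base_cov: np.ndarray
    effect_edges: list[tuple[int, int]] = field(default_factory=list)
    effect_delta: float = 0.0
    state_covs: list[np.ndarray] | None = None
    mean_dwell: float = 40.0

    def __post_init__(self) -> None:
        self.base_cov = np.asarray(self.base_cov, dtype=float)
        if self.base_cov.shape != (self.n_rois, self.n_rois):
            raise ValueError("base_cov must be N x N")
        if not np.allclose(np.diag(self.base_cov), 1.0):
            raise ValueError("base_cov must have unit diagonal")
        _check_spd(self.base_cov, "base_cov")
        seen = set()
        for i, j in self.effect_edges:
            if i == j:
                raise ValueError("effect edge endpoints must differ")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError("effect edges must be distinct")
            seen.add(key)
        if not -1 < self.effect_delta < 1:
            raise ValueError("effect_delta must lie in (-1, 1)")
        if self.state_covs is not None:
            for k, s in enumerate(self.state_covs):
                _check_spd(np.asarray(s), f"state cov {k}")


@dataclass
class CovariateModel:
    """Per-covariate group-imbalance parameters.

    ``sex_p`` / ``manufacturer_p`` / ``site_probs`` give the category
    probabilities per group (case, control); ``motion_group_shift`` is an
    additive shift of log head motion in the case group (0 = no confounding).
    """

    sex_p: tuple[float, float] = (0.5, 0.5)
    manufacturer_p: tuple[float, float] = (0.75, 0.75)
    n_sites: int = 4
    motion_log_mean: float = -2.5
    motion_log_sd: float = 0.4
    motion_group_shift: float = 0.0


@dataclass
class CohortSpec:
    """Simulation settings shared by both groups."""

    n_subjects_per_group: tuple[int, int] = (60, 60)
    t_points: int = 370
    tr_seconds: float = 0.8
    ar_coefficient: float = 0.3
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_points < 2:
            raise ValueError("t_points must be >= 2")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")


@dataclass
class Cohort:
    """Assembled two-group cohort with its planted ground truth."""

    subjects: list[RoiTimeSeries]
    labels: np.ndarray  # 1 = case, 0 = control
    covariates: "object"  # pandas DataFrame, one row per subject
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.labels):
            raise ValueError("one label per subject required")
        if len(self.covariates) != len(self.subjects):
            raise ValueError("one covariate row per subject required")
        if not (0 < self.labels.sum() < len(self.labels)):
            raise ValueError("both groups must be non-empty")


def _random_base_corr(n_rois: int, rng: np.random.Generator) -> np.ndarray:
    """A well-conditioned random correlation matrix with mild off-diagonals."""
    q = rng.standard_normal((n_rois, n_rois)) / np.sqrt(n_rois)
    a = q @ q.T + 2.0 * np.eye(n_rois)
    d = np.sqrt(np.diag(a))
    return nearest_spd_corr(a / np.outer(d, d))


def make_group_models(
    n_rois: int,
    n_effect_edges: int,
    effect_delta: float,
    n_states: int = 0,
    seed: int = 0,
    mean_dwell: float = 40.0,
) -> tuple[GroupModel, GroupModel]:
    """Two group models identical except at the planted effect edges.

    The case group's correlation at each effect edge is shifted by
    ``effect_delta`` (clipped into (-0.97, 0.97)) and the perturbed matrix is
    repaired to the nearest SPD correlation matrix.  With ``n_states > 0``
    the case group additionally carries state covariances whose effect edges
    alternate in sign across states (a purely dynamic difference).
    """
    max_edges = n_rois * (n_rois - 1) // 2
    if n_effect_edges > max_edges:
        raise ValueError("more effect edges than ROI pairs")
    rng = np.random.default_rng(seed)
    base = _random_base_corr(n_rois, rng)
    all_pairs = [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]
    chosen = [all_pairs[k] for k in rng.choice(max_edges, n_effect_edges, replace=False)]

    def _plant(mat: np.ndarray) -> np.ndarray:
        for i, j in chosen:
            v = np.clip(base[i, j] + effect_delta, -0.97, 0.97)
            mat[i, j] = mat[j, i] = v
        return mat

    # perturb; repair only if the shift breaks positive definiteness, and
    # re-clamp the planted entries so exactly the effect edges differ
    pert = _plant(base.copy())
    if np.linalg.eigvalsh(pert).min() <= 1e-8:
        for _ in range(20):
            pert = _plant(nearest_spd_corr(pert))
            if np.linalg.eigvalsh(pert).min() > 1e-8:
                break
        else:
            raise ValueError(
                "perturbed covariance not SPD after repair; reduce effect_delta "
                "or the number of effect edges"
            )
    _check_spd(pert, "perturbed covariance")

    state_covs = None
    if n_states > 0:
        state_covs = []
        for s in range(n_states):
            sc = base.copy()
            sign = 1.0 if s % 2 == 0 else -1.0
            for i, j in chosen:
                v = np.clip(base[i, j] + sign * effect_delta, -0.97, 0.97)
                sc[i, j] = sc[j, i] = v
            sc = nearest_spd_corr(sc)
            state_covs.append(sc)

    control = GroupModel(n_rois, base, [], 0.0)
    case = GroupModel(
        n_rois,
        pert if n_states == 0 else base,
        list(chosen),
        effect_delta,
        state_covs=state_covs,
        mean_dwell=mean_dwell,
    )
    return case, control


def _ar1_noise(t: int, n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) innovations, T x N."""
    eps = rng.standard_normal((t, n))
    if phi == 0:
        return eps
    out = np.empty_like(eps)
    out[0] = eps[0]
    scale = np.sqrt(1 - phi**2)
    for k in range(1, t):
        out[k] = phi * out[k - 1] + scale * eps[k]
    return out


def simulate_subject(
    model: GroupModel, spec: CohortSpec, subject_seed: int
) -> RoiTimeSeries:
    """One subject's T x N series from the group model.

    Static scenario: AR(1)-colored Gaussian noise mapped through the Cholesky
    factor of the target covariance, so both the cross-covariance and the
    lag-1 autocorrelation are controlled.  Dynamic scenario: piecewise
    stationary segments drawn from the state covariances with geometric
    dwell times (mean ``model.mean_dwell``).
    """
    rng = np.random.default_rng(subject_seed)
    t, n = spec.t_points, model.n_rois
    z = _ar1_noise(t, n, spec.ar_coefficient, rng)
    if model.state_covs is None:
        data = z @ np.linalg.cholesky(model.base_cov).T
    else:
        chols = [np.linalg.cholesky(c).T for c in model.state_covs]
        data = np.empty((t, n))
        pos = 0
        state = int(rng.integers(len(chols)))
        p_switch = 1.0 / model.mean_dwell
        while pos < t:
            dwell = int(rng.geometric(p_switch))
            end = min(pos + dwell, t)
            data[pos:end] = z[pos:end] @ chols[state]
            pos = end
            state = (state + 1 + int(rng.integers(len(chols) - 1))) % len(chols) \
                if len(chols) > 1 else state
    return RoiTimeSeries(data, tr_seconds=spec.tr_seconds, subject_id=f"seed{subject_seed}")


def simulate_voxel_volume(
    shape: tuple[int, int, int],
    active_regions: list[tuple[slice, slice, slice]],
    effect_type: str,
    t_points: int = 200,
    tr_seconds: float = 0.8,
    seed: int = 0,
    effect_strength: float = 1.0,
    shared_fraction: float = 0.8,
    mask: np.ndarray | None = None,
) -> VoxelSeries:
    """Small 4D volume with planted amplitude or homogeneity effects.

    ``amplitude`` effects add a band-limited (0.01-0.1 Hz) signal of amplitude
    ``effect_strength`` inside the active regions, boosting ALFF/fALFF there.
    ``homogeneity`` effects mix a shared latent band-limited signal into every
    voxel of the region with weight ``shared_fraction`` (1.0 means identical
    series, hence ReHo = 1), raising rank concordance.
    """
    if effect_type not in {"amplitude", "homogeneity", "none"}:
        raise ValueError("effect_type must be 'amplitude', 'homogeneity' or 'none'")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    for reg in active_regions:
        sel = np.zeros(shape, dtype=bool)
        sel[reg] = True
        if (sel & ~mask).any():
            raise ValueError("active region extends outside the mask")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal(shape + (t_points,))
    tt = np.arange(t_points) * tr_seconds
    # band-limited latent: sum of in-band sinusoids with random phases
    freqs = np.linspace(_BAND[0] + 0.005, _BAND[1] - 0.005, 5)

    def band_signal() -> np.ndarray:
        phases = rng.uniform(0, 2 * np.pi, len(freqs))
        s = np.sum([np.sin(2 * np.pi * f * tt + p) for f, p in zip(freqs, phases)], axis=0)
        return s / s.std()

    for reg in active_regions:
        if effect_type == "amplitude":
            data[reg] += effect_strength * band_signal()
        elif effect_type == "homogeneity":
            shared = band_signal()
            block = data[reg]
            data[reg] = shared_fraction * shared + (1 - shared_fraction) * block
    data[~mask] = 0.0
    return VoxelSeries(data, tr_seconds=tr_seconds, mask=mask)


def _sample_covariates(
    n_case: int, n_control: int, cm: CovariateModel, rng: np.random.Generator
):
    import pandas as pd

    labels = np.r_[np.ones(n_case, int), np.zeros(n_control, int)]
    sex, manu, site, motion = [], [], [], []
    for lab in labels:
        g = 0 if lab == 1 else 1
        sex.append("F" if rng.random() < cm.sex_p[g] else "M")
        manu.append("SIEMENS" if rng.random() < cm.manufacturer_p[g] else "GE")
        site.append(f"site{int(rng.integers(cm.n_sites)) + 1}")
        mu = cm.motion_log_mean + (cm.motion_group_shift if lab == 1 else 0.0)
        motion.append(float(np.exp(rng.normal(mu, cm.motion_log_sd))))
    return pd.DataFrame(
        {"sex": sex, "manufacturer": manu, "site": site, "motion": motion}
    ), labels


def make_cohort(models: tuple[GroupModel, GroupModel], spec: CohortSpec) -> Cohort:
    """Assemble a cohort: case model first, control model second.

    Per-subject seeds are drawn from a generator seeded with ``spec.seed`` so
    the whole cohort is a deterministic function of the spec.  The planted
    effect edges and delta are recorded in ``ground_truth``.
    """
    case_model, control_model = models
    n_case, n_control = spec.n_subjects_per_group
    rng = np.random.default_rng(spec.seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_case + n_control)
    covariates, labels = _sample_covariates(
        n_case, n_control, spec.covariate_model, rng
    )
    subjects = []
    for idx, seed in enumerate(subject_seeds):
        model = case_model if labels[idx] == 1 else control_model
        ts = simulate_subject(model, spec, int(seed))
        ts.subject_id = f"sub{idx:04d}"
        subjects.append(ts)
    gt = {
        "effect_edges": list(case_model.effect_edges),
        "effect_delta": case_model.effect_delta,
        "dynamic": case_model.state_covs is not None,
    }
    return Cohort(subjects, labels, covariates, ground_truth=gt)
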