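"""Synthetic cohorts with the statistical structure the analysis assumes.

The real inputs (ROI BOLD series, motion traces, covariates) come from
patient data that are not publicly available, so this module generates
cohorts in which every quantity the pipeline estimates has a known ground
truth: block-community covariance over atlas systems (stationary AR(1)
temporal smoothing so spectra reach the 0.01-0.08 Hz band), a disease-burden
(FW) effect that attenuates within-DMN connectivity, outcome paths from DMN
integration and FW to the processing-speed score, motion spikes that
exercise the scrubbing rule, and serial metrics with configurable
between/within variance components.

Defaults emulate the genetic-SVD (cross-sectional, n=41, TR 0.7 s, 675
volumes, FW in [0.18, 0.56]) and sporadic-SVD serial (n=44, monthly visits,
median 8) study arms.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats as sps

from fcgraph.atlas import NodeAtlas, UNASSIGNED, _validate_table
from fcgraph.preprocess import MotionParams, NuisanceSet, RoiTimeSeries


class SynthError(ValueError):
    pass


def make_synthetic_atlas(
    n_dmn: int = 24,
    n_fpcn: int = 20,
    n_hsmn: int = 20,
    n_vn: int = 20,
    n_other: int = 6,
    n_unassigned: int = 10,
    seed: int = 0,
) -> NodeAtlas:
    """A reduced atlas with the same system structure as the 264-node set.

    Used for scaled-down simulations: the four analyzed systems each keep
    at least the 20-node minimum, one small extra system belongs to the
    global network only, and some nodes stay unassigned.  Coordinates are
    arbitrary points in an MNI-sized box.
    """
    blocks = [
        ("Default mode", n_dmn),
        ("Fronto-parietal Task Control", n_fpcn),
        ("Sensory/somatomotor Hand", n_hsmn),
        ("Visual", n_vn),
        ("Salience", n_other),
        (UNASSIGNED, n_unassigned),
    ]
    rng = np.random.default_rng(seed)
    labels = [name for name, n in blocks for _ in range(n)]
    n_total = len(labels)
    coords = rng.uniform([-70, -105, -45], [70, 70, 80], size=(n_total, 3)).round(1)
    df = pd.DataFrame(
        {
            "node_id": np.arange(n_total),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "system": labels,
        }
    )
    return NodeAtlas(_validate_table(df))


@dataclass(frozen=True)
class CohortConfig:
    """Generating conditions for a synthetic cohort.

    Defaults follow the cross-sectional genetic-SVD arm: 41 analyzed
    subjects, single visit, multiband fMRI at TR 0.7 s with 675 acquired
    volumes, FW (the scalar white-matter free-water disease-burden score)
    in [0.18, 0.56].  Correlation targets and effect slopes are the planted
    ground truth echoed back for calibration tests.
    """

    n_subjects: int = 41
    n_visits: int = 1
    tr: float = 0.7
    n_volumes: int = 675
    atlas: NodeAtlas = None
    # community structure
    base_within_system_r: float = 0.30
    base_between_system_r: float = 0.05
    ar_coefficient: float = 0.4
    # disease burden and effect paths
    fw_mean: float = 0.28
    fw_sd: float = 0.07
    fw_bounds: tuple = (0.18, 0.56)
    effect_fw_on_dmn: float = -0.06     # within-DMN r change per SD of FW
    dmn_integration_noise_sd: float = 0.04
    effect_ge_on_tmtb: float = 0.0      # std slope of TMT-B on DMN integration
    effect_fw_on_tmtb_direct: float = 0.0
    tmtb_noise_sd: float = 1.0
    # motion
    motion_drift_step_mm: float = 0.002
    spike_rate: float = 0.01            # per volume
    spike_fd_range: tuple = (0.6, 2.0)  # mm
    # nuisance confounds mixed into the node series
    n_confounds: int = 3
    confound_loading: float = 0.5
    # serial (test-retest) arm
    visit_interval_days: float = 30.0
    variance_ratio: float = 1.0         # sigma^2_between / sigma^2_within
    metric_within_sd: float = 1.0
    metric_grand_mean: float = 0.0
    age_inflation: float = 0.0          # within-SD increase per SD of age
    fw_slope_per_day: float = 0.00017
    fw_between_sd: float = 0.03
    fw_visit_sd: float = 0.0033
    seed: int = 0

    def __post_init__(self):
        for name in ("base_within_system_r", "base_between_system_r"):
            if not -1 < getattr(self, name) < 1:
                raise SynthError(f"{name} must lie in (-1, 1)")
        if not 0 <= self.spike_rate <= 1:
            raise SynthError("spike_rate must lie in [0, 1]")
        if self.seed is None:
            raise SynthError("seed is mandatory")
        if self.atlas is None:
            object.__setattr__(self, "atlas", make_synthetic_atlas())

    def cadasil_like(self, **overrides) -> "CohortConfig":
        """The planted-mediation regime: FW attenuates DMN integration,
        DMN integration raises processing-speed performance, plus a direct
        FW effect -- the effect-size regime of the cross-sectional arm."""
        params = dict(
            effect_fw_on_dmn=-0.05,
            effect_ge_on_tmtb=0.65,
            effect_fw_on_tmtb_direct=-0.2,
            tmtb_noise_sd=0.6,
        )
        params.update(overrides)
        return replace(self, **params)


def _system_blocks(atlas: NodeAtlas) -> np.ndarray:
    """Integer block label per node (each system, incl. unassigned, is a block)."""
    systems = atlas.systems.to_numpy()
    _, labels = np.unique(systems, return_inverse=True)
    return labels


def _block_covariance(atlas: NodeAtlas, within_r, between_r: float, dmn_r: float) -> np.ndarray:
    blocks = _system_blocks(atlas)
    same = blocks[:, None] == blocks[None, :]
    cov = np.where(same, within_r, between_r)
    dmn = (atlas.systems == "Default mode").to_numpy()
    cov[np.ix_(dmn, dmn)] = dmn_r
    np.fill_diagonal(cov, 1.0)
    return cov


def generate_timeseries(
    config: CohortConfig,
    rng: np.random.Generator,
    fw: float,
    dmn_within_r: float | None = None,
    subject_id: str = "s000",
    visit_id: str = "v00",
) -> RoiTimeSeries:
    """Stationary AR(1)-smoothed multivariate Gaussian draw with block
    covariance over atlas systems; within-DMN correlation may be attenuated
    as a function of FW (``dmn_within_r`` overrides when given)."""
    if dmn_within_r is None:
        fw_z = (fw - config.fw_mean) / config.fw_sd
        dmn_within_r = config.base_within_system_r + config.effect_fw_on_dmn * fw_z
    cov = _block_covariance(
        config.atlas, config.base_within_system_r, config.base_between_system_r, dmn_within_r
    )
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise SynthError(
            "implied covariance is not positive-definite "
            f"(within={config.base_within_system_r}, between={config.base_between_system_r}, "
            f"dmn={dmn_within_r:.3f})"
        )
    T, N = config.n_volumes, config.atlas.n_nodes
    eps = rng.standard_normal((T, N)) @ L.T
    phi = config.ar_coefficient
    # z_t = phi z_{t-1} + sqrt(1-phi^2) eps_t keeps the stationary covariance
    z = signal.lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], eps, axis=0)
    z[0] = eps[0]  # stationary start
    return RoiTimeSeries(data=z, tr=config.tr, subject_id=subject_id, visit_id=visit_id)


def generate_motion(config: CohortConfig, rng: np.random.Generator) -> MotionParams:
    """Slow random-walk drift plus step-displacement spikes whose FD
    magnitudes are drawn from ``spike_fd_range``."""
    T = config.n_volumes
    drift = np.cumsum(rng.normal(0, config.motion_drift_step_mm, size=(T, 6)), axis=0)
    drift[:, 3:] /= 50.0  # comparable arc-length contribution for rotations
    spikes = np.flatnonzero(rng.random(T - 1) < config.spike_rate) + 1
    for t in spikes:
        # persistent step on the x translation -> a single FD excursion at t
        drift[t:, 0] += rng.uniform(*config.spike_fd_range) * rng.choice([-1, 1])
    return MotionParams(params=drift)


def _generate_confounds(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Independent low-frequency confound time-courses (whole-brain/WM/CSF
    stand-ins): heavily AR-smoothed unit-variance noise."""
    T = config.n_volumes
    raw = rng.standard_normal((T, config.n_confounds))
    smooth = signal.lfilter([1.0], [1.0, -0.95], raw, axis=0)
    return smooth / smooth.std(axis=0)


def generate_covariates(
    config: CohortConfig,
    rng: np.random.Generator,
    dmn_integration: np.ndarray | None = None,
) -> pd.DataFrame:
    """Subject covariate table with Table-1-like marginals.

    The processing-speed score is generated from the subject's ground-truth
    DMN integration (``dmn_integration``, z-scored internally) and FW via
    the configured effect slopes; age, sex and vascular risk factors are
    drawn independently.
    """
    n = config.n_subjects
    lo, hi = config.fw_bounds
    a, b = (lo - config.fw_mean) / config.fw_sd, (hi - config.fw_mean) / config.fw_sd
    fw = sps.truncnorm.rvs(a, b, loc=config.fw_mean, scale=config.fw_sd, size=n, random_state=rng)
    fw_z = (fw - fw.mean()) / fw.std(ddof=1)
    if dmn_integration is None:
        dmn_integration = config.effect_fw_on_dmn * fw_z + config.dmn_integration_noise_sd * rng.standard_normal(n)
    gi_z = (dmn_integration - dmn_integration.mean()) / max(dmn_integration.std(ddof=1), 1e-12)
    tmtb = (
        config.effect_ge_on_tmtb * gi_z
        + config.effect_fw_on_tmtb_direct * fw_z
        + config.tmtb_noise_sd * rng.standard_normal(n)
    )
    age = np.clip(rng.normal(52, 8, n), 30, 65).round(0)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "fw": fw,
            "tmtb_z": tmtb,
            "age": age,
            "sex": rng.random(n) < 0.66,
            "mean_fd": np.abs(rng.normal(0.15, 0.05, n)),
            "brain_volume": rng.normal(0.76, 0.04, n),
            "wmh_volume": np.exp(rng.normal(np.log(0.04), 0.8, n)),
            "hypertension": rng.random(n) < 0.27,
            "diabetes": rng.random(n) < 0.05,
            "hypercholesterolemia": rng.random(n) < 0.44,
            "smoking": rng.random(n) < 0.66,
        }
    ).astype({c: int for c in ("sex", "hypertension", "diabetes", "hypercholesterolemia", "smoking")})


@dataclass(frozen=True)
class SyntheticCohort:
    """Per subject x visit raw inputs plus the generating ground truth."""

    config: CohortConfig
    timeseries: dict = field(repr=False)
    motion: dict = field(repr=False)
    nuisance: dict = field(repr=False)
    covariates: pd.DataFrame = field(repr=False)
    ground_truth: dict = field(repr=False)

    @property
    def keys(self):
        return sorted(self.timeseries)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort: time series, motion, nuisance, covariates.

    The motion parameters are included among the nuisance regressors
    (canonical K = 6 + ``n_confounds``), and the confounds are mixed into
    the node series with loading ``confound_loading`` so nuisance
    regression has real structure to remove.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    # ground-truth DMN integration per subject
    lo, hi = config.fw_bounds
    covariates = generate_covariates(config, rng)
    fw = covariates["fw"].to_numpy()
    fw_z = (fw - fw.mean()) / fw.std(ddof=1)
    dmn_r = (
        config.base_within_system_r
        + config.effect_fw_on_dmn * fw_z
        + config.dmn_integration_noise_sd * rng.standard_normal(n)
    )
    # regenerate the outcome from the realized integration parameter
    gi_z = (dmn_r - dmn_r.mean()) / max(dmn_r.std(ddof=1), 1e-12)
    tmtb = (
        config.effect_ge_on_tmtb * gi_z
        + config.effect_fw_on_tmtb_direct * fw_z
        + config.tmtb_noise_sd * rng.standard_normal(n)
    )
    covariates = covariates.assign(tmtb_z=tmtb)

    timeseries, motion, nuisance = {}, {}, {}
    mean_fds = np.zeros(n)
    from fcgraph.preprocess import compute_fd  # local import avoids cycle at module load

    for i, subject in enumerate(covariates["subject_id"]):
        for v in range(config.n_visits):
            visit = f"v{v:02d}"
            ts = generate_timeseries(
                config, rng, fw[i], dmn_within_r=dmn_r[i], subject_id=subject, visit_id=visit
            )
            mot = generate_motion(config, rng)
            confounds = _generate_confounds(config, rng)
            mixing = rng.standard_normal((config.n_confounds, ts.n_nodes)) * config.confound_loading
            ts = replace(ts, data=ts.data + confounds @ mixing)
            timeseries[(subject, visit)] = ts
            motion[(subject, visit)] = mot
            nuisance[(subject, visit)] = NuisanceSet(
                regressors=np.column_stack([mot.params, confounds])
            )
            if v == 0:
                mean_fds[i] = compute_fd(mot).mean_fd
    covariates = covariates.assign(mean_fd=mean_fds)
    ground_truth = {
        "dmn_within_r": dmn_r,
        "fw": fw,
        "tmtb_z": tmtb,
        "config": config,
    }
    return SyntheticCohort(
        config=config,
        timeseries=timeseries,
        motion=motion,
        nuisance=nuisance,
        covariates=covariates,
        ground_truth=ground_truth,
    )


def generate_serial_metrics(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Serial (test-retest) metric values: subject mean + visit noise.

    Between/within variances follow ``variance_ratio`` =
    sigma^2_between / sigma^2_within.  When ``age_inflation`` is non-zero
    and a covariate table is supplied, each subject's within-SD is scaled
    by (1 + age_inflation * z(age)), emulating higher across-visit
    variability in older subjects.
    """
    if config.n_visits < 3:
        raise SynthError("serial generation needs n_visits >= 3")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k = config.n_subjects, config.n_visits
    sw = config.metric_within_sd
    sb = np.sqrt(config.variance_ratio) * sw
    subj_means = config.metric_grand_mean + sb * rng.standard_normal(n)
    within_sd = np.full(n, sw)
    if config.age_inflation != 0:
        if covariates is None:
            raise SynthError("age_inflation requires a covariate table")
        age_z = sps.zscore(covariates["age"].to_numpy(float), ddof=1)
        within_sd = np.clip(sw * (1 + config.age_inflation * age_z), 0.05 * sw, None)
    rows = []
    for i in range(n):
        noise = within_sd[i] * rng.standard_normal(k)
        for v in range(k):
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "visit_id": f"v{v:02d}",
                    "time_days": v * config.visit_interval_days,
                    "value": subj_means[i] + noise[v],
                }
            )
    return pd.DataFrame(rows)


def generate_serial_fw(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Serial FW values: stable subject level, slow linear drift, small
    visit noise -- the high-reliability regime of the disease-burden score."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1 if config.seed is not None else None)
    n, k = config.n_subjects, config.n_visits
    base = config.fw_mean + config.fw_between_sd * rng.standard_normal(n)
    rows = []
    for i in range(n):
        for v in range(k):
            t = v * config.visit_interval_days
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "visit_id": f"v{v:02d}",
                    "time_days": t,
                    "value": base[i] + config.fw_slope_per_day * t + config.fw_visit_sd * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


def generate_mediation_data(
    a: float, b: float, c_prime: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (x, m, y) with population standardized paths exactly (a, b, c').

    x ~ N(0,1); m = a x + sqrt(1-a^2) e1; y = b m + c' x + s e2 with s
    chosen so Var(y) = 1, hence the population indirect effect is a*b.
    """
    if not abs(a) < 1:
        raise SynthError("|a| must be < 1")
    resid_var = 1.0 - b**2 - c_prime**2 - 2 * a * b * c_prime
    if resid_var <= 0:
        raise SynthError("path coefficients imply non-positive outcome residual variance")
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(1 - a**2) * rng.standard_normal(n)
    y = b * m + c_prime * x + np.sqrt(resid_var) * rng.standard_normal(n)
    return x, m, y
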