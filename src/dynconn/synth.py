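"""Synthetic cohorts with state-switching functional connectivity.

The generator is a hidden-Markov covariance-switching model: each subject's
BOLD-like signal is drawn volume-by-volume from a zero-mean multivariate
normal whose covariance is set by a latent connectivity "state" that
persists for geometrically distributed dwell times.  The group manipulation
targets the switching rate only — patients dwell in each state for a
shorter time than controls — so the injected effect is specifically
*dynamic* rather than a change in connectivity strength.  Faster switching
should surface as higher temporal variability, lower temporal correlation
coefficient and shorter characteristic temporal path length.

Covariates (age, sex, education, head motion, site) are drawn from simple
parametric models with, by default, no effect on the signal; a symptom
score is linked linearly to each patient's realized switching rate so that
the severity correlation has a known recoverable direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .windows import ROITimeSeries

__all__ = [
    "CohortConfig",
    "SubjectGroundTruth",
    "generate_state_sequence",
    "make_state_covariances",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``dwell_mean_vols`` gives each group's typical (median) dwell time in
    volumes; every subject draws an individual mean dwell from a lognormal
    around that median with log-scale spread ``dwell_log_sigma``, so
    switching rate varies between subjects of the same group (set the
    sigma to 0 for a homogeneous group).  The default gap (patients 35,
    controls 115 at 230 volumes) places controls in a near-stable regime
    with a couple of state transitions per scan and patients in a
    frequently reconfiguring one.
    """

    n_patients: int = 40
    n_controls: int = 40
    regions: int = 20
    volumes: int = 230
    tr_s: float = 2.0
    n_states: int = 3
    n_blocks: int = 4
    within_block_r: float = 0.6
    state_covariances: tuple | None = None  # overrides the block recipe
    dwell_mean_vols: dict = field(
        default_factory=lambda: {"MDD": 35.0, "HC": 115.0}
    )
    dwell_log_sigma: dict = field(
        default_factory=lambda: {"MDD": 0.45, "HC": 0.30}
    )
    observation_noise_sd: float = 0.5
    fd_noise_gain: float = 0.0  # optional motion -> noise coupling, default off
    n_sites: int = 2
    symptom_intercept: float = 14.0
    symptom_slope: float = 120.0  # HAMD points per unit switch rate (per volume)
    symptom_noise_sd: float = 3.0
    fedn_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regions < 2 or self.volumes < 2:
            raise ValueError("need at least 2 regions and 2 volumes")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for g, d in self.dwell_mean_vols.items():
            if d < 1:
                raise ValueError(f"dwell_mean_vols[{g!r}] must be >= 1")
        for g, s in self.dwell_log_sigma.items():
            if s < 0:
                raise ValueError(f"dwell_log_sigma[{g!r}] must be >= 0")
        if self.state_covariances is not None:
            covs = tuple(np.asarray(c, dtype=float) for c in self.state_covariances)
            if len(covs) != self.n_states:
                raise ValueError("need one covariance per state")
            for c in covs:
                if c.shape != (self.regions, self.regions):
                    raise ValueError("covariance shape must be regions x regions")
                if np.abs(c - c.T).max() > 1e-10:
                    raise ValueError("state covariance must be symmetric")
                if np.linalg.eigvalsh(c).min() <= 0:
                    raise ValueError("state covariance must be positive-definite")
            object.__setattr__(self, "state_covariances", covs)


@dataclass(frozen=True, eq=False)
class SubjectGroundTruth:
    subject_id: str
    group: str
    state_sequence: np.ndarray
    n_transitions: int
    realized_switch_rate: float  # transitions per volume step
    dwell_mean_vols: float  # the subject's drawn mean dwell parameter
    covariates: dict
    symptom: float


def generate_state_sequence(
    volumes: int, n_states: int, dwell_mean_vols: float, rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov state sequence with geometric dwell times.

    Stay probability is 1 - 1/dwell_mean_vols, jumps are uniform among the
    other states; run lengths are therefore geometric with mean
    ``dwell_mean_vols``.  With a single state (or infinite dwell) the
    sequence is constant.
    """
    if volumes < 1:
        raise ValueError("volumes must be >= 1")
    if dwell_mean_vols < 1:
        raise ValueError("dwell_mean_vols must be >= 1")
    cur = int(rng.integers(n_states))
    if n_states == 1 or not np.isfinite(dwell_mean_vols):
        return np.full(volumes, cur, dtype=np.int64)
    p = 1.0 / dwell_mean_vols
    states: list[int] = []
    runs: list[int] = []
    remaining = volumes
    while remaining > 0:
        run = int(rng.geometric(p)) if p > 0 else remaining
        run = min(run, remaining)
        states.append(cur)
        runs.append(run)
        remaining -= run
        jump = int(rng.integers(n_states - 1))
        cur = jump if jump < cur else jump + 1
    return np.repeat(np.asarray(states, dtype=np.int64), runs)


def make_state_covariances(config: CohortConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Community-block state covariances: unit variance, correlation
    ``within_block_r`` inside blocks, 0 between; the block partition is a
    fresh random permutation of regions per state, so states differ in
    which regions co-fluctuate."""
    if config.state_covariances is not None:
        return [np.array(c) for c in config.state_covariances]
    N, B, r = config.regions, config.n_blocks, config.within_block_r
    if not 0 <= r < 1:
        raise ValueError("within_block_r must lie in [0, 1)")
    sizes = [N // B + (1 if i < N % B else 0) for i in range(B)]
    covs = []
    for _ in range(config.n_states):
        perm = rng.permutation(N)
        C = np.eye(N)
        start = 0
        for sz in sizes:
            block = perm[start : start + sz]
            C[np.ix_(block, block)] = r
            start += sz
        np.fill_diagonal(C, 1.0)
        covs.append(C)
    return covs


def _symptom(config: CohortConfig, switch_rate: float, rng) -> float:
    score = (
        config.symptom_intercept
        + config.symptom_slope * switch_rate
        + rng.normal(0.0, config.symptom_noise_sd)
    )
    return float(max(score, 0.0))


def generate_subject(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    state_covariances=None,
    subject_id: str = "sub",
) -> tuple[ROITimeSeries, SubjectGroundTruth]:
    """Draw one subject: latent state path, signal, covariates, symptom."""
    covs = (
        state_covariances
        if state_covariances is not None
        else make_state_covariances(config, rng)
    )
    chols = [np.linalg.cholesky(c) for c in covs]
    median = config.dwell_mean_vols[group]
    sigma = config.dwell_log_sigma.get(group, 0.0)
    dwell = float(np.clip(median * np.exp(sigma * rng.standard_normal()), 1.0, 1e9))
    seq = generate_state_sequence(config.volumes, config.n_states, dwell, rng)
    age = float(np.clip(rng.normal(38.0, 12.0), 18.0, 65.0))
    sex = "male" if rng.random() < 0.5 else "female"
    education = float(np.clip(rng.normal(12.0, 3.0), 6.0, 22.0))
    mean_fd = float(rng.gamma(4.0, 0.03))

    z = rng.standard_normal((config.volumes, config.regions))
    X = np.empty_like(z)
    for s in range(config.n_states):
        idx = seq == s
        if idx.any():
            X[idx] = z[idx] @ chols[s].T
    noise_sd = config.observation_noise_sd * (1.0 + config.fd_noise_gain * mean_fd)
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)

    n_trans = int((seq[1:] != seq[:-1]).sum())
    switch_rate = n_trans / max(config.volumes - 1, 1)
    is_patient = group != "HC"
    symptom = _symptom(config, switch_rate, rng) if is_patient else float("nan")
    ts = ROITimeSeries(data=X, tr_s=config.tr_s)
    truth = SubjectGroundTruth(
        subject_id=subject_id,
        group=group,
        state_sequence=seq,
        n_transitions=n_trans,
        realized_switch_rate=switch_rate,
        dwell_mean_vols=dwell,
        covariates={
            "age": age, "sex": sex, "education": education, "mean_fd": mean_fd
        },
        symptom=symptom,
    )
    return ts, truth


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[tuple[str, ROITimeSeries]], pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: time series, phenotype table, ground truth.

    Subjects are assigned to sites round-robin within group, which
    guarantees every site contains both groups whenever each group has at
    least ``n_sites`` members (checked).  Randomness is split into
    per-subject substreams spawned from the config seed, so any subject is
    reproducible independent of generation order.
    """
    for label, count in (("patients", config.n_patients), ("controls", config.n_controls)):
        if count < 0:
            raise ValueError(f"negative number of {label}")
    both = config.n_patients > 0 and config.n_controls > 0
    if both and min(config.n_patients, config.n_controls) < config.n_sites:
        raise ValueError(
            "each group needs at least n_sites subjects so every site "
            "contains both groups"
        )
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_patients + config.n_controls
    streams = ss.spawn(n_total + 1)
    shared_rng = np.random.default_rng(streams[0])
    covs = make_state_covariances(config, shared_rng)

    groups = ["MDD"] * config.n_patients + ["HC"] * config.n_controls
    fedn_cut = int(round(config.fedn_fraction * config.n_patients))
    patient_order = shared_rng.permutation(config.n_patients)

    ts_list: list[tuple[str, ROITimeSeries]] = []
    pheno_rows = []
    truth_rows = []
    site_counter = {"MDD": 0, "HC": 0}
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:04d}"
        rng = np.random.default_rng(streams[i + 1])
        ts, truth = generate_subject(
            config, group, rng, state_covariances=covs, subject_id=sid
        )
        site = f"site{site_counter[group] % config.n_sites + 1:02d}"
        site_counter[group] += 1
        if group == "MDD":
            fedn = "FEDN" if patient_order[i] < fedn_cut else "nonFEDN"
            duration = float(rng.lognormal(3.0, 0.8))
        else:
            fedn = "not_applicable"
            duration = float("nan")
        pheno_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": truth.covariates["age"],
                "sex": truth.covariates["sex"],
                "education": truth.covariates["education"],
                "mean_fd": truth.covariates["mean_fd"],
                "site": site,
                "hamd": truth.symptom,
                "duration_months": duration,
                "fedn_status": fedn,
            }
        )
        truth_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "n_transitions": truth.n_transitions,
                "realized_switch_rate": truth.realized_switch_rate,
                "dwell_mean_vols": truth.dwell_mean_vols,
                "state_sequence": "".join(map(str, truth.state_sequence)),
            }
        )
        ts_list.append((sid, ts))
    pheno = pd.DataFrame(pheno_rows)
    truth = pd.DataFrame(truth_rows)
    if both:
        tab = pd.crosstab(pheno["site"], pheno["group"])
        if ((tab > 0).sum(axis=1) < 2).any():
            raise ValueError("site assignment produced a single-group site")
    return ts_list, pheno, truth


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    if d.get("state_covariances") is not None:
        d["state_covariances"] = [np.asarray(c).tolist() for c in d["state_covariances"]]
    return d
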