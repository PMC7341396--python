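"""Synthetic four-stage cohort generator.

Emulates the statistical structure a staged resting-state fMRI study
assumes once preprocessing has reduced each subject to a T x N matrix of
ROI time series: 90 AAL regions, ~130 retained volumes, and four ordered
diagnostic stages (NC, EMCI, LMCI, AD).  Each subject's time series is
drawn as T i.i.d. samples from a zero-mean multivariate Gaussian whose
correlation matrix has block structure over the resting-state networks:
ROIs sharing a network correlate at a stage-dependent level ``within_r``,
all other pairs at a common baseline ``between_r``.

Two stage trajectories of within-network connectivity are encoded:

* "inversion" networks (AUD, DMN, VIS, SUB by default) rise from NC to a
  peak at EMCI and then fall through LMCI to AD — an inverted U;
* "decline" networks (SEN, ATT by default) decrease monotonically.

MMSE scores are drawn per stage from Gaussians with the cohort's reported
stage means and SDs, rounded to integers and clipped to [0, 30].

The Gaussian model is deliberate: downstream analysis consumes only
Pearson correlations, which the covariance controls exactly.  Temporal
autocorrelation is not simulated by default (an AR(1) knob exists but
defaults off) so that the correlation targets stay exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_MMSE_PARAMS",
    "DEFAULT_WITHIN_R",
    "DEFAULT_BETWEEN_R",
    "RSNPartition",
    "default_partition",
    "CohortConfig",
    "ROITimeSeries",
    "build_stage_covariance",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "read_partition",
    "write_partition",
]

#: disease stages in progression order
STAGES = ("NC", "EMCI", "LMCI", "AD")

#: per-stage subject counts of the reference cohort
DEFAULT_GROUP_SIZES = {"NC": 35, "EMCI": 37, "LMCI": 33, "AD": 25}

#: per-stage MMSE (mean, sd) of the reference cohort
DEFAULT_MMSE_PARAMS = {
    "NC": (28.89, 1.21),
    "EMCI": (28.08, 1.74),
    "LMCI": (27.85, 1.64),
    "AD": (22.72, 2.41),
}

#: within-network correlation across (NC, EMCI, LMCI, AD):
#: inverted-U ("inversion") for AUD/DMN/VIS/SUB, monotone fall ("decline")
#: for SEN/ATT
DEFAULT_WITHIN_R = {
    "DMN": (0.30, 0.45, 0.35, 0.20),
    "AUD": (0.30, 0.45, 0.35, 0.20),
    "VIS": (0.30, 0.45, 0.35, 0.20),
    "SUB": (0.30, 0.45, 0.35, 0.20),
    "SEN": (0.45, 0.38, 0.30, 0.22),
    "ATT": (0.45, 0.38, 0.30, 0.22),
}

DEFAULT_BETWEEN_R = 0.05

#: trajectory tag implied by each default network
DEFAULT_NETWORK_PATTERNS = {
    "DMN": "inversion", "AUD": "inversion", "VIS": "inversion", "SUB": "inversion",
    "SEN": "decline", "ATT": "decline",
}


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RSNPartition:
    """Assignment of ROI indices to named resting-state networks."""

    networks: tuple[str, ...]
    assignment: dict[int, str]

    def __post_init__(self) -> None:
        seen = set(self.assignment.values())
        missing = [n for n in self.networks if n not in seen]
        if missing:
            raise ValueError(f"empty network(s): {missing}")
        unknown = seen - set(self.networks)
        if unknown:
            raise ValueError(f"ROIs assigned to undeclared network(s): {sorted(unknown)}")

    @property
    def n_rois(self) -> int:
        return len(self.assignment)

    def indices(self, network: str) -> np.ndarray:
        """ROI indices of one network, in ascending order."""
        if network not in self.networks:
            raise KeyError(f"unknown network {network!r}; have {self.networks}")
        return np.array(sorted(i for i, n in self.assignment.items() if n == network))

    def labels(self) -> np.ndarray:
        """Network name per ROI index 0..N-1."""
        return np.array([self.assignment[i] for i in range(self.n_rois)])

    def validate_cover(self, n_rois: int) -> None:
        expected = set(range(n_rois))
        got = set(self.assignment)
        if got != expected:
            raise ValueError(
                f"partition must cover ROI indices 0..{n_rois - 1} exactly once; "
                f"missing {sorted(expected - got)[:5]}, extra {sorted(got - expected)[:5]}"
            )


#: default block sizes for the 90-ROI atlas partition (contiguous blocks).
#: The true atlas-to-network mapping is study-specific; real-data runs must
#: supply their own partition file.
DEFAULT_BLOCK_SIZES = {"DMN": 20, "ATT": 16, "SUB": 12, "AUD": 10, "VIS": 16, "SEN": 16}


def default_partition(n_rois: int = 90) -> RSNPartition:
    """Contiguous-block partition of ``n_rois`` ROIs into the six RSNs.

    Block sizes scale proportionally from the 90-ROI defaults; every
    network keeps at least 3 ROIs (the minimum for graph metrics) when
    ``n_rois`` allows it.
    """
    names = tuple(DEFAULT_BLOCK_SIZES)
    min_size = 3 if n_rois >= 3 * len(names) else 1
    sizes = np.array([DEFAULT_BLOCK_SIZES[n] for n in names], dtype=float)
    scaled = np.floor(sizes * n_rois / sizes.sum()).astype(int)
    scaled = np.maximum(scaled, min_size)
    # distribute the remainder to the largest blocks
    while scaled.sum() < n_rois:
        scaled[np.argmax(sizes - scaled)] += 1
    while scaled.sum() > n_rois:
        candidates = np.where(scaled > min_size, scaled, -1)
        scaled[np.argmax(candidates)] -= 1
    assignment: dict[int, str] = {}
    start = 0
    for name, size in zip(names, scaled):
        for i in range(start, start + size):
            assignment[i] = name
        start += size
    return RSNPartition(networks=names, assignment=assignment)


def read_partition(path: str | Path) -> RSNPartition:
    """Read a partition TSV with columns roi_index, roi_name, network."""
    df = pd.read_csv(path, sep="\t")
    required = {"roi_index", "network"}
    if not required.issubset(df.columns):
        raise ValueError(f"partition file needs columns {sorted(required)}, got {list(df.columns)}")
    assignment = dict(zip(df["roi_index"].astype(int), df["network"].astype(str)))
    if len(assignment) != len(df):
        raise ValueError("duplicate roi_index in partition file")
    networks = tuple(dict.fromkeys(df["network"].astype(str)))
    return RSNPartition(networks=networks, assignment=assignment)


def write_partition(partition: RSNPartition, path: str | Path) -> Path:
    path = Path(path)
    labels = partition.labels()
    df = pd.DataFrame({
        "roi_index": np.arange(partition.n_rois),
        "roi_name": [f"ROI{i:03d}" for i in range(partition.n_rois)],
        "network": labels,
    })
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort.

    ``within_r`` maps network name -> 4-tuple of within-network target
    correlations across (NC, EMCI, LMCI, AD).  ``ar1`` adds optional AR(1)
    temporal autocorrelation to each ROI signal (0 disables it).
    """

    n_rois: int = 90
    n_timepoints: int = 130
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    partition: RSNPartition | None = None
    within_r: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_R))
    between_r: float = DEFAULT_BETWEEN_R
    mmse_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MMSE_PARAMS))
    network_patterns: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_PATTERNS))
    ar1: float = 0.0
    min_timepoints: int = 30
    seed: int = 0

    def resolved_partition(self) -> RSNPartition:
        return self.partition if self.partition is not None else default_partition(self.n_rois)

    def validate(self) -> None:
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_timepoints < self.min_timepoints:
            raise ValueError(
                f"n_timepoints={self.n_timepoints} below minimum {self.min_timepoints} "
                "needed for stable correlation estimates"
            )
        for stage, n in self.group_sizes.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if n < 0:
                raise ValueError(f"negative group size for {stage}")
        part = self.resolved_partition()
        part.validate_cover(self.n_rois)
        for net in part.networks:
            traj = self.within_r.get(net)
            if traj is None:
                raise ValueError(f"no within_r trajectory for network {net!r}")
            if len(traj) != len(STAGES):
                raise ValueError(f"within_r[{net!r}] must have {len(STAGES)} values")
            if any(not (0 <= r < 1) for r in traj):
                raise ValueError(f"within_r[{net!r}] values must lie in [0, 1)")
            pattern = self.network_patterns.get(net)
            if pattern == "inversion":
                v = traj
                if not (v[1] > v[0] and v[1] > v[2] > v[3]):
                    raise ValueError(
                        f"inversion network {net!r} needs rise-then-fall with peak at EMCI, got {v}"
                    )
            elif pattern == "decline":
                if not all(a > b for a, b in zip(traj, traj[1:])):
                    raise ValueError(f"decline network {net!r} needs strictly decreasing values, got {traj}")
        if not (0 <= self.between_r < 1):
            raise ValueError("between_r must lie in [0, 1)")
        for stage, (_, sd) in self.mmse_params.items():
            if sd < 0:
                raise ValueError(f"mmse sd for {stage} must be >= 0")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject: T x N signal matrix plus stage label and MMSE score."""

    subject_id: str
    stage: str
    mmse: int
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE {self.mmse} outside [0, 30]")
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("data must be 2-D (time x ROI)")
        if np.isnan(d).any():
            raise ValueError("data contains missing values")
        object.__setattr__(self, "data", d)


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def _nearest_pd(a: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite one."""
    w, v = np.linalg.eigh(a)
    w = np.maximum(w, 1e-8)
    return (v * w) @ v.T


def build_stage_covariance(config: CohortConfig, stage: str) -> np.ndarray:
    """Block correlation matrix implied by the config at one stage.

    Entry (i, j) is ``within_r[network, stage]`` when i and j share a
    network, ``between_r`` otherwise, and 1 on the diagonal.  The result
    is checked for positive definiteness; a near-PD violation triggers a
    nearest-PD repair (with a warning), a gross one raises and names the
    offending blocks.
    """
    config.validate()
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    stage_idx = STAGES.index(stage)
    part = config.resolved_partition()
    labels = part.labels()
    n = config.n_rois
    cov = np.full((n, n), float(config.between_r))
    for net in part.networks:
        idx = part.indices(net)
        r = float(config.within_r[net][stage_idx])
        cov[np.ix_(idx, idx)] = r
    np.fill_diagonal(cov, 1.0)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0:
        if eigvals[0] > -1e-6:
            warnings.warn(
                f"stage {stage} covariance nearly singular (min eigenvalue {eigvals[0]:.2e}); "
                "applying nearest-PD repair", stacklevel=2,
            )
            cov = _nearest_pd(cov)
        else:
            offending = sorted({labels[i] for i in range(n)})
            raise ValueError(
                f"stage {stage} covariance not positive definite "
                f"(min eigenvalue {eigvals[0]:.3e}); check within_r/between_r of blocks {offending}"
            )
    return cov


# ---------------------------------------------------------------------------
# cohort generation and I/O
# ---------------------------------------------------------------------------

def _simulate_subject(cov_chol: np.ndarray, t: int, ar1: float,
                      rng: np.random.Generator) -> np.ndarray:
    n = cov_chol.shape[0]
    z = rng.standard_normal((t, n))
    if ar1 > 0:
        # AR(1) innovations, scaled back to unit marginal variance
        for row in range(1, t):
            z[row] = ar1 * z[row - 1] + np.sqrt(1 - ar1**2) * z[row]
    return z @ cov_chol.T


def generate_cohort(config: CohortConfig) -> list[ROITimeSeries]:
    """Draw the full four-stage cohort described by ``config``.

    Subjects are drawn stage by stage in the fixed order NC, EMCI, LMCI,
    AD with ids like ``EMCI_003``, so a given seed always yields the same
    cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort: list[ROITimeSeries] = []
    for stage in STAGES:
        n_subj = config.group_sizes.get(stage, 0)
        if n_subj == 0:
            continue
        cov = build_stage_covariance(config, stage)
        chol = np.linalg.cholesky(cov)
        mean, sd = config.mmse_params[stage]
        for s in range(n_subj):
            data = _simulate_subject(chol, config.n_timepoints, config.ar1, rng)
            mmse = int(np.clip(np.rint(rng.normal(mean, sd)), 0, 30))
            cohort.append(ROITimeSeries(
                subject_id=f"{stage}_{s:03d}", stage=stage, mmse=mmse, data=data,
            ))
    return cohort


def write_cohort(cohort: list[ROITimeSeries], directory: str | Path) -> Path:
    """Write one TSV per subject plus a manifest; returns the manifest path.

    Subject files are T x N tab-separated matrices without a header; the
    manifest lists subject_id, stage, mmse and the data file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [s.subject_id for s in cohort]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    rows = []
    for subject in cohort:
        fname = f"{subject.subject_id}.tsv"
        np.savetxt(directory / fname, subject.data, delimiter="\t", fmt="%.17g")
        rows.append({
            "subject_id": subject.subject_id, "stage": subject.stage,
            "mmse": subject.mmse, "path": fname,
        })
    manifest = pd.DataFrame(rows, columns=["subject_id", "stage", "mmse", "path"])
    manifest_path = directory / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> list[ROITimeSeries]:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    cohort = []
    for row in manifest.itertuples(index=False):
        data = np.loadtxt(base / row.path, delimiter="\t", ndmin=2)
        cohort.append(ROITimeSeries(
            subject_id=str(row.subject_id), stage=str(row.stage),
            mmse=int(row.mmse), data=data,
        ))
    return cohort
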