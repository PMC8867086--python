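"""Seeded generators for model validation and end-to-end pipeline tests.

Two generators are provided:

* :func:`sample_matrix_normal` draws matrices W = M + A·Z·Aᵀ (A a symmetric
  square root of the factor C, Z i.i.d. standard normal), so that
  vec(W) has covariance C ⊗ C — the exact model the fitting code assumes.
  Used for parameter-recovery tests.

* :func:`generate_cohort` emulates a two-group resting-state cohort: each
  subject's time series is drawn from a multivariate normal whose
  correlation matrix has a block structure aligned with the sub-network
  partition (``rho_within`` on within-network pairs, ``rho_between``
  elsewhere).  Optional state switching redraws segments from jittered
  per-state correlation matrices, creating genuinely dynamic connectivity;
  patients additionally have the within-network correlations of one
  designated sub-network shifted by ``effect_delta``.  Independent Gaussian
  measurement noise is added last.  All randomness derives from the spec
  seed via per-subject seed sequences, so a cohort is bit-reproducible and
  independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import LabelTable, RoiTimeSeries, SubNetworkPartition

_PD_FLOOR = 1e-6  # eigenvalue clip when projecting a shifted matrix back to PD


def _psd_sqrt(c: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(c)
    if vals[0] < -1e-8 * max(abs(vals[-1]), 1.0):
        raise ValidationError(f"factor not positive semi-definite (λmin={vals[0]:.3g})")
    return (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def sample_matrix_normal(
    mean: np.ndarray, factor: np.ndarray, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """n draws from the matrix-variate normal with row/col covariance ``factor``.

    Returns an (n, N, N) stack.  With a zero factor every draw equals the
    mean exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = np.asarray(mean, dtype=float)
    a = _psd_sqrt(np.asarray(factor, dtype=float))
    z = rng.standard_normal((n, *mean.shape))
    return mean[None] + a @ z @ a.T


def nearest_correlation(mat: np.ndarray, floor: float = _PD_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix
    by eigenvalue clipping followed by diagonal renormalization."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    clipped = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    out = clipped / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class CohortSpec:
    """Study conditions for a synthetic two-group cohort.

    Defaults emulate a typical single-site cohort: 45 patients + 47
    controls, 170 time points, and (unless a partition is supplied) the
    bundled six-network AAL-116 division.  Correlation levels and the
    group effect are chosen as plausible resting-state values: moderate
    within-network coupling (0.5), weak between-network coupling (0.1),
    and a patient-group *reduction* of default-mode within-network
    correlations (−0.15), with two slowly alternating connectivity states
    and unit-variance signal plus measurement noise of SD 0.5.
    """

    n_asd: int = 45
    n_nc: int = 47
    m_time: int = 170
    partition: SubNetworkPartition | None = None  # None → bundled AAL-116 six networks
    rho_within: float = 0.5
    rho_between: float = 0.1
    effect_network: str = "DMN"
    effect_delta: float = -0.15
    n_states: int = 2
    state_dwell: int = 45
    state_amplitude: float = 0.15
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition is None:
            from .io_formats import aal116_partition

            self.partition = aal116_partition()
        if not (0.0 <= self.rho_between <= self.rho_within < 1.0):
            raise ValidationError(
                f"need 0 ≤ rho_between ≤ rho_within < 1, got "
                f"between={self.rho_between}, within={self.rho_within}"
            )
        if self.n_states < 1 or self.state_dwell < 1:
            raise ValidationError("n_states and state_dwell must be ≥ 1")
        if self.effect_delta != 0.0 and self.effect_network not in self.partition.networks:
            raise ValidationError(
                f"effect network {self.effect_network!r} not in partition "
                f"{sorted(self.partition.networks)}"
            )
        if self.n_asd < 1 or self.n_nc < 1 or self.m_time < 2:
            raise ValidationError("cohort must have subjects and ≥ 2 time points")


def _block_correlation(spec: CohortSpec) -> np.ndarray:
    part = spec.partition
    n = part.n_roi
    membership = np.empty(n, dtype=int)
    for g, idx in enumerate(part.networks.values()):
        membership[idx] = g
    same = membership[:, None] == membership[None, :]
    base = np.where(same, spec.rho_within, spec.rho_between)
    np.fill_diagonal(base, 1.0)
    return base


def _state_matrices(spec: CohortSpec, base: np.ndarray) -> list[np.ndarray]:
    """Per-state correlation matrices: state 0 is the base structure,
    further states jitter each network's within-block level."""
    part = spec.partition
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD15EA5E]))
    mats = [nearest_correlation(base)]
    for _ in range(1, spec.n_states):
        m = base.copy()
        for idx in part.networks.values():
            shift = rng.uniform(-spec.state_amplitude, spec.state_amplitude)
            block = np.ix_(idx, idx)
            m[block] = np.clip(m[block] + shift, -0.95, 0.95)
        np.fill_diagonal(m, 1.0)
        mats.append(nearest_correlation(m))
    return mats


def _apply_effect(mats: list[np.ndarray], spec: CohortSpec) -> list[np.ndarray]:
    if spec.effect_delta == 0.0:
        return mats
    idx = spec.partition.networks[spec.effect_network]
    out = []
    for m in mats:
        shifted = m.copy()
        block = np.ix_(idx, idx)
        shifted[block] = np.clip(shifted[block] + spec.effect_delta, -0.95, 0.95)
        np.fill_diagonal(shifted, 1.0)
        out.append(nearest_correlation(shifted))
    return out


def effect_edges(spec: CohortSpec) -> list[tuple[int, int]]:
    """(i, j) ROI pairs (i > j) whose correlation the group effect shifts."""
    if spec.effect_delta == 0.0:
        return []
    idx = sorted(spec.partition.networks[spec.effect_network])
    return [(i, j) for i in idx for j in idx if i > j]


def _check_pd(mats: list[np.ndarray], label: str) -> None:
    for s, m in enumerate(mats):
        lam = np.linalg.eigvalsh(m)[0]
        if lam <= 0:
            raise ValidationError(
                f"{label} state-{s} correlation matrix not positive definite "
                f"(λmin={lam:.3g}); adjust rho/effect parameters"
            )


def _simulate_subject(
    rng: np.random.Generator, chols: list[np.ndarray], spec: CohortSpec
) -> np.ndarray:
    n = chols[0].shape[0]
    rows = []
    t = 0
    seg = 0
    while t < spec.m_time:
        length = min(spec.state_dwell, spec.m_time - t)
        state = seg % spec.n_states
        z = rng.standard_normal((length, n))
        rows.append(z @ chols[state].T)
        t += length
        seg += 1
    signal = np.vstack(rows)
    return signal + spec.noise_sd * rng.standard_normal(signal.shape)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[RoiTimeSeries], LabelTable, dict]:
    """Simulate the cohort; returns (subjects, labels, ground truth).

    Ground truth records the shifted edges, the per-segment state schedule
    (shared by all subjects), and the generating parameters — enough to
    verify edge and sub-network recovery downstream.
    """
    part = spec.partition
    n = part.n_roi
    base = _block_correlation(spec)
    nc_mats = _state_matrices(spec, base)
    asd_mats = _apply_effect(nc_mats, spec)
    _check_pd(nc_mats, "control")
    _check_pd(asd_mats, "patient")
    nc_chols = [np.linalg.cholesky(m) for m in nc_mats]
    asd_chols = [np.linalg.cholesky(m) for m in asd_mats]

    roi_names = [f"roi_{i:03d}" for i in range(n)]
    subjects: list[RoiTimeSeries] = []
    labels: dict[str, int] = {}
    for g, (count, prefix, chols, lab) in enumerate(
        [(spec.n_asd, "asd", asd_chols, 1), (spec.n_nc, "nc", nc_chols, -1)]
    ):
        for s in range(count):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, g, s]))
            sid = f"{prefix}_{s:03d}"
            subjects.append(
                RoiTimeSeries(
                    subject_id=sid,
                    values=_simulate_subject(rng, chols, spec),
                    roi_names=list(roi_names),
                )
            )
            labels[sid] = lab

    n_segments = -(-spec.m_time // spec.state_dwell)
    ground_truth = {
        "effect_network": spec.effect_network if spec.effect_delta != 0.0 else None,
        "effect_delta": spec.effect_delta,
        "effect_edges": [list(e) for e in effect_edges(spec)],
        "state_schedule": [seg % spec.n_states for seg in range(n_segments)],
        "state_dwell": spec.state_dwell,
        "rho_within": spec.rho_within,
        "rho_between": spec.rho_between,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return subjects, LabelTable(labels=labels), ground_truth
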