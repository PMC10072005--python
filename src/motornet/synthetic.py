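"""Seeded synthetic resting-state cohorts with group-dependent network topology.

Real patient recordings behind this kind of study are rarely deposited, so the
package ships a generative stand-in that every downstream stage can be tested
against.  Each simulated subject owns a latent binary "motor network" drawn
from a ring-lattice-with-rewiring (Watts–Strogatz) family: a low rewiring
probability yields a regular, highly clustered lattice, a high one an
essentially random graph.  The three groups differ only in that probability —
moderate-to-severe patients (MtS) get the most lattice-like networks, mild
patients intermediate ones, healthy controls the most random — which is the
single knob that induces the group ordering of clustering, local efficiency,
transitivity (MtS > Mild > Healthy) and the reversed ordering of global
efficiency that the pipeline is meant to recover.

The latent graph is mapped to a target covariance, band-limited correlated
Gaussian series are simulated at the device sampling rate, a shared
superficial component (what common-average-reference filtering later removes)
and broadband sensor noise are added, and transient motion-artifact spikes are
injected.  Fugl-Meyer Assessment (FMA) scores are generated as a noisy
decreasing function of the subject's latent regularity, truncated to the
group's clinical range (Mild ≥ 85, MtS < 85), so that the expected
metric–FMA correlation signs are recoverable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.signal

from .recording import HemodynamicRecording, write_recording_csv

__all__ = [
    "GROUPS",
    "CohortConfig",
    "SubjectMeta",
    "GroundTruth",
    "CohortSubject",
    "make_group_network",
    "network_to_covariance",
    "simulate_recording",
    "inject_artifacts",
    "generate_cohort",
    "write_cohort",
    "read_metadata_csv",
]

GROUPS = ("Healthy", "Mild", "MtS")

#: FMA range implied by the clinical grouping cutoff (score 85).
_FMA_RANGE = {"Mild": (85.0, 100.0), "MtS": (5.0, 84.0)}

# Age / gender frequencies emulating a typical poststroke cohort
# (controls younger and near-all male; patients 60-65 y, mostly male).
_AGE_PARAMS = {"Healthy": (51.0, 3.0, 48.0, 59.0), "Mild": (65.0, 8.0, 35.0, 80.0), "MtS": (60.0, 11.0, 30.0, 80.0)}
_MALE_PROB = {"Healthy": 10 / 11, "Mild": 13 / 15, "MtS": 12 / 16}


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults reproduce the reference study conditions: 11 healthy controls,
    15 mild and 16 moderate-to-severe patients, 22 channels at 10 Hz for
    6 minutes.
    """

    n_healthy: int = 11
    n_mild: int = 15
    n_mts: int = 16
    n_channels: int = 22
    fs: float = 10.0
    duration: float = 360.0
    #: group → Watts–Strogatz rewiring probability of the latent network;
    #: must be ordered Healthy > Mild > MtS (more regular ⇒ higher clustering).
    group_rewiring: dict[str, float] = field(
        default_factory=lambda: {"Healthy": 0.7, "Mild": 0.22, "MtS": 0.04}
    )
    #: half-width of the uniform per-subject jitter around the group rewiring
    rewiring_jitter: dict[str, float] = field(
        default_factory=lambda: {"Healthy": 0.04, "Mild": 0.03, "MtS": 0.015}
    )
    latent_density: float = 88 / 231  # ≈0.381: k=8 ring lattice on 22 nodes
    edge_strength: float = 0.45
    global_amplitude: float = 0.5
    noise_amplitude: float = 0.3
    signal_scale: float = 0.03  # mM·mm overall amplitude scale
    artifact_spike_rate: float = 2.0  # events per minute
    artifact_amplitude: float = 10.0  # spike peak in multiples of channel SD
    fma_intercept: float = 328.0
    fma_slope: float = 300.0
    fma_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_mild", "n_mts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_healthy + self.n_mild + self.n_mts < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.n_channels < 2:
            raise ValueError("need at least two channels")
        if not 0 < self.latent_density <= 1:
            raise ValueError("latent_density must be in (0, 1]")
        if not 0 < self.edge_strength < 1:
            raise ValueError("edge_strength must be in (0, 1)")
        p = self.group_rewiring
        if not (p["Healthy"] > p["Mild"] > p["MtS"]):
            raise ValueError(
                "group rewiring probabilities must be ordered Healthy > Mild > MtS"
            )
        for g, v in p.items():
            if not 0 <= v <= 1:
                raise ValueError(f"rewiring probability for {g} out of [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.n_healthy + self.n_mild + self.n_mts


@dataclass
class SubjectMeta:
    """Demographic / clinical metadata for one subject."""

    subject_id: str
    group: str
    age: float
    gender: str  # "male" | "female"
    fma: float | None = None  # patients only
    lesion_side: str | None = None  # "left" | "right"; patients only
    months_post_stroke: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        is_patient = self.group != "Healthy"
        if is_patient and self.fma is None:
            raise ValueError("patients must carry an FMA score")
        if not is_patient and self.fma is not None:
            raise ValueError("healthy controls carry no FMA score")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass
class GroundTruth:
    """Latent generative state of one synthetic subject."""

    adjacency: np.ndarray  # binary, symmetric, zero diagonal
    rewiring_prob: float
    fma: float | None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("latent adjacency must be symmetric with zero diagonal")


@dataclass
class CohortSubject:
    recording: HemodynamicRecording
    meta: SubjectMeta
    truth: GroundTruth
    artifact_positions: list[tuple[int, int, int]]


def make_group_network(
    n_nodes: int, density: float, rewiring_prob: float, seed: int
) -> np.ndarray:
    """Ring-lattice adjacency with Watts–Strogatz edge rewiring.

    The base graph connects each node to its ``k`` nearest ring neighbours
    (``k`` even, chosen from the requested density); any remaining edges are
    laid down as next-nearest chords so the exact edge count
    ``round(density·n(n−1)/2)`` is met.  Each lattice edge is then rewired to
    a uniform random non-neighbour with probability ``rewiring_prob``
    (edge count preserved).  ``rewiring_prob = 0`` returns the pure lattice.
    """
    if not 0 <= rewiring_prob <= 1:
        raise ValueError("rewiring_prob must be in [0, 1]")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    n_edges = int(np.floor(density * n_pairs + 0.5))
    if n_edges < n_nodes:
        raise ValueError(
            f"density {density:.3f} gives {n_edges} edges; need at least "
            f"{n_nodes} for a ring-lattice base"
        )
    if n_edges > n_pairs:
        raise ValueError("density exceeds 1")

    rng = np.random.default_rng(seed)
    adj = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    k_half = n_edges // n_nodes  # neighbours per side
    edges: list[tuple[int, int]] = []
    for offset in range(1, k_half + 1):
        for i in range(n_nodes):
            j = (i + offset) % n_nodes
            edges.append((min(i, j), max(i, j)))
    # chords for the remainder so the edge count is exact
    remainder = n_edges - n_nodes * k_half
    offset = k_half + 1
    i = 0
    while remainder > 0:
        if offset > n_nodes // 2:
            raise ValueError("cannot place remaining chords without duplicates")
        j = (i + offset) % n_nodes
        e = (min(i, j), max(i, j))
        if e not in edges:
            edges.append(e)
            remainder -= 1
        i += 1
        if i == n_nodes:
            i = 0
            offset += 1
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1

    if rewiring_prob > 0:
        for i, j in edges:
            if rng.random() >= rewiring_prob:
                continue
            # rewire the far endpoint of (i, j), keeping i
            candidates = np.flatnonzero(adj[i] == 0)
            candidates = candidates[candidates != i]
            if candidates.size == 0:
                continue
            new_j = int(rng.choice(candidates))
            adj[i, j] = adj[j, i] = 0
            adj[i, new_j] = adj[new_j, i] = 1
    assert int(adj.sum()) // 2 == n_edges
    return adj


def network_to_covariance(
    adjacency: np.ndarray,
    edge_strength: float,
    diagonal_load: float = 1.0,
    alpha_scale: float = 0.7,
) -> np.ndarray:
    """Map a binary graph to a symmetric positive-definite target covariance.

    A network-diffusion (resolvent) model is used: the raw correlation
    structure is ``(I − αA)⁻¹`` normalized to unit diagonal, with
    ``α = alpha_scale / λ_max(A)``, so correlation decays with graph
    distance — directly connected channels correlate most, two-step
    neighbours weakly, distant channels barely.  Off-diagonals are then
    rescaled so the *mean* correlation over connected pairs equals
    ``edge_strength`` exactly (for a single connected pair this makes the
    implied correlation equal ``edge_strength``), and the diagonal starts at
    ``diagonal_load`` and is inflated geometrically until the matrix is
    positive definite (rarely needed; the resolvent is already PD for
    ``alpha_scale < 1``).  An empty graph maps to a diagonal matrix.

    Connected pairs receive systematically higher target correlations than
    unconnected ones; for near-regular graphs the two ranges are disjoint,
    for heavily rewired graphs they may overlap slightly at the tails.
    """
    adjacency = np.asarray(adjacency, dtype=float)
    if not np.allclose(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if diagonal_load <= 0:
        raise ValueError("diagonal_load must be positive")
    if not 0 < alpha_scale < 1:
        raise ValueError("alpha_scale must be in (0, 1)")
    n = adjacency.shape[0]
    iu = np.triu_indices(n, k=1)
    edges = adjacency[iu] > 0
    if not edges.any():
        return diagonal_load * np.eye(n)
    lam_max = np.linalg.eigvalsh(adjacency)[-1]
    resolvent = np.linalg.inv(np.eye(n) - (alpha_scale / lam_max) * adjacency)
    scale = np.sqrt(np.diag(resolvent))
    corr = resolvent / np.outer(scale, scale)
    beta = edge_strength / corr[iu][edges].mean()
    load = float(diagonal_load)
    cov = beta * corr
    np.fill_diagonal(cov, load)
    while np.linalg.eigvalsh(cov)[0] <= 1e-8:
        load *= 1.2
        np.fill_diagonal(cov, load)
    return cov


def _bandlimit(x: np.ndarray, fs: float, low: float = 0.01, high: float = 0.1) -> np.ndarray:
    """Ideal (FFT) band-pass: zero power outside [low, high].

    The generator defines its ground-truth spectra with a flat in-band
    response, so the effective sample count of the simulated series is the
    full 2·bandwidth·duration and carries no filter-transient leakage.
    """
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(x.shape[-1], 1.0 / fs)
    spec[..., (f < low) | (f > high)] = 0
    return np.fft.irfft(spec, n=x.shape[-1], axis=-1)


def simulate_recording(
    covariance: np.ndarray,
    fs: float,
    duration: float,
    global_amplitude: float,
    seed: int,
    noise_amplitude: float = 0.0,
    signal_scale: float = 1.0,
    subject_id: str = "sim",
) -> HemodynamicRecording:
    """Simulate one band-limited multichannel recording.

    Correlated Gaussian series with the requested covariance are drawn white
    in time and band-limited to the low-frequency analysis band
    (0.01–0.1 Hz); because every channel passes through the same filter the
    cross-channel correlation structure is preserved.  A shared band-limited
    superficial component (scaled by ``global_amplitude``) and broadband
    white sensor noise (``noise_amplitude``, per-channel SD relative to the
    unit neural series) are added on top.
    """
    covariance = np.asarray(covariance, dtype=float)
    n = covariance.shape[0]
    n_samples = int(round(fs * duration))
    if n_samples < 600:
        raise ValueError("recording must contain at least 600 samples")
    try:
        chol = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    rng = np.random.default_rng(seed)
    neural = chol @ rng.standard_normal((n, n_samples))
    neural = _bandlimit(neural, fs)
    data = neural
    if global_amplitude:
        shared = _bandlimit(rng.standard_normal(n_samples), fs)
        data = data + global_amplitude * shared[None, :]
    if noise_amplitude:
        data = data + noise_amplitude * rng.standard_normal((n, n_samples))
    return HemodynamicRecording(
        subject_id=subject_id, data=signal_scale * data, fs=fs
    )


def inject_artifacts(
    recording: HemodynamicRecording,
    spike_rate: float,
    amplitude: float,
    seed: int,
) -> tuple[HemodynamicRecording, list[tuple[int, int, int]]]:
    """Add transient motion-artifact spikes; returns the exact positions.

    The number of events is Poisson with mean ``spike_rate`` (events/min)
    times the recording length; each event is a half-sine deflection of
    random width 0.2–0.8 s with random sign on one random channel, peaking at
    ``amplitude`` times that channel's clean SD.
    """
    if spike_rate < 0:
        raise ValueError("spike_rate must be non-negative")
    if spike_rate > 0 and amplitude <= 0:
        raise ValueError("amplitude must be positive")
    out = recording.copy()
    positions: list[tuple[int, int, int]] = []
    if spike_rate == 0:
        return out, positions
    rng = np.random.default_rng(seed)
    fs = recording.fs
    minutes = recording.duration / 60.0
    n_events = rng.poisson(spike_rate * minutes)
    sds = recording.data.std(axis=1)
    for _ in range(n_events):
        ch = int(rng.integers(recording.n_channels))
        width = int(round(rng.uniform(0.2, 0.8) * fs))
        width = max(width, 3)
        start = int(rng.integers(0, recording.n_samples - width))
        # half-sine sampled at interval midpoints, normalized to unit peak
        bump = np.sin(np.pi * (np.arange(width) + 0.5) / width)
        bump /= bump.max()
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[ch, start : start + width] += sign * amplitude * sds[ch] * bump
        positions.append((ch, start, start + width))
    return out, positions


def _draw_fma(group: str, rewiring_prob: float, cfg: CohortConfig, rng) -> float:
    lo, hi = _FMA_RANGE[group]
    raw = (
        cfg.fma_intercept
        - cfg.fma_slope * (1.0 - rewiring_prob)
        + rng.normal(0.0, cfg.fma_noise_sd)
    )
    return float(np.clip(raw, lo, hi))


def generate_cohort(config: CohortConfig | None = None) -> list[CohortSubject]:
    """Generate a full seeded cohort of recordings, metadata and ground truth.

    Per-subject random streams are spawned from the master seed with the
    subject index as spawn key, so adding subjects to one group never shifts
    another subject's realization.
    """
    cfg = config if config is not None else CohortConfig()
    subjects: list[CohortSubject] = []
    labels = (
        ["Healthy"] * cfg.n_healthy + ["Mild"] * cfg.n_mild + ["MtS"] * cfg.n_mts
    )
    for idx, group in enumerate(labels):
        ss = np.random.SeedSequence(cfg.seed, spawn_key=(idx,))
        s_topo, s_signal, s_artifact, s_meta = ss.spawn(4)
        rng_meta = np.random.default_rng(s_meta)

        jitter = cfg.rewiring_jitter.get(group, 0.0)
        p = float(
            np.clip(
                cfg.group_rewiring[group] + rng_meta.uniform(-jitter, jitter),
                0.01,
                0.97,
            )
        )
        adj = make_group_network(
            cfg.n_channels, cfg.latent_density, p, seed=s_topo.generate_state(1)[0]
        )
        cov = network_to_covariance(adj, cfg.edge_strength)
        rec = simulate_recording(
            cov,
            cfg.fs,
            cfg.duration,
            cfg.global_amplitude,
            seed=s_signal.generate_state(1)[0],
            noise_amplitude=cfg.noise_amplitude,
            signal_scale=cfg.signal_scale,
            subject_id=f"S{idx + 1:03d}",
        )
        rec, positions = inject_artifacts(
            rec,
            cfg.artifact_spike_rate,
            cfg.artifact_amplitude,
            seed=s_artifact.generate_state(1)[0],
        )

        is_patient = group != "Healthy"
        fma = _draw_fma(group, p, cfg, rng_meta) if is_patient else None
        mu, sd, lo, hi = _AGE_PARAMS[group]
        age = float(np.clip(rng_meta.normal(mu, sd), lo, hi))
        gender = "male" if rng_meta.random() < _MALE_PROB[group] else "female"
        meta = SubjectMeta(
            subject_id=rec.subject_id,
            group=group,
            age=round(age, 1),
            gender=gender,
            fma=None if fma is None else round(fma, 1),
            lesion_side=("left" if rng_meta.random() < 0.5 else "right") if is_patient else None,
            months_post_stroke=round(float(abs(rng_meta.normal(1.2, 1.0)) + 0.1), 2)
            if is_patient
            else None,
        )
        truth = GroundTruth(adjacency=adj, rewiring_prob=p, fma=meta.fma)
        subjects.append(CohortSubject(rec, meta, truth, positions))
    return subjects


def metadata_frame(subjects: Iterable[CohortSubject | SubjectMeta]) -> pd.DataFrame:
    """Cohort metadata as a tidy DataFrame (one row per subject)."""
    rows = []
    for s in subjects:
        m = s.meta if isinstance(s, CohortSubject) else s
        rows.append(
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "age": m.age,
                "gender": m.gender,
                "FMA": m.fma,
                "lesion_side": m.lesion_side,
                "months_post_stroke": m.months_post_stroke,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(subjects: list[CohortSubject], out_dir: str | Path) -> Path:
    """Write per-subject signal CSVs plus a cohort ``metadata.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_recording_csv(s.recording, out_dir / f"{s.meta.subject_id}.csv")
    metadata_frame(subjects).to_csv(out_dir / "metadata.csv", index=False)
    return out_dir


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"subject_id", "group"}
    if not required <= set(frame.columns):
        raise ValueError(f"metadata file missing columns {required - set(frame.columns)}")
    unknown = set(frame["group"]) - set(GROUPS)
    if unknown:
        warnings.warn(f"metadata contains unknown groups: {sorted(unknown)}")
    return frame
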