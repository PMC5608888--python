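"""Synthetic cohorts: behavioral trial logs plus coupled multichannel signals.

No recordings from the original child cohort are available, so this module
generates subjects whose statistics mirror the study conditions end to end:

* **Ground-truth connectivity.** A Watts–Strogatz small-world graph on 48
  nodes (mean degree 8, rewiring probability 0.1) stands in for the unknown
  true inter-channel coupling; ring-lattice and Erdős–Rényi-type topologies
  are available for controls.
* **Signals.** Each channel is a band-limited (0.008–0.09 Hz) Gaussian noise
  source mixed with its graph neighbors, ``x = (I + coupling * A) @ z``, then
  standardized. Pearson correlations are therefore systematically higher for
  adjacent channel pairs, which is all the downstream estimator needs.
* **Behavior.** A 36-trial guessing game in which a lie is only possible on
  an incorrectly guessed trial (falsely reporting the guess as correct). The
  per-opportunity lie hazard is logistic in age. The defaults reproduce the
  target cohort statistics: ~68% of subjects lie at least once and the mean
  first-lie trial (FLT) among liars is ~11.45 (see docs/methods.md for the
  closed-form calibration).
* **State change.** At the first-lie trial onset a liar's generating network
  switches to a partially rewired copy (``disruption_fraction`` of edges
  rewired), giving the pipeline a controlled coupling disruption to recover.

All operations are deterministic given their seed; a cohort uses one master
seed with per-subject substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import (
    ChannelTimeSeries,
    Trial,
    TrialLog,
    read_timeseries_tsv,
    read_trials_csv,
    write_timeseries_tsv,
    write_trials_csv,
)
from .errors import InvalidParameterError
from .preprocess import DEFAULT_BAND

__all__ = [
    "GroundTruthNetwork",
    "BehaviorModel",
    "SubjectRecord",
    "CohortConfig",
    "generate_ground_truth_network",
    "simulate_timecourses",
    "simulate_behavior",
    "rewire_edges",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: midpoint of the 7-12 year age range; the hazard's logistic reference age
REFERENCE_AGE = 9.5


@dataclass
class GroundTruthNetwork:
    """The true coupling graph a simulated cohort's signals are built on."""

    adjacency: np.ndarray
    topology_label: str
    mean_degree: float
    rewiring_p: float

    def __post_init__(self):
        a = (np.asarray(self.adjacency) != 0).astype(np.uint8)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidParameterError("adjacency must be square")
        if not np.array_equal(a, a.T) or np.any(np.diag(a)):
            raise InvalidParameterError("adjacency must be symmetric and loop-free")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> set[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return set(zip(iu.tolist(), ju.tolist()))


@dataclass(frozen=True)
class BehaviorModel:
    """Per-trial guessing and per-opportunity lying probabilities.

    ``lie_hazard_base`` is the per-opportunity (i.e. per incorrect guess)
    probability of lying at the reference age; ``lie_hazard_age_slope`` shifts
    its log-odds per year of age. Defaults are calibrated so a cohort of 59
    children aged uniformly 7-12 yields ~67.8% liars with mean FLT ~11.45.
    """

    p_incorrect_guess: float = 0.5
    lie_hazard_base: float = 0.076
    lie_hazard_age_slope: float = -0.85
    n_trials: int = 36

    def __post_init__(self):
        if not 0 <= self.p_incorrect_guess <= 1:
            raise InvalidParameterError("p_incorrect_guess must be in [0, 1]")
        if not 0 <= self.lie_hazard_base <= 1:
            raise InvalidParameterError("lie_hazard_base must be in [0, 1]")
        if self.n_trials < 1:
            raise InvalidParameterError("n_trials must be >= 1")

    def hazard(self, age_years: float) -> float:
        """Per-opportunity lie probability at a given age."""
        if self.lie_hazard_base in (0.0, 1.0):
            return self.lie_hazard_base
        return float(
            expit(logit(self.lie_hazard_base) + self.lie_hazard_age_slope * (age_years - REFERENCE_AGE))
        )


@dataclass
class SubjectRecord:
    """One simulated subject: behavior, signals, and (for liars) both networks."""

    subject_id: str
    age_years: float
    is_liar: bool
    trial_log: TrialLog
    timeseries: ChannelTimeSeries
    network_pre: GroundTruthNetwork | None = None
    network_post: GroundTruthNetwork | None = None

    def __post_init__(self):
        if self.is_liar != self.trial_log.is_liar:
            raise InvalidParameterError("is_liar inconsistent with trial log")

    @property
    def flt_trial(self) -> int | None:
        return self.trial_log.first_lie_trial

    @property
    def lie_count(self) -> int:
        return self.trial_log.lie_count


def generate_ground_truth_network(
    n_nodes: int = 48,
    topology: str = "smallworld",
    mean_degree: int = 8,
    rewiring_p: float = 0.1,
    seed: int | None = None,
) -> GroundTruthNetwork:
    """Construct a ground-truth coupling graph.

    ``smallworld`` is a Watts–Strogatz graph, ``lattice`` the underlying ring
    (rewiring probability forced to 0), and ``random`` a G(n, m) graph with
    the same edge count; all three have exactly ``n_nodes * mean_degree / 2``
    edges, so topologies are comparable at fixed density.
    """
    if n_nodes < 4:
        raise InvalidParameterError("n_nodes must be >= 4")
    if mean_degree >= n_nodes:
        raise InvalidParameterError("mean_degree must be < n_nodes")
    if mean_degree < 2:
        raise InvalidParameterError("mean_degree must be >= 2")
    if not 0 <= rewiring_p <= 1:
        raise InvalidParameterError("rewiring_p must be in [0, 1]")
    if topology in ("smallworld", "lattice") and mean_degree % 2 != 0:
        raise InvalidParameterError("ring construction requires an even mean_degree")
    n_edges = int(round(n_nodes * mean_degree / 2))
    if topology == "lattice":
        g = nx.watts_strogatz_graph(n_nodes, mean_degree, 0.0, seed=seed)
        rewiring_p = 0.0
    elif topology == "smallworld":
        g = nx.watts_strogatz_graph(n_nodes, mean_degree, rewiring_p, seed=seed)
    elif topology == "random":
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    else:
        raise InvalidParameterError(f"unknown topology {topology!r}")
    adj = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=np.uint8)
    return GroundTruthNetwork(adj, topology, float(mean_degree), float(rewiring_p))


def _bandlimited_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sampling_rate: float,
    band: tuple[float, float],
    noise_sd: float,
) -> np.ndarray:
    """Stationary band-limited Gaussian noise, one row per channel.

    The zero-phase filter's startup transient at such a low normalized cutoff
    decays over hundreds of samples and is shaped alike across channels, which
    would spuriously correlate independent channels near the series edges.
    The noise is therefore synthesized with a burn-in margin of two slow
    periods on each side and only the stationary interior is returned.
    """
    from scipy import signal

    low, high = band
    sos = signal.butter(4, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    burn = int(np.ceil(2.0 / low * sampling_rate))
    z = rng.standard_normal((n_channels, n_samples + 2 * burn)) * noise_sd
    filtered = signal.sosfiltfilt(sos, z, axis=1)
    return filtered[:, burn : burn + n_samples]


def simulate_timecourses(
    network: GroundTruthNetwork,
    n_samples: int = 10800,
    sampling_rate: float = 10.0,
    coupling: float = 0.5,
    noise_sd: float = 1.0,
    band: tuple[float, float] = DEFAULT_BAND,
    seed: int | None = None,
) -> ChannelTimeSeries:
    """Shared-neighbor mixture signals: ``x = (I + coupling * A) @ z``.

    ``z`` is independent band-limited Gaussian noise per channel; after mixing,
    each channel is standardized to zero mean and unit variance. Adjacent
    channel pairs share a noise source and hence correlate systematically
    above non-adjacent pairs whenever ``coupling > 0``.
    """
    if coupling < 0:
        raise InvalidParameterError("coupling must be >= 0")
    if not 0 < band[0] < band[1] < sampling_rate / 2:
        raise InvalidParameterError("band must lie strictly inside (0, Nyquist)")
    rng = np.random.default_rng(seed)
    z = _bandlimited_noise(rng, network.n_nodes, n_samples, sampling_rate, band, noise_sd)
    x = z + coupling * (network.adjacency.astype(float) @ z)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    return ChannelTimeSeries(x, sampling_rate)


def simulate_behavior(
    model: BehaviorModel,
    age_years: float,
    seed: int | None = None,
    samples_per_trial: int = 300,
) -> TrialLog:
    """One subject's 36-trial log; lies arise only on incorrect guesses.

    Trial onsets are evenly spaced every ``samples_per_trial`` samples
    (default 300 samples = 30 s at 10 Hz).
    """
    if not 7.0 <= age_years <= 12.0:
        raise InvalidParameterError("age_years must be within [7, 12]")
    rng = np.random.default_rng(seed)
    hazard = model.hazard(age_years)
    trials = []
    for t in range(1, model.n_trials + 1):
        incorrect = rng.random() < model.p_incorrect_guess
        lie = bool(incorrect and rng.random() < hazard)
        trials.append(
            Trial(
                trial_index=t,
                onset_sample=(t - 1) * samples_per_trial,
                guess_correct=not incorrect,
                reported_correct=(not incorrect) or lie,
                is_lie=lie,
            )
        )
    return TrialLog(trials)


def rewire_edges(
    network: GroundTruthNetwork, fraction: float, seed: int | None = None
) -> GroundTruthNetwork:
    """Rewire ``ceil(fraction * E)`` edges to uniformly random new positions.

    The rewired copy has the same edge count; exactly that many edges are
    removed and the same number of previously absent pairs added, so the
    symmetric difference with the source is twice the rewired count.
    """
    if not 0 <= fraction <= 1:
        raise InvalidParameterError("fraction must be in [0, 1]")
    if fraction == 0:
        return GroundTruthNetwork(
            network.adjacency.copy(), network.topology_label,
            network.mean_degree, network.rewiring_p,
        )
    rng = np.random.default_rng(seed)
    n = network.n_nodes
    m = math.ceil(fraction * network.n_edges)
    iu, ju = np.nonzero(np.triu(network.adjacency, k=1))
    drop = rng.choice(iu.size, size=m, replace=False)
    # non-edges of the original graph (upper triangle, excluding the diagonal)
    mask = np.triu(np.ones((n, n), dtype=bool), k=1) & (network.adjacency == 0)
    ku, lu = np.nonzero(mask)
    if ku.size < m:
        raise InvalidParameterError("not enough vacant pairs to rewire into")
    add = rng.choice(ku.size, size=m, replace=False)
    adj = network.adjacency.copy()
    adj[iu[drop], ju[drop]] = 0
    adj[ju[drop], iu[drop]] = 0
    adj[ku[add], lu[add]] = 1
    adj[lu[add], ku[add]] = 1
    return GroundTruthNetwork(adj, f"{network.topology_label}+rewired",
                              network.mean_degree, network.rewiring_p)


@dataclass(frozen=True)
class CohortConfig:
    """Everything that defines how a synthetic cohort is generated."""

    n_channels: int = 48
    topology: str = "smallworld"
    mean_degree: int = 8
    rewiring_p: float = 0.1
    coupling: float = 0.5
    noise_sd: float = 1.0
    sampling_rate: float = 10.0
    band: tuple[float, float] = DEFAULT_BAND
    samples_per_trial: int = 300
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    age_range: tuple[float, float] = (7.0, 12.0)
    disruption_fraction: float = 0.3
    #: force an exact number of liars (rejection-resampled trial logs); None = free
    n_liars: int | None = None


def generate_cohort(
    n_subjects: int = 59,
    config: CohortConfig | None = None,
    seed: int | None = None,
) -> list[SubjectRecord]:
    """Simulate a cohort of subjects on one shared ground-truth network.

    Each liar's signals are generated from the intact network before the
    first-lie trial onset and from a per-subject rewired copy
    (``disruption_fraction`` of edges) afterwards; lie-free subjects use the
    intact network throughout. Per-subject RNG substreams are spawned
    deterministically from the master seed.
    """
    if n_subjects < 2:
        raise InvalidParameterError("n_subjects must be >= 2")
    config = config or CohortConfig()
    if config.n_liars is not None and not 0 <= config.n_liars <= n_subjects:
        raise InvalidParameterError("n_liars must be in [0, n_subjects]")
    master = np.random.SeedSequence(seed)
    net_ss, *subject_ss = master.spawn(n_subjects + 1)
    network = generate_ground_truth_network(
        config.n_channels, config.topology, config.mean_degree, config.rewiring_p,
        seed=int(net_ss.generate_state(1)[0] & 0x7FFFFFFF),
    )
    n_samples = config.behavior.n_trials * config.samples_per_trial

    want_liar: list[bool] | None = None
    if config.n_liars is not None:
        order = np.random.default_rng(int(net_ss.generate_state(2)[1] & 0x7FFFFFFF))
        picks = set(order.permutation(n_subjects)[: config.n_liars].tolist())
        want_liar = [i in picks for i in range(n_subjects)]

    records = []
    for i, ss in enumerate(subject_ss):
        rng = np.random.default_rng(ss)
        age = float(rng.uniform(*config.age_range))
        log = simulate_behavior(
            config.behavior, age,
            seed=rng.integers(2**31), samples_per_trial=config.samples_per_trial,
        )
        if want_liar is not None:
            # conditional simulation: redraw until the log matches the target status
            while log.is_liar != want_liar[i]:
                log = simulate_behavior(
                    config.behavior, age,
                    seed=rng.integers(2**31), samples_per_trial=config.samples_per_trial,
                )
        net_post = None
        if log.is_liar:
            net_post = rewire_edges(network, config.disruption_fraction,
                                    seed=rng.integers(2**31))
            split = log.onset_of_trial(log.first_lie_trial)
            ts_seed = rng.integers(2**31)
            z = _bandlimited_noise(
                np.random.default_rng(ts_seed), config.n_channels, n_samples,
                config.sampling_rate, config.band, config.noise_sd,
            )
            a_pre = network.adjacency.astype(float)
            a_post = net_post.adjacency.astype(float)
            x = np.empty_like(z)
            x[:, :split] = z[:, :split] + config.coupling * (a_pre @ z[:, :split])
            x[:, split:] = z[:, split:] + config.coupling * (a_post @ z[:, split:])
            x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
            ts = ChannelTimeSeries(x, config.sampling_rate)
        else:
            ts = simulate_timecourses(
                network, n_samples, config.sampling_rate, config.coupling,
                config.noise_sd, config.band, seed=rng.integers(2**31),
            )
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                age_years=age,
                is_liar=log.is_liar,
                trial_log=log,
                timeseries=ts,
                network_pre=network,
                network_post=net_post if log.is_liar else network,
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort directory layout
# ---------------------------------------------------------------------------

def write_cohort(records: list[SubjectRecord], directory: str | Path) -> None:
    """Write per-subject ``timeseries.tsv``/``trials.csv`` plus ``subjects.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        sub_dir = directory / rec.subject_id
        sub_dir.mkdir(exist_ok=True)
        write_timeseries_tsv(rec.timeseries, sub_dir / "timeseries.tsv")
        write_trials_csv(rec.trial_log, sub_dir / "trials.csv")
        rows.append((rec.subject_id, rec.age_years, int(rec.is_liar),
                     rec.flt_trial if rec.flt_trial is not None else ""))
    pd.DataFrame(rows, columns=["subject_id", "age_years", "is_liar", "flt_trial"]).to_csv(
        directory / "subjects.csv", index=False
    )


def read_cohort(directory: str | Path, sampling_rate: float = 10.0) -> list[SubjectRecord]:
    """Read a cohort directory written by :func:`write_cohort` (or real data in
    the same layout). Ground-truth networks are not serialized and come back
    as None."""
    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv")
    records = []
    for r in subjects.itertuples():
        sub_dir = directory / str(r.subject_id)
        ts = read_timeseries_tsv(sub_dir / "timeseries.tsv", sampling_rate)
        log = read_trials_csv(sub_dir / "trials.csv")
        records.append(
            SubjectRecord(
                subject_id=str(r.subject_id),
                age_years=float(r.age_years),
                is_liar=bool(r.is_liar),
                trial_log=log,
                timeseries=ts,
            )
        )
    return records
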