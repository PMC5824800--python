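"""Population loop: N protocells exchanging code fragments, no descent.

Each iteration draws an ordered (donor, receiver) pair uniformly at random,
samples a 10-pair fragment from the donor and trains it into the receiver.
Receiver expressivity and robustness are recorded after every transfer;
population-level statistics (universality, snapshot means, box-plot
summaries of the per-transfer receiver series) are recorded every
``recording_interval`` transfers.

Randomness is split into four independent streams derived from the master
seed — network initialization, pair selection, fragment sampling, training
shuffles — so trajectories depend only on the seed and the dynamical
parameters, never on recording settings.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from .chemical_space import AminoAcidTable, load_amino_acid_table
from .codon_space import CODONS, CODON_ENCODINGS, CodonTable
from .horizontal_transfer import TransferRecord, sample_amino_acid_indices
from .metrics import delta_code_from_assignments
from .translation_network import PerceptronTranslator, forward_batch, init_network, train_on_pairs

__all__ = [
    "RunConfig",
    "MetricsSeries",
    "SimulationResult",
    "ReplicateResult",
    "run_simulation",
    "run_replicates",
    "derive_run_seeds",
]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one simulation experiment."""

    population_size: int = 16
    total_transfers: int = 100_000
    pairs_per_transfer: int = 10
    epochs_per_transfer: int = 500
    learning_rate: float = 0.1
    recording_interval: int = 500
    master_seed: int = 0
    n_runs: int = 50
    init: str = "uniform"
    assignment_noise_rate: float = 0.0
    log_transfers: bool = False
    checkpoint_every: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("total_transfers", "pairs_per_transfer", "recording_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.epochs_per_transfer < 0:
            raise ValueError("epochs_per_transfer must be >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0.0 <= self.assignment_noise_rate <= 1.0:
            raise ValueError("assignment_noise_rate must be in [0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)


_BOX_FIELDS = ("mean", "q1", "median", "q3", "whisker_lo", "whisker_hi", "n_outliers")


def _box_stats(values: np.ndarray) -> dict:
    """Tukey box-plot summary: quartiles, 1.5*IQR whiskers, outlier count."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return {
        "mean": float(v.mean()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "n_outliers": int(v.size - inside.size),
    }


@dataclass
class MetricsSeries:
    """Interval-sampled population statistics of one run (or run average)."""

    data: pd.DataFrame  # one row per recording point

    @classmethod
    def from_records(cls, records: list[dict]) -> "MetricsSeries":
        return cls(pd.DataFrame.from_records(records))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MetricsSeries":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class SimulationResult:
    config: RunConfig
    population: list  # of PerceptronTranslator
    codes: list  # final CodonTable per protocell
    metrics: MetricsSeries
    receiver_expressivity: np.ndarray  # per transfer
    receiver_delta_code: np.ndarray  # per transfer
    transfer_log: list  # of TransferRecord (empty unless log_transfers)


@dataclass
class ReplicateResult:
    config: RunConfig
    runs: list  # of SimulationResult
    aggregate: MetricsSeries  # pointwise mean across runs
    optimal_codes: list  # best final code of each run


def _decode(net: PerceptronTranslator, chem_matrix: np.ndarray) -> np.ndarray:
    """(64, 20) squared-distance matrix; argmin(axis=1) is the decoding."""
    out = forward_batch(net, CODON_ENCODINGS)
    return (
        (out**2).sum(axis=1)[:, None]
        - 2.0 * (out @ chem_matrix.T)
        + (chem_matrix**2).sum(axis=1)[None, :]
    )


def _pairwise_distance_stats(assign: np.ndarray) -> tuple[float, float]:
    n = assign.shape[0]
    d = [
        np.count_nonzero(assign[i] != assign[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    d = np.asarray(d, dtype=float)
    return float(d.mean()), float(d.std())


def run_simulation(
    config: RunConfig,
    aa_table: AminoAcidTable | None = None,
    checkpoint_dir: str | Path | None = None,
) -> SimulationResult:
    """Run one seeded simulation to completion.

    Fully deterministic in ``config`` (including the master seed). If
    ``checkpoint_dir`` is given and ``config.checkpoint_every`` is set,
    the full population state is serialized every K transfers.
    """
    aa = aa_table if aa_table is not None else load_amino_acid_table()
    chem = aa.chem_matrix
    pr = aa.polar_requirement
    weights = aa.transfer_weights
    n = config.population_size
    n_pairs = config.pairs_per_transfer

    ss = np.random.SeedSequence(config.master_seed)
    ss_init, ss_pair, ss_frag, ss_train = ss.spawn(4)
    rng_init = np.random.Generator(np.random.PCG64(ss_init))
    rng_pair = np.random.Generator(np.random.PCG64(ss_pair))
    rng_frag = np.random.Generator(np.random.PCG64(ss_frag))
    rng_train = np.random.Generator(np.random.PCG64(ss_train))

    population = [
        init_network(rng_init, config.learning_rate, config.init) for _ in range(n)
    ]
    # cached read-out assignments; valid between transfers since weights
    # change only when a protocell receives
    assign = np.stack([np.argmin(_decode(net, chem), axis=1) for net in population])

    recv_expr = np.empty(config.total_transfers, dtype=np.int64)
    recv_delta = np.empty(config.total_transfers, dtype=float)
    interval_records: list[dict] = []
    transfer_log: list[TransferRecord] = []

    last_recorded = 0

    def record_interval(t: int) -> None:
        nonlocal last_recorded
        expr_window = recv_expr[last_recorded:t]
        delta_window = recv_delta[last_recorded:t]
        last_recorded = t
        umean, ustd = _pairwise_distance_stats(assign)
        pop_expr = [len(np.unique(a)) for a in assign]
        pop_delta = [delta_code_from_assignments(a, pr) for a in assign]
        rec = {"transfer": t}
        rec.update({f"expressivity_{k}": v for k, v in _box_stats(expr_window).items()})
        rec.update({f"delta_code_{k}": v for k, v in _box_stats(delta_window).items()})
        rec.update(
            {
                "universality_mean": umean,
                "universality_std": ustd,
                "population_expressivity_mean": float(np.mean(pop_expr)),
                "population_delta_code_mean": float(np.mean(pop_delta)),
            }
        )
        interval_records.append(rec)

    for t in range(1, config.total_transfers + 1):
        donor = int(rng_pair.integers(n))
        receiver = int(rng_pair.integers(n - 1))
        if receiver >= donor:
            receiver += 1

        aa_idx = sample_amino_acid_indices(weights, rng_frag, n_pairs)
        if config.assignment_noise_rate > 0.0:
            flip = rng_frag.random(n_pairs) < config.assignment_noise_rate
            if flip.any():
                aa_idx = aa_idx.copy()
                aa_idx[flip] = rng_frag.integers(len(aa.names3), size=int(flip.sum()))
        d2_donor = _decode(population[donor], chem)
        codon_idx = np.argmin(d2_donor[:, aa_idx], axis=0)
        disagreements = int(
            np.count_nonzero(assign[donor][codon_idx] != aa_idx)
        )

        pairs = [
            (CODON_ENCODINGS[c], chem[k]) for c, k in zip(codon_idx, aa_idx)
        ]
        train_on_pairs(
            population[receiver], pairs, config.epochs_per_transfer, rng_train
        )

        assign[receiver] = np.argmin(_decode(population[receiver], chem), axis=1)
        recv_expr[t - 1] = len(np.unique(assign[receiver]))
        recv_delta[t - 1] = delta_code_from_assignments(assign[receiver], pr)

        if config.log_transfers:
            transfer_log.append(
                TransferRecord(
                    donor=donor,
                    receiver=receiver,
                    pairs=[
                        (CODONS[c], aa.names3[k]) for c, k in zip(codon_idx, aa_idx)
                    ],
                    disagreements=disagreements,
                    receiver_expressivity=int(recv_expr[t - 1]),
                    receiver_delta_code=float(recv_delta[t - 1]),
                )
            )

        if t % config.recording_interval == 0 or t == config.total_transfers:
            record_interval(t)
        if (
            checkpoint_dir is not None
            and config.checkpoint_every
            and t % config.checkpoint_every == 0
        ):
            _write_checkpoint(Path(checkpoint_dir), config, t, population)

    codes = [CodonTable(a, aa.names3) for a in assign]
    return SimulationResult(
        config=config,
        population=population,
        codes=codes,
        metrics=MetricsSeries.from_records(interval_records),
        receiver_expressivity=recv_expr,
        receiver_delta_code=recv_delta,
        transfer_log=transfer_log,
    )


def _write_checkpoint(
    directory: Path, config: RunConfig, t: int, population: list
) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": config.to_dict(),
        "transfer": t,
        "population": [json.loads(net.to_json()) for net in population],
    }
    (directory / f"checkpoint_{t:08d}.json").write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[RunConfig, int, list]:
    """Read back a checkpoint written during ``run_simulation``."""
    obj = json.loads(Path(path).read_text())
    config = RunConfig.from_dict(obj["config"])
    population = [
        PerceptronTranslator.from_json(json.dumps(p)) for p in obj["population"]
    ]
    return config, obj["transfer"], population


def derive_run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Distinct, reproducible per-run seeds derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_runs, np.uint64)
    seeds = [int(s) for s in state]
    if len(set(seeds)) != n_runs:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("seed derivation collision; choose another master seed")
    return seeds


def run_replicates(
    config: RunConfig, aa_table: AminoAcidTable | None = None
) -> ReplicateResult:
    """Run ``config.n_runs`` independent simulations and average metrics."""
    from .regularity import select_optimal_codes

    aa = aa_table if aa_table is not None else load_amino_acid_table()
    seeds = derive_run_seeds(config.master_seed, config.n_runs)
    runs = [
        run_simulation(dataclasses.replace(config, master_seed=s, n_runs=1), aa)
        for s in seeds
    ]
    frames = [r.metrics.data for r in runs]
    if len(frames) == 1:
        agg = frames[0].copy()
    else:
        agg = sum(frames[1:], frames[0].copy()) / len(frames)
        agg["transfer"] = frames[0]["transfer"]  # identical across runs
    optimal = select_optimal_codes([r.codes for r in runs], aa)
    return ReplicateResult(
        config=config,
        runs=runs,
        aggregate=MetricsSeries(agg),
        optimal_codes=optimal,
    )
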