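"""Core containers and file I/O for trialised spike data and latent trajectories.

The universal input is a :class:`SpikeDataset`: an integer tensor of spike
counts with shape ``(trials, time_bins, neurons)`` together with a neuron
partition (held-in / held-out), an optional set of *k*-out neurons reserved
for few-shot decoding, and a train/test trial partition.  Latent
trajectories inferred by a model are carried as :class:`PosteriorLatents`,
either dense real vectors (state-space models) or per-timestep probability
simplices (HMM posteriors).  Predicted firing rates are
:class:`RatePredictions`, strictly positive expected counts per bin.

Datasets round-trip through NPZ or HDF5 containers with identical content.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "HELD_IN",
    "HELD_OUT",
    "TRAIN",
    "TEST",
    "RATE_FLOOR",
    "ValidationError",
    "FormatError",
    "SpikeDataset",
    "PosteriorLatents",
    "RatePredictions",
    "load_dataset",
    "save_dataset",
    "partition_neurons",
    "save_latents",
    "load_latents",
]

HELD_IN = 0
HELD_OUT = 1
TRAIN = 0
TEST = 1

#: Floor applied to predicted rates before any logarithm, so the Poisson
#: log-likelihood stays finite for (erroneously) zero rate predictions.
RATE_FLOOR = 1e-10

SIMPLEX_TOL = 1e-8


class ValidationError(ValueError):
    """A container violated one of its invariants."""


class FormatError(ValueError):
    """A file did not conform to the dataset container layout."""


@dataclass
class SpikeDataset:
    """Trialised spike counts plus neuron and trial partitions.

    Parameters
    ----------
    spikes:
        Integer counts, shape ``(S, T, N)`` = (trials, time bins, neurons).
    neuron_partition:
        Length-``N`` labels, ``HELD_IN`` (0) or ``HELD_OUT`` (1).
    kout_indices:
        Indices of the neurons reserved for few-shot decoding.  May coincide
        with the held-out set (the usual benchmark convention) but must never
        overlap the held-in set.
    trial_partition:
        Length-``S`` labels, ``TRAIN`` (0) or ``TEST`` (1).
    bin_width_s:
        Bin width in seconds; metadata only.
    seed:
        Provenance seed of the generator that produced the data, if any.
    """

    spikes: np.ndarray
    neuron_partition: np.ndarray
    kout_indices: np.ndarray
    trial_partition: np.ndarray
    bin_width_s: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        self.neuron_partition = np.asarray(self.neuron_partition, dtype=np.int8)
        self.kout_indices = np.asarray(self.kout_indices, dtype=np.int64)
        self.trial_partition = np.asarray(self.trial_partition, dtype=np.int8)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        x = self.spikes
        if x.ndim != 3:
            raise ValidationError(f"spikes must be 3-d (S,T,N), got shape {x.shape}")
        if not np.issubdtype(x.dtype, np.integer):
            if np.issubdtype(x.dtype, np.floating) and np.all(x == np.floor(x)):
                self.spikes = x = x.astype(np.int64)
            else:
                raise ValidationError("spike counts must be integers")
        if x.size and x.min() < 0:
            raise ValidationError("spike counts must be >= 0")
        S, _, N = x.shape
        if self.neuron_partition.shape != (N,):
            raise ValidationError("neuron_partition must have one label per neuron")
        if not np.isin(self.neuron_partition, [HELD_IN, HELD_OUT]).all():
            raise ValidationError("neuron_partition labels must be 0 (held-in) or 1 (held-out)")
        if self.trial_partition.shape != (S,):
            raise ValidationError("trial_partition must have one label per trial")
        if not np.isin(self.trial_partition, [TRAIN, TEST]).all():
            raise ValidationError("trial_partition labels must be 0 (train) or 1 (test)")
        if (self.trial_partition == TRAIN).sum() < 1 or (self.trial_partition == TEST).sum() < 1:
            raise ValidationError("need at least one train and one test trial")
        k = self.kout_indices
        if k.size and (k.min() < 0 or k.max() >= N):
            raise ValidationError("kout_indices out of range")
        if np.intersect1d(k, self.held_in_indices).size:
            raise ValidationError("k-out neurons must not overlap the held-in set")

    # -- convenience views ----------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[2]

    @property
    def held_in_indices(self) -> np.ndarray:
        return np.flatnonzero(self.neuron_partition == HELD_IN)

    @property
    def held_out_indices(self) -> np.ndarray:
        return np.flatnonzero(self.neuron_partition == HELD_OUT)

    @property
    def train_trials(self) -> np.ndarray:
        return np.flatnonzero(self.trial_partition == TRAIN)

    @property
    def test_trials(self) -> np.ndarray:
        return np.flatnonzero(self.trial_partition == TEST)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeDataset):
            return NotImplemented
        return (
            np.array_equal(self.spikes, other.spikes)
            and np.array_equal(self.neuron_partition, other.neuron_partition)
            and np.array_equal(self.kout_indices, other.kout_indices)
            and np.array_equal(self.trial_partition, other.trial_partition)
            and self.bin_width_s == other.bin_width_s
            and self.seed == other.seed
        )


@dataclass
class PosteriorLatents:
    """Per-trial latent trajectories, shape ``(S, T, D)``.

    ``kind='dense'`` for real-valued state estimates (e.g. smoothed means of
    a state-space model); ``kind='simplex'`` for per-timestep posterior
    probability mass functions over discrete states, each slice summing to 1.
    """

    values: np.ndarray
    kind: str = "dense"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("latent values must be 3-d (S,T,D)")
        if self.kind not in ("dense", "simplex"):
            raise ValidationError(f"unknown latent kind {self.kind!r}")
        if self.kind == "simplex":
            v = self.values
            if v.size and v.min() < -SIMPLEX_TOL:
                raise ValidationError("simplex latents must be non-negative")
            sums = v.sum(axis=2)
            if v.size and np.abs(sums - 1.0).max() > SIMPLEX_TOL:
                raise ValidationError("simplex latents must sum to 1 per (trial, time)")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[2]

    def subset(self, trials: np.ndarray) -> "PosteriorLatents":
        return PosteriorLatents(self.values[np.asarray(trials)], kind=self.kind)


@dataclass
class RatePredictions:
    """Predicted expected counts per bin, shape ``(S_eval, T, n_targets)``.

    All entries are strictly positive; :data:`RATE_FLOOR` is applied on
    construction so downstream log-likelihoods are finite.
    """

    rates: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 3:
            raise ValidationError("rates must be 3-d (S,T,targets)")
        if not np.all(np.isfinite(r)):
            raise ValidationError("rates must be finite")
        if r.size and r.min() < 0:
            raise ValidationError("rates must be non-negative before flooring")
        self.rates = np.maximum(r, RATE_FLOOR)


# ---------------------------------------------------------------------------
# container I/O

_ARRAY_KEYS = ("spikes", "neuron_partition", "kout_indices", "trial_partition")


def _dataset_payload(ds: SpikeDataset) -> dict[str, np.ndarray]:
    return {
        "spikes": ds.spikes.astype(np.int64),
        "neuron_partition": ds.neuron_partition.astype(np.int8),
        "kout_indices": ds.kout_indices.astype(np.int64),
        "trial_partition": ds.trial_partition.astype(np.int8),
    }


def save_dataset(ds: SpikeDataset, path: str | Path, force: bool = False) -> None:
    """Write a dataset to ``path`` (``.npz`` or ``.h5``/``.hdf5`` by suffix).

    Refuses to overwrite an existing file unless ``force`` is given.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    payload = _dataset_payload(ds)
    seed = -1 if ds.seed is None else int(ds.seed)
    if path.suffix == ".npz":
        np.savez(
            path,
            **payload,
            bin_width_s=np.float64(ds.bin_width_s),
            seed=np.int64(seed),
        )
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for k, v in payload.items():
                f.create_dataset(k, data=v)
            f.attrs["bin_width_s"] = float(ds.bin_width_s)
            f.attrs["seed"] = seed
    else:
        raise FormatError(f"unsupported container suffix {path.suffix!r}")


def load_dataset(path: str | Path) -> SpikeDataset:
    """Read a dataset container written by :func:`save_dataset`.

    Raises :class:`FormatError` on missing arrays and
    :class:`ValidationError` when the content violates the type invariants.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            try:
                arrays = {k: f[k] for k in _ARRAY_KEYS}
                bin_width = float(f["bin_width_s"])
                seed = int(f["seed"])
            except KeyError as e:  # pragma: no cover - message detail
                raise FormatError(f"missing array {e} in {path}") from e
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            missing = [k for k in _ARRAY_KEYS if k not in f]
            if missing:
                raise FormatError(f"missing arrays {missing} in {path}")
            arrays = {k: f[k][...] for k in _ARRAY_KEYS}
            bin_width = float(f.attrs["bin_width_s"])
            seed = int(f.attrs["seed"])
    else:
        raise FormatError(f"unsupported container suffix {path.suffix!r}")
    return SpikeDataset(
        spikes=arrays["spikes"],
        neuron_partition=arrays["neuron_partition"],
        kout_indices=arrays["kout_indices"],
        trial_partition=arrays["trial_partition"],
        bin_width_s=bin_width,
        seed=None if seed == -1 else seed,
    )


def save_latents(latents: PosteriorLatents, path: str | Path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    np.savez(path, values=latents.values, kind=np.array(latents.kind))


def load_latents(path: str | Path) -> PosteriorLatents:
    with np.load(path) as f:
        try:
            return PosteriorLatents(values=f["values"], kind=str(f["kind"]))
        except KeyError as e:
            raise FormatError(f"missing array {e} in {path}") from e


# ---------------------------------------------------------------------------
# partition logic


def partition_neurons(
    ds: SpikeDataset,
    n_out: int,
    seed: int,
    kout: str = "held_out",
) -> SpikeDataset:
    """Uniformly random held-in / held-out split of the neuron axis.

    ``kout='held_out'`` reuses the held-out neurons as the k-out set (the
    benchmark convention); ``kout='none'`` leaves the k-out set empty.
    Deterministic given ``seed``; the spike tensor is shared, not copied.
    """
    N = ds.n_neurons
    if not 1 <= n_out < N:
        raise ValueError(f"n_out must be in [1, {N - 1}], got {n_out}")
    rng = np.random.default_rng(seed)
    out = rng.choice(N, size=n_out, replace=False)
    labels = np.full(N, HELD_IN, dtype=np.int8)
    labels[out] = HELD_OUT
    if kout == "held_out":
        kout_idx = np.sort(out)
    elif kout == "none":
        kout_idx = np.empty(0, dtype=np.int64)
    else:
        raise ValueError(f"unknown kout policy {kout!r}")
    return dataclasses.replace(ds, neuron_partition=labels, kout_indices=kout_idx)
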