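"""Dataset schema, HDF5 container and split bookkeeping.

A fine-tuning dataset holds one record per molecule: the atom embedding
matrix from the foundation model, per-atom electronegativity ``e`` and
hardness ``s``, foundation partial charges ``q``, total charge ``Q``,
baseline calculated and experimental free energies with uncertainties,
and the frames-by-atoms matrix ``phi`` of environment electrostatic
potentials (kcal mol^-1 e^-1) saved from equilibrium sampling at the
unperturbed potential.  Frames are treated as i.i.d. decorrelated
snapshots throughout.

On disk a dataset is an HDF5 file (one group per molecule) plus a JSON
sidecar manifest ``<path>.manifest.json`` holding ids, split labels and
scalar metadata.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .constants import beta_from_temperature

SPLITS = ("train", "validate", "test")

CHARGE_SUM_TOL = 1e-8


class ValidationError(ValueError):
    """A molecule record violates a dataset invariant.

    Carries the offending ``molecule_id`` and ``field`` name.
    """

    def __init__(self, molecule_id: str, field_name: str, message: str):
        self.molecule_id = molecule_id
        self.field = field_name
        super().__init__(f"molecule {molecule_id!r}, field {field_name!r}: {message}")


class SchemaError(ValueError):
    """An on-disk container does not conform to the dataset schema."""


@dataclass(eq=False)
class MoleculeRecord:
    """One molecule's embeddings, electrostatic parameters and saved frames."""

    molecule_id: str
    embeddings: np.ndarray  # (n_atoms, m), dimensionless
    e: np.ndarray  # (n_atoms,), electronegativity, kcal mol^-1 e^-1
    s: np.ndarray  # (n_atoms,), hardness, kcal mol^-1 e^-2, strictly positive
    q: np.ndarray  # (n_atoms,), partial charges, e
    Q: float  # total molecular charge, e
    dG_calc: float  # baseline calculated free energy, kcal/mol
    dG_calc_unc: float
    dG_expt: float  # experimental free energy, kcal/mol
    dG_expt_unc: float
    phi: np.ndarray  # (n_frames, n_atoms), kcal mol^-1 e^-1
    split: str = "train"
    ensemble: Optional[object] = None  # SyntheticEnsembleSpec for synthetic data

    @property
    def n_atoms(self) -> int:
        return self.e.shape[0]

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    def validate(self, m: int) -> None:
        """Check all record invariants; raise ValidationError naming the field."""
        n = self.n_atoms
        if self.embeddings.ndim != 2 or self.embeddings.shape != (n, m):
            raise ValidationError(
                self.molecule_id, "embeddings",
                f"expected shape ({n}, {m}), got {self.embeddings.shape}")
        for name in ("e", "s", "q"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValidationError(self.molecule_id, name,
                                      f"expected shape ({n},), got {arr.shape}")
        if not np.all(self.s > 0):
            raise ValidationError(self.molecule_id, "s",
                                  "hardness must be strictly positive")
        dq = abs(float(np.sum(self.q)) - self.Q)
        if dq > CHARGE_SUM_TOL:
            raise ValidationError(self.molecule_id, "q",
                                  f"sum(q) deviates from Q by {dq:.3g} e")
        if self.phi.ndim != 2 or self.phi.shape[1] != n or self.phi.shape[0] < 2:
            raise ValidationError(
                self.molecule_id, "phi",
                f"expected (>=2, {n}) potential frames, got {self.phi.shape}")
        if self.split not in SPLITS:
            raise ValidationError(self.molecule_id, "split",
                                  f"unknown split label {self.split!r}")
        for name in ("dG_calc_unc", "dG_expt_unc"):
            if getattr(self, name) < 0:
                raise ValidationError(self.molecule_id, name, "must be nonnegative")


@dataclass(eq=False)
class Dataset:
    """Ordered collection of molecule records sharing one embedding dimension.

    ``beta`` is the inverse thermal energy 1/(kB*T) in mol kcal^-1.
    """

    molecules: list
    m: int
    beta: float = field(default_factory=beta_from_temperature)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    def by_split(self, split: str) -> list:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return [rec for rec in self.molecules if rec.split == split]

    def validate(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        ids = [rec.molecule_id for rec in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule_ids are not unique")
        for rec in self.molecules:
            rec.validate(self.m)


def _manifest_path(path) -> Path:
    return Path(str(path) + ".manifest.json")


def write_dataset(dataset: Dataset, path) -> None:
    """Write a validated dataset to an HDF5 container with a JSON manifest.

    Round-trips bit-exactly through :func:`read_dataset`: all arrays and
    free-energy scalars are stored as binary float64 in HDF5; the JSON
    sidecar carries ids, splits, ``m``, ``beta`` and metadata.
    """
    dataset.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        mol_root = f.create_group("molecules")
        for rec in dataset.molecules:
            g = mol_root.create_group(rec.molecule_id)
            for name in ("embeddings", "e", "s", "q", "phi"):
                g.create_dataset(name, data=np.asarray(getattr(rec, name), dtype=np.float64))
            for name in ("Q", "dG_calc", "dG_calc_unc", "dG_expt", "dG_expt_unc"):
                g.attrs[name] = float(getattr(rec, name))
            if rec.ensemble is not None:
                eg = g.create_group("ensemble")
                eg.create_dataset("mu0", data=np.asarray(rec.ensemble.mu0, dtype=np.float64))
                eg.create_dataset("A", data=np.asarray(rec.ensemble.A, dtype=np.float64))
                eg.create_dataset("Sigma_phi",
                                  data=np.asarray(rec.ensemble.Sigma_phi, dtype=np.float64))
                eg.attrs["n_frames"] = int(rec.ensemble.n_frames)
                eg.attrs["seed"] = int(rec.ensemble.seed)
    manifest = {
        "format": "qtune-dataset-v1",
        "ids": [rec.molecule_id for rec in dataset.molecules],
        "splits": {rec.molecule_id: rec.split for rec in dataset.molecules},
        "m": int(dataset.m),
        "beta": dataset.beta,
        "metadata": dataset.metadata,
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_dataset(path) -> Dataset:
    """Load and validate a dataset written by :func:`write_dataset`."""
    from .synthetic import SyntheticEnsembleSpec  # avoid circular import

    path = Path(path)
    mpath = _manifest_path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset container not found: {path}")
    if not mpath.exists():
        raise SchemaError(f"manifest sidecar not found: {mpath}")
    manifest = json.loads(mpath.read_text())
    m = int(manifest["m"])
    molecules = []
    with h5py.File(path, "r") as f:
        if "molecules" not in f:
            raise SchemaError("container missing 'molecules' group")
        mol_root = f["molecules"]
        for mol_id in manifest["ids"]:
            if mol_id not in mol_root:
                raise SchemaError(f"manifest lists {mol_id!r} but container lacks it")
            g = mol_root[mol_id]
            arrays = {}
            for name in ("embeddings", "e", "s", "q", "phi"):
                if name not in g:
                    raise SchemaError(f"molecule {mol_id!r} missing array {name!r}")
                arrays[name] = np.asarray(g[name], dtype=np.float64)
            split = manifest["splits"].get(mol_id)
            if split not in SPLITS:
                raise SchemaError(f"molecule {mol_id!r} has unknown split {split!r}")
            ensemble = None
            if "ensemble" in g:
                eg = g["ensemble"]
                ensemble = SyntheticEnsembleSpec(
                    mu0=np.asarray(eg["mu0"], dtype=np.float64),
                    A=np.asarray(eg["A"], dtype=np.float64),
                    Sigma_phi=np.asarray(eg["Sigma_phi"], dtype=np.float64),
                    n_frames=int(eg.attrs["n_frames"]),
                    seed=int(eg.attrs["seed"]),
                )
            rec = MoleculeRecord(
                molecule_id=mol_id,
                split=split,
                ensemble=ensemble,
                **arrays,
                **{name: float(g.attrs[name])
                   for name in ("Q", "dG_calc", "dG_calc_unc", "dG_expt", "dG_expt_unc")},
            )
            if rec.embeddings.shape[1] != m:
                raise SchemaError(
                    f"molecule {mol_id!r}: manifest m={m} but embeddings have "
                    f"{rec.embeddings.shape[1]} columns")
            molecules.append(rec)
    ds = Dataset(molecules=molecules, m=m, beta=float(manifest["beta"]),
                 metadata=manifest.get("metadata", {}))
    ds.validate()
    return ds


def split_sizes(n: int, train_fraction: float) -> tuple:
    """Deterministic split sizes: floor for train, 25/75 floor split of the rest.

    Training gets floor(train_fraction*N); of the remaining molecules, a
    quarter (floored) goes to validation and the remainder to test.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0,1), got {train_fraction}")
    n_train = math.floor(train_fraction * n)
    if n_train == 0:
        raise ValueError(
            f"train_fraction={train_fraction} yields an empty training set for N={n}")
    n_rest = n - n_train
    n_validate = math.floor(0.25 * n_rest)
    n_test = n_rest - n_validate
    return n_train, n_validate, n_test


def assign_splits(dataset: Dataset, train_fraction: float, seed: int) -> Dataset:
    """Randomly partition molecules into train/validate/test splits.

    Uniform assignment without replacement, deterministic given ``seed``.
    Split sizes depend only on N and ``train_fraction`` (see
    :func:`split_sizes`); a warning is emitted if any split is empty.
    """
    n = len(dataset)
    if n < 4:
        raise ValueError(f"need at least 4 molecules to split, got {n}")
    n_train, n_validate, n_test = split_sizes(n, train_fraction)
    if min(n_train, n_validate, n_test) == 0:
        warnings.warn(
            f"split sizes ({n_train}, {n_validate}, {n_test}) leave a split empty",
            stacklevel=2)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = [""] * n
    for pos in order[:n_train]:
        labels[pos] = "train"
    for pos in order[n_train:n_train + n_validate]:
        labels[pos] = "validate"
    for pos in order[n_train + n_validate:]:
        labels[pos] = "test"
    molecules = [replace(rec, split=lab) for rec, lab in zip(dataset.molecules, labels)]
    meta = dict(dataset.metadata)
    meta["split"] = {"train_fraction": train_fraction, "seed": seed}
    return Dataset(molecules=molecules, m=dataset.m, beta=dataset.beta, metadata=meta)
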