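"""Low-rank principal-component basis over pooled atom embeddings.

Atom embeddings from every molecule are pooled column-wise into a data
matrix H (m x n_atoms_total).  The truncated eigenbasis of the centered
scatter matrix (H - mu)(H - mu)^T supplies the r directions of highest
variance; projecting each embedding onto this basis yields the low-rank
feature vector that drives the electrostatic perturbation.  Eigenpairs
are obtained from an SVD of the centered matrix (eigenvalues are squared
singular values — unnormalized scatter convention, no 1/n factor).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .data import Dataset, _manifest_path

ORTHO_TOL = 1e-8


@dataclass(eq=False)
class ProjectionBasis:
    """Truncated principal-component basis for atom embeddings.

    Columns of ``Q_basis`` are orthonormal; ``variances`` are the
    corresponding scatter eigenvalues in non-increasing order.  ``center``
    records whether :func:`project` subtracts the mean embedding ``mu``
    (the default) or projects raw vectors.
    """

    Q_basis: np.ndarray  # (m, r), orthonormal columns
    mu: np.ndarray  # (m,), mean embedding
    variances: np.ndarray  # (r,), non-increasing
    r: int
    center: bool = True

    def validate(self) -> None:
        m, r = self.Q_basis.shape
        if r != self.r:
            raise ValueError(f"rank mismatch: matrix has {r} columns, r={self.r}")
        gram = self.Q_basis.T @ self.Q_basis
        if not np.allclose(gram, np.eye(r), atol=ORTHO_TOL):
            raise ValueError("basis columns are not orthonormal")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances are not sorted non-increasing")


def pool_embeddings(dataset: Dataset) -> np.ndarray:
    """Concatenate all atom embeddings column-wise into an m x n_total matrix.

    Column order is molecule order, then atom order within a molecule.
    """
    if len(dataset) == 0:
        raise ValueError("cannot pool embeddings of an empty dataset")
    blocks = []
    for rec in dataset:
        if rec.embeddings.shape[1] != dataset.m:
            raise ValueError(
                f"molecule {rec.molecule_id!r} has embedding dimension "
                f"{rec.embeddings.shape[1]}, dataset m={dataset.m}")
        blocks.append(rec.embeddings.T)
    return np.concatenate(blocks, axis=1)


def fit_basis(H: np.ndarray, r: int, center: bool = True) -> ProjectionBasis:
    """Top-r principal directions of the embedding scatter matrix.

    Computed by SVD of the centered data matrix; eigenvalues are squared
    singular values.  The sign of each column is fixed so its
    largest-magnitude component is positive, making results reproducible.
    A warning is emitted when ``r`` exceeds the numerical rank (trailing
    variances ~0; basis completed from the SVD's orthogonal complement).
    """
    H = np.asarray(H, dtype=np.float64)
    m, n = H.shape
    if n < 2:
        raise ValueError(f"need at least 2 pooled embeddings, got {n}")
    if not 1 <= r <= min(m, n):
        raise ValueError(f"rank r={r} outside [1, min(m={m}, n={n})]")
    mu = H.mean(axis=1)
    X = H - mu[:, None]
    U, sing, _ = np.linalg.svd(X, full_matrices=True)
    variances = np.zeros(min(m, n))
    variances[: sing.shape[0]] = sing**2
    numerical_rank = int(np.sum(sing > sing[0] * max(m, n) * np.finfo(float).eps)) \
        if sing.size and sing[0] > 0 else 0
    if r > numerical_rank:
        warnings.warn(
            f"requested rank {r} exceeds numerical rank {numerical_rank}; "
            "trailing variances are ~0 and those directions are arbitrary",
            stacklevel=2)
    Q = U[:, :r].copy()
    # deterministic sign: largest-magnitude component of each column positive
    idx = np.argmax(np.abs(Q), axis=0)
    signs = np.sign(Q[idx, np.arange(r)])
    signs[signs == 0] = 1.0
    Q *= signs
    return ProjectionBasis(Q_basis=Q, mu=mu, variances=variances[:r].copy(),
                           r=r, center=center)


def project(basis: ProjectionBasis, h: np.ndarray) -> np.ndarray:
    """Project embedding vector(s) onto the low-rank basis.

    Accepts a single embedding (m,) or a stack (n, m); returns (r,) or
    (n, r).  With centering enabled (default) the mean embedding is
    subtracted first; with ``center=False`` raw vectors are projected.
    """
    h = np.asarray(h, dtype=np.float64)
    single = h.ndim == 1
    H = h[None, :] if single else h
    if H.shape[1] != basis.Q_basis.shape[0]:
        raise ValueError(
            f"embedding dimension {H.shape[1]} does not match basis "
            f"dimension {basis.Q_basis.shape[0]}")
    if basis.center:
        H = H - basis.mu[None, :]
    out = H @ basis.Q_basis
    return out[0] if single else out


def save_basis(basis: ProjectionBasis, path) -> None:
    """Persist a fitted basis under the ``projection/`` group of a dataset container."""
    with h5py.File(path, "a") as f:
        if "projection" in f:
            del f["projection"]
        g = f.create_group("projection")
        g.create_dataset("Q_basis", data=basis.Q_basis)
        g.create_dataset("mu", data=basis.mu)
        g.create_dataset("variances", data=basis.variances)
        g.attrs["r"] = int(basis.r)
        g.attrs["center"] = bool(basis.center)
    mpath = _manifest_path(path)
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
        manifest["projection"] = {"r": int(basis.r), "center": bool(basis.center)}
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_basis(path) -> ProjectionBasis:
    with h5py.File(path, "r") as f:
        if "projection" not in f:
            raise KeyError(f"container {path} has no fitted projection basis")
        g = f["projection"]
        basis = ProjectionBasis(
            Q_basis=np.asarray(g["Q_basis"], dtype=np.float64),
            mu=np.asarray(g["mu"], dtype=np.float64),
            variances=np.asarray(g["variances"], dtype=np.float64),
            r=int(g.attrs["r"]),
            center=bool(g.attrs["center"]),
        )
    basis.validate()
    return basis
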