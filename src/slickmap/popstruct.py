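"""Population structure: kinship matrices, least-related subset selection, PCA.

Two relatedness estimators are provided: an IBS allele-sharing proportion
(used for pruning duplicates/close relatives before association) and a
centered/scaled genomic relationship matrix (GRM, used as the random-effect
covariance in the mixed model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray  # (n, n) symmetric
    mode: str  # "ibs" | "grm"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def kinship(gm: GenotypeMatrix, mode: str = "ibs") -> KinshipMatrix:
    """Pairwise relatedness.

    ``ibs``: mean over sites non-missing in both samples of ``(2 - |gi - gj|)/2``
    (1 for identical genotypes, 0 for opposite homozygotes).
    ``grm``: VanRaden-style centered/scaled cross-product,
    ``Z Z' / m`` with ``Z = (G - 2p)/sqrt(2 p (1-p))`` and missing calls
    imputed to the column mean.
    """
    calls = gm.calls.astype(np.float64)
    obs = gm.calls != MISSING
    if not obs.any(axis=1).all():
        bad = gm.samples.loc[~obs.any(axis=1), "sample_id"].iloc[0]
        raise ValueError(f"sample {bad} has no non-missing genotypes")
    if mode == "ibs":
        # sum |gi-gj| over shared sites decomposes into matrix products:
        # |a-b| = (a-b)^2 - 2*[one is 0 and the other 2]
        G = np.where(obs, calls, 0.0)
        G2 = G * G
        M = obs.astype(np.float64)
        n_shared = M @ M.T
        if (n_shared == 0).any():
            i, j = np.argwhere(n_shared == 0)[0]
            raise ValueError(
                "no overlapping non-missing sites for pair "
                f"({gm.sample_ids()[i]}, {gm.sample_ids()[j]})"
            )
        sq = G2 @ M.T + M @ G2.T - 2.0 * (G @ G.T)
        # indicators restricted to observed calls (MISSING is -1, not 0)
        is0 = ((gm.calls == 0)).astype(np.float64)
        is2 = ((gm.calls == 2)).astype(np.float64)
        extreme = is0 @ is2.T + is2 @ is0.T
        absdiff = sq - 2.0 * extreme
        K = (2.0 * n_shared - absdiff) / (2.0 * n_shared)
        K = np.clip(K, 0.0, 1.0)
    elif mode == "grm":
        p = gm.allele_freq()
        keep = np.isfinite(p) & (p > 0) & (p < 1)
        p = p[keep]
        X = calls[:, keep]
        ob = obs[:, keep]
        mean = 2.0 * p
        X = np.where(ob, X, mean)
        Z = (X - mean) / np.sqrt(2.0 * p * (1.0 - p))
        K = Z @ Z.T / Z.shape[1]
    else:
        raise ValueError(f"unknown kinship mode {mode!r}")
    K = (K + K.T) / 2.0
    return KinshipMatrix(gm.sample_ids(), K, mode)


def select_least_related(K: KinshipMatrix, max_kin: float) -> list[str]:
    """Greedy pruning until no retained off-diagonal kinship exceeds *max_kin*.

    Repeatedly drops the sample involved in the most above-threshold pairs
    (ties: largest mean kinship, then lexicographically smallest id).
    """
    V = K.values
    if max_kin >= np.min(np.diag(V)):
        raise ValueError(
            f"max_kin={max_kin} is not below the diagonal; nothing could ever be pruned"
        )
    ids = list(K.sample_ids)
    active = list(range(len(ids)))
    while True:
        sub = V[np.ix_(active, active)]
        over = (sub > max_kin) & ~np.eye(len(active), dtype=bool)
        counts = over.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        mean_kin = (sub.sum(axis=1) - np.diag(sub)) / max(len(active) - 1, 1)
        order = sorted(
            range(len(active)),
            key=lambda k: (-counts[k], -mean_kin[k], ids[active[k]]),
        )
        active.pop(order[0])
    return [ids[i] for i in active]


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n, n_components)
    eigenvalues: np.ndarray
    scaling: str = "eigenstrat"

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Principal components with the usual allele-frequency scaling.

    Genotypes are centered by ``2 p`` and scaled by ``sqrt(p (1-p))``;
    missing calls are imputed to the column mean before scaling; components
    come from the eigendecomposition of the sample covariance (via SVD).
    Monomorphic sites are removed first.
    """
    if gm.n_samples < 2:
        raise ValueError("pca requires at least 2 samples")
    p = gm.allele_freq()
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if keep.sum() < 2:
        raise ValueError("pca requires at least 2 polymorphic variants")
    p = p[keep]
    X = gm.calls[:, keep].astype(np.float64)
    ob = gm.calls[:, keep] != MISSING
    mean = 2.0 * p
    X = np.where(ob, X, mean)
    Z = (X - mean) / np.sqrt(p * (1.0 - p))
    Z = Z - Z.mean(axis=0)
    n_components = min(n_components, min(Z.shape) - 1) or 1
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (gm.n_samples - 1)
    scores = U * s
    return PCAResult(gm.sample_ids(), scores[:, :n_components], eigvals[:n_components])


def write_matrix_tsv(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")
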