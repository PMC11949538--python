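"""Genetic-ancestry assignment by Mahalanobis distance in PC space.

Each reference population contributes a sample mean and covariance over the
first 10 principal components; a subject is assigned to the population with
the smallest (squared) Mahalanobis distance from its centroid.  Squared
distances are monotone-equivalent to raw distances for the argmin.  Ties
break to the first population in the model's fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

N_PCS = 10
PC_COLS = [f"PC{i}" for i in range(1, N_PCS + 1)]


@dataclass
class AncestryModel:
    populations: list[str]
    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    _chol: dict = field(default_factory=dict, repr=False)

    def cho(self, pop: str):
        if pop not in self._chol:
            self._chol[pop] = cho_factor(self.covariances[pop], lower=True)
        return self._chol[pop]


def fit_reference_model(
    reference: pd.DataFrame,
    label_col: str = "population",
    ridge: float = 1e-6,
    cond_max: float = 1e8,
) -> AncestryModel:
    """Per-population mean and covariance of the 10 PCs.

    ``reference`` must carry PC1..PC10 and a label column.  Populations need
    more than 10 samples (covariance rank in 10 dimensions).  A covariance
    whose condition number exceeds ``cond_max`` is regularised by adding
    ``ridge * I`` until it is invertible.
    """
    pops = list(dict.fromkeys(reference[label_col]))  # stable first-seen order
    means, covs = {}, {}
    for pop in pops:
        x = reference.loc[reference[label_col] == pop, PC_COLS].to_numpy(dtype=float)
        if len(x) <= N_PCS:
            raise ValueError(
                f"population {pop!r} has {len(x)} samples; > {N_PCS} required for a "
                f"full-rank {N_PCS}x{N_PCS} covariance"
            )
        means[pop] = x.mean(axis=0)
        c = np.cov(x, rowvar=False)
        while np.linalg.cond(c) > cond_max:
            c = c + ridge * np.eye(N_PCS)
        covs[pop] = c
    return AncestryModel(populations=pops, means=means, covariances=covs)


def assign_ancestry(pcs: pd.DataFrame, model: AncestryModel) -> pd.DataFrame:
    """Assign every row of ``pcs`` (index = subject id, columns PC1..PC10).

    Returns a DataFrame with the winning label and the squared Mahalanobis
    distance to every population (columns ``d_<pop>``).
    """
    missing = [c for c in PC_COLS if c not in pcs.columns]
    if missing:
        raise ValueError(f"PC table lacks columns {missing}")
    x = pcs[PC_COLS].to_numpy(dtype=float)
    d2 = np.empty((len(x), len(model.populations)))
    for j, pop in enumerate(model.populations):
        diff = x - model.means[pop]
        sol = cho_solve(model.cho(pop), diff.T)
        d2[:, j] = np.einsum("ij,ji->i", diff, sol)
    best = np.argmin(d2, axis=1)  # argmin takes the first minimum: fixed-order ties
    out = pd.DataFrame(
        {"label": [model.populations[j] for j in best]}, index=pcs.index
    )
    for j, pop in enumerate(model.populations):
        out[f"d_{pop}"] = d2[:, j]
    return out


def read_eigenvec(path, n_pcs: int = N_PCS, label_col: bool = False) -> pd.DataFrame:
    """Read a PLINK-style .eigenvec whitespace table (FID IID PC1..PCk
    [label]).  Returns a DataFrame indexed by IID."""
    names = ["FID", "IID"] + [f"PC{i}" for i in range(1, n_pcs + 1)]
    if label_col:
        names.append("population")
    df = pd.read_csv(path, sep=r"\s+", header=None, names=names, comment="#")
    return df.set_index("IID")


def write_eigenvec(df: pd.DataFrame, path, label_col: str | None = None) -> None:
    """Write a PLINK-style .eigenvec table (FID = IID unless present)."""
    out = df.copy()
    out.insert(0, "IID", df.index.astype(str))
    if "FID" not in out.columns:
        out.insert(0, "FID", out["IID"])
    keep = ["FID", "IID"] + PC_COLS + ([label_col] if label_col else [])
    out[keep].to_csv(path, sep=" ", header=False, index=False)
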