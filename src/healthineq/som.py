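"""2x2 self-organizing map for socioeconomic grouping.

Respondents are clustered on three standardized SES features — income,
expenditure and the household-facilities score (100 points per facility,
a no-op after z-scoring) — with a 2x2 Kohonen map: four prototype
("codebook") vectors on a square grid, trained by sequential competitive
learning.  The two codebook vectors farthest apart in feature space define
the low- and high-SES "homogeneous groups"; respondents mapped to the other
two neurons belong to neither group.

Neuron numbering follows the bottom-row-left-first convention: 1 and 2 are
the bottom row (left to right), 3 and 4 the top row.

Only the 2x2 square grid is supported: two groups are wanted, and the tiny
grid keeps training exact and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SES_FEATURES = ("z_income", "z_expenditure", "z_facilities")

# grid coordinates (col, row) of neurons 1..4
_GRID = np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)])
_GRID_D2 = ((_GRID[:, None, :] - _GRID[None, :, :]) ** 2).sum(-1)

DEGENERACY_THRESHOLD = 1e-6


class DegenerateSOMError(RuntimeError):
    """All codebook vectors collapsed; grouping is not meaningful."""


def build_ses_features(records: pd.DataFrame) -> pd.DataFrame:
    """Z-scored SES features (income, expenditure, facilities) per record.

    Facilities are scored as count*100 before standardization; the scaling
    is affine so the z-scores are unchanged by it.  Uses population SD.
    Raises on zero-variance features, which cannot be standardized.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to standardize SES features")
    raw = pd.DataFrame(
        {
            "z_income": records["income"].to_numpy(dtype=float),
            "z_expenditure": records["expenditure"].to_numpy(dtype=float),
            "z_facilities": records["facilities_count"].to_numpy(dtype=float) * 100.0,
        },
        index=records.index,
    )
    for col in raw.columns:
        sd = raw[col].std(ddof=0)
        if sd == 0:
            raise ValueError(f"SES feature {col!r} has zero variance; cannot standardize")
        raw[col] = (raw[col] - raw[col].mean()) / sd
    return raw


def _select_extreme_pair(dist: np.ndarray) -> tuple[int, int]:
    """Most-distant neuron pair (1-based), lowest-index pair on exact ties."""
    best = (1, 2)
    best_d = -np.inf
    for i in range(4):
        for j in range(i + 1, 4):
            if dist[i, j] > best_d:
                best_d = dist[i, j]
                best = (i + 1, j + 1)
    return best


@dataclass
class SOMResults:
    """Trained 2x2 map: codebook, distances, extreme pair and assignments.

    ``assignment`` gives each record's best-matching neuron (1-4) in the
    original row order; ``low_neuron``/``high_neuron`` are the extreme-pair
    members ordered by their members' mean composite SES (NaN-mean composite
    of the three z-features).  ``degenerate`` is set when the maximum
    codebook distance falls below the degeneracy threshold, in which case
    grouping is refused.
    """

    codebook: np.ndarray
    distance_matrix: np.ndarray
    extreme_pair: tuple[int, int]
    assignment: np.ndarray
    degenerate: bool
    low_neuron: int | None
    high_neuron: int | None
    seed: int
    epochs: int
    schedule: dict = field(default_factory=dict)

    def neuron_sizes(self) -> dict[int, int]:
        return {k: int((self.assignment == k).sum()) for k in (1, 2, 3, 4)}

    def group_labels(self) -> np.ndarray:
        """Per-record label in {'low', 'high', 'none'}."""
        if self.degenerate:
            raise DegenerateSOMError(
                "SOM is degenerate (codebook collapsed); skip grouping"
            )
        labels = np.full(self.assignment.shape, "none", dtype=object)
        labels[self.assignment == self.low_neuron] = "low"
        labels[self.assignment == self.high_neuron] = "high"
        return labels

    def summary(self) -> str:
        sizes = self.neuron_sizes()
        lines = [
            "2x2 Self-Organizing Map",
            "=======================",
            f"seed: {self.seed}   epochs: {self.epochs}   schedule: {self.schedule}",
            f"neuron sizes: {sizes}",
            "codebook (neurons 1-4 x features z_income, z_expenditure, z_facilities):",
            np.array2string(self.codebook, precision=4),
            "inter-neuron distances:",
            np.array2string(self.distance_matrix, precision=4),
            f"extreme pair: {self.extreme_pair}   "
            f"low-SES neuron: {self.low_neuron}   high-SES neuron: {self.high_neuron}",
        ]
        if self.degenerate:
            lines.append("WARNING: degenerate map (codebook collapsed)")
        return "\n".join(lines)


class SESSelfOrganizingMap:
    """Sequential-Kohonen 2x2 map over standardized SES features.

    Parameters
    ----------
    features : DataFrame with columns z_income, z_expenditure, z_facilities
        Standardized features from :func:`build_ses_features`.
    epochs : int
        Full passes over the data (default 500).
    seed : int
        Mandatory for reproducibility: drives codebook initialization (four
        records sampled from the data) and per-epoch presentation order.
    record_ids : array-like, optional
        Stable keys; when given, the presentation order is derived from the
        id-sorted data so training is invariant to row permutation.
    lr0, lr1 : initial / final learning rate (linear decay, default 0.5→0.01).
    sigma0, sigma1 : initial / final Gaussian neighborhood radius in grid
        units (default 1→0.01).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        *,
        epochs: int = 500,
        seed: int = 0,
        record_ids=None,
        lr0: float = 0.5,
        lr1: float = 0.01,
        sigma0: float = 1.0,
        sigma1: float = 0.01,
    ):
        X = features[list(SES_FEATURES)].to_numpy(dtype=float)
        if X.shape[0] < 4:
            raise ValueError(f"need at least 4 records to train a 2x2 map, got {X.shape[0]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in SES features")
        self.X = X
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.lr0, self.lr1 = float(lr0), float(lr1)
        self.sigma0, self.sigma1 = float(sigma0), float(sigma1)
        if record_ids is not None:
            ids = np.asarray(record_ids)
            if ids.size != X.shape[0]:
                raise ValueError("record_ids length must match features")
            self._order = np.argsort(ids, kind="stable")
        else:
            self._order = np.arange(X.shape[0])

    def fit(self) -> SOMResults:
        rng = np.random.default_rng(self.seed)
        Xs = self.X[self._order]
        n = Xs.shape[0]
        W = Xs[rng.choice(n, size=4, replace=False)].astype(float).copy()

        total = max(self.epochs * n - 1, 1)
        t = 0
        for _ in range(self.epochs):
            for i in rng.permutation(n):
                x = Xs[i]
                frac = t / total
                eta = self.lr0 + (self.lr1 - self.lr0) * frac
                sig = self.sigma0 + (self.sigma1 - self.sigma0) * frac
                diff = W - x
                bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                theta = np.exp(-_GRID_D2[bmu] / (2.0 * sig * sig))
                W -= (eta * theta)[:, None] * diff
                t += 1

        dist = np.sqrt(((W[:, None, :] - W[None, :, :]) ** 2).sum(-1))
        pair = _select_extreme_pair(dist)
        degenerate = float(dist.max()) < DEGENERACY_THRESHOLD

        d_all = ((self.X[:, None, :] - W[None, :, :]) ** 2).sum(-1)
        assignment = d_all.argmin(axis=1) + 1

        low = high = None
        if not degenerate:
            composite = self.X.mean(axis=1)
            means = {}
            for k in pair:
                members = composite[assignment == k]
                means[k] = members.mean() if members.size else np.inf
            low, high = sorted(pair, key=lambda k: means[k])
        return SOMResults(
            codebook=W,
            distance_matrix=dist,
            extreme_pair=pair,
            assignment=assignment,
            degenerate=degenerate,
            low_neuron=low,
            high_neuron=high,
            seed=self.seed,
            epochs=self.epochs,
            schedule={
                "lr": (self.lr0, self.lr1),
                "sigma": (self.sigma0, self.sigma1),
                "neighborhood": "gaussian",
                "decay": "linear",
            },
        )


def train_som(
    features: pd.DataFrame, epochs: int = 500, seed: int = 0, **kwargs
) -> SOMResults:
    """Train the 2x2 map; functional convenience form."""
    return SESSelfOrganizingMap(features, epochs=epochs, seed=seed, **kwargs).fit()


def identify_extreme_groups(model: SOMResults, records: pd.DataFrame):
    """Respondent id sets of the low- and high-SES extreme neurons.

    Records assigned to the two non-extreme neurons belong to neither group.
    Raises :class:`DegenerateSOMError` for a collapsed map.
    """
    if model.degenerate:
        raise DegenerateSOMError("SOM is degenerate (codebook collapsed); skip grouping")
    ids = records["id"].to_numpy() if "id" in records.columns else records.index.to_numpy()
    low_ids = ids[model.assignment == model.low_neuron]
    high_ids = ids[model.assignment == model.high_neuron]
    return low_ids, high_ids
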