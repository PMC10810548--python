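"""Self-organizing map over bioassay activity profiles.

Compounds with similar activity profiles are hypothesised to share
targets or modes of action; the SOM groups profiles onto a grid of
units whose codebook vectors are trained by online competitive
learning with Euclidean distance. A compound's cluster is its
best-matching unit (BMU) after training; empty units are not clusters.

Training is the classic online Kohonen scheme: codebook initialised
from randomly sampled data rows; per presented row, the BMU and its
Gaussian grid neighbourhood move toward the row; learning rate and
neighbourhood radius decay linearly over all steps. Everything is a
deterministic function of the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .containers import ActivityMatrix, ClusterAssignment

logger = logging.getLogger(__name__)

DEFAULT_GRID = 12  # 12x12 = 144 units; a conventional square grid
DEFAULT_EPOCHS = 100
DEFAULT_LR_INITIAL = 0.05
DEFAULT_LR_FINAL = 0.01
DEFAULT_RADIUS_FINAL = 0.25


@dataclass
class SomModel:
    """Trained map: grid geometry plus per-unit codebook vectors.

    Unit indices are 0-based row-major over the grid; ``codebook`` has
    one row per unit, in curve-rank units, with one column per assay.
    """

    grid_rows: int
    grid_cols: int
    topology: str
    codebook: np.ndarray
    assay_ids: tuple[str, ...]
    training_params: dict

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def unit_positions(self) -> np.ndarray:
        """Grid-space coordinates of each unit (row-major order)."""
        rows, cols = np.divmod(np.arange(self.n_units), self.grid_cols)
        if self.topology == "hexagonal":
            # even-r offset coordinates: odd rows shifted half a unit
            x = cols + 0.5 * (rows % 2)
            y = rows * (np.sqrt(3.0) / 2.0)
            return np.column_stack([x, y]).astype(float)
        return np.column_stack([cols, rows]).astype(float)


def train_som(
    matrix: ActivityMatrix,
    grid_rows: int = DEFAULT_GRID,
    grid_cols: int = DEFAULT_GRID,
    topology: str = "rectangular",
    epochs: int = DEFAULT_EPOCHS,
    lr_initial: float = DEFAULT_LR_INITIAL,
    lr_final: float = DEFAULT_LR_FINAL,
    radius_initial: float | None = None,
    radius_final: float = DEFAULT_RADIUS_FINAL,
    seed: int = 0,
    max_unit_ratio: float = 1.0,
) -> SomModel:
    """Fit a SOM to the activity matrix by online training.

    radius_initial defaults to half the larger grid dimension. A grid
    with more than ``max_unit_ratio`` units per data row triggers a
    warning (such maps are mostly empty). Updates are convex
    (learning rate and Gaussian kernel are both <= 1), so codebook
    values never leave the per-assay range of the training data.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid must have at least one unit")
    if topology not in ("rectangular", "hexagonal"):
        raise ValueError(f"unknown topology {topology!r}")
    if epochs < 0:
        raise ValueError("epochs must be nonnegative")
    if not (lr_initial >= lr_final > 0):
        raise ValueError("need lr_initial >= lr_final > 0")
    if matrix.n_compounds == 0 or matrix.n_assays == 0:
        raise ValueError("cannot train on an empty activity matrix")

    n_units = grid_rows * grid_cols
    n = matrix.n_compounds
    if n_units > max_unit_ratio * n:
        warnings.warn(
            f"{n_units} SOM units for {n} compounds exceeds "
            f"{max_unit_ratio:g} units per row; many units will stay empty",
            stacklevel=2,
        )
    if radius_initial is None:
        radius_initial = max(grid_rows, grid_cols) / 2.0
    if radius_initial < radius_final:
        raise ValueError("radius_initial must be >= radius_final")

    rng = np.random.default_rng(seed)
    data = matrix.values
    init_idx = rng.choice(n, size=n_units, replace=n_units > n)
    codebook = data[init_idx].astype(float).copy()

    model = SomModel(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        topology=topology,
        codebook=codebook,
        assay_ids=matrix.assay_ids,
        training_params={
            "epochs": epochs,
            "lr_initial": lr_initial,
            "lr_final": lr_final,
            "radius_initial": radius_initial,
            "radius_final": radius_final,
            "seed": seed,
        },
    )
    if epochs == 0:
        return model

    positions = model.unit_positions()
    # pairwise squared grid distances between units, reused every step
    grid_sq = cdist(positions, positions, metric="sqeuclidean")

    total_steps = epochs * n
    step = 0
    denom = max(total_steps - 1, 1)
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / denom
            lr = lr_initial + (lr_final - lr_initial) * frac
            radius = radius_initial + (radius_final - radius_initial) * frac
            x = data[i]
            diff = x - codebook
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = np.exp(-grid_sq[bmu] / (2.0 * radius * radius))
            codebook += (lr * h)[:, None] * diff
            step += 1
    return model


def assign_bmu(model: SomModel, matrix: ActivityMatrix) -> ClusterAssignment:
    """Map each compound to its best-matching unit.

    Ties in Euclidean distance break toward the lowest unit index;
    units with no assigned compound yield no cluster label.
    """
    if tuple(matrix.assay_ids) != tuple(model.assay_ids):
        raise ValueError("assay list of matrix does not match the model codebook")
    dists = cdist(matrix.values, model.codebook)
    bmus = np.argmin(dists, axis=1)  # argmin takes the lowest index on ties
    return ClusterAssignment(
        {cid: int(b) for cid, b in zip(matrix.compound_ids, bmus)}
    )


def quantization_error(model: SomModel, matrix: ActivityMatrix) -> float:
    """Mean Euclidean distance from each compound to its BMU."""
    if matrix.n_compounds == 0:
        raise ValueError("empty activity matrix")
    if tuple(matrix.assay_ids) != tuple(model.assay_ids):
        raise ValueError("assay list of matrix does not match the model codebook")
    dists = cdist(matrix.values, model.codebook)
    return float(np.mean(dists.min(axis=1)))
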