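"""Batch self-organizing map over scaled cytometry events.

A SOM quantizes the event cloud into a small grid of *nodes* (codebook
vectors) while preserving topology: nearby nodes on the grid are nearby
in marker space.  With a 10 x 10 grid this yields the 100 unsupervised
subsets that a minimal-spanning-tree display then organizes along
differentiation paths.

:class:`BatchSOM` follows the scikit-learn estimator contract (``fit``,
``predict``, ``get_params``/``set_params``, trailing-underscore fitted
attributes) so it composes with sklearn pipelines and model selection.

Training is the deterministic batch formulation: the codebook is
initialized by seeded sampling of events; each epoch assigns every event
to its best-matching unit (BMU) and replaces every codebook vector with
the Gaussian-neighborhood-weighted mean of the events assigned around it
on the grid.  The neighborhood radius shrinks linearly across epochs; a
short radius-zero refinement phase (plain Lloyd updates) then sharpens
node positions so small, well-separated populations keep dedicated
nodes.  Given the same inputs and seed the result is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin

from .events import EventMatrix
from .exceptions import ConfigurationError, ValidationError
from .panel import ScalingStats

logger = logging.getLogger(__name__)


def _pairwise_sq_dists(x: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (n_events, n_nodes)."""
    # ||x||^2 - 2 x.c + ||c||^2 ; clip tiny negatives from cancellation
    d = (
        (x * x).sum(axis=1)[:, None]
        - 2.0 * x @ codebook.T
        + (codebook * codebook).sum(axis=1)[None, :]
    )
    return np.maximum(d, 0.0)


class BatchSOM(ClusterMixin, BaseEstimator):
    """Batch-trained Kohonen map on a rectangular grid.

    Parameters
    ----------
    grid_rows, grid_cols
        Grid dimensions; the default 10 x 10 yields 100 nodes.
    n_epochs
        Neighborhood-decay epochs.
    initial_radius
        Starting neighborhood radius in grid (Chebyshev) units; default
        half the grid diagonal.
    final_radius
        Radius reached at the last decay epoch.
    refine_epochs
        Additional radius-zero (Lloyd) epochs sharpening the quantization.
    recycle_threshold
        During refinement, an empty node may be re-seeded onto the event
        worst served by the current codebook, provided that event lies
        further than ``recycle_threshold`` times the RMS quantization
        distance — the standard empty-cluster handling that gives small,
        well-separated populations (the rare progenitor subsets) nodes
        of their own while leaving most empty nodes in place as
        interpolating positions between populations.  ``None`` disables
        recycling.
    random_state
        Seed for codebook initialization; required for reproducibility.

    Attributes
    ----------
    codebook_ : ndarray of shape (n_nodes, n_features)
    quantization_errors_ : list of float
        Mean squared BMU distance at the start of each epoch (plus one
        final entry); non-increasing across the radius-zero phase.
    labels_ : ndarray, BMU of each training event
    """

    def __init__(
        self,
        grid_rows: int = 10,
        grid_cols: int = 10,
        n_epochs: int = 10,
        initial_radius: float | None = None,
        final_radius: float = 1.0,
        refine_epochs: int = 3,
        recycle_threshold: float | None = 4.0,
        max_recycles_per_epoch: int = 2,
        random_state: int | None = None,
    ):
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.n_epochs = n_epochs
        self.initial_radius = initial_radius
        self.final_radius = final_radius
        self.refine_epochs = refine_epochs
        self.recycle_threshold = recycle_threshold
        self.max_recycles_per_epoch = max_recycles_per_epoch
        self.random_state = random_state

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(self.grid_rows) * int(self.grid_cols)

    def _grid_distances(self) -> np.ndarray:
        """Chebyshev distances between grid positions (row-major node order)."""
        rows, cols = np.divmod(np.arange(self.n_nodes), self.grid_cols)
        dr = np.abs(rows[:, None] - rows[None, :])
        dc = np.abs(cols[:, None] - cols[None, :])
        return np.maximum(dr, dc).astype(float)

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValidationError("training data must be a non-empty 2-D array")
        if not np.isfinite(x).all():
            raise ValidationError("training data contain non-finite values")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid dimensions must be positive")
        n, n_nodes = x.shape[0], self.n_nodes
        if n < n_nodes:
            logger.warning(
                "fewer events (%d) than nodes (%d); codebook will repeat events",
                n,
                n_nodes,
            )
        rng = np.random.default_rng(self.random_state)
        idx = rng.choice(n, size=n_nodes, replace=n < n_nodes)
        codebook = x[idx].copy()

        grid_d = self._grid_distances()
        diag = max(self.grid_rows, self.grid_cols) - 1
        r0 = self.initial_radius if self.initial_radius is not None else max(diag / 2.0, 1.0)
        rf = self.final_radius
        qe: list[float] = []

        for epoch in range(int(self.n_epochs) + int(self.refine_epochs)):
            d2 = _pairwise_sq_dists(x, codebook)
            bmu = d2.argmin(axis=1)
            qe.append(float(d2[np.arange(n), bmu].mean()))
            counts = np.bincount(bmu, minlength=n_nodes).astype(float)
            sums = np.zeros_like(codebook)
            np.add.at(sums, bmu, x)
            if epoch < self.n_epochs:
                if self.n_epochs > 1:
                    r = r0 + (rf - r0) * epoch / (self.n_epochs - 1)
                else:
                    r = rf
                h = np.exp(-(grid_d**2) / (2.0 * r * r))
                wsum = h @ sums
                wcnt = h @ counts
                ok = wcnt > 0
                codebook[ok] = wsum[ok] / wcnt[ok, None]
            else:
                # refinement: plain Lloyd update; empty nodes stay put as
                # interpolating positions unless an event is quantized
                # badly enough to justify recycling one onto it
                ok = counts > 0
                codebook[ok] = sums[ok] / counts[ok, None]
                empty_ids = np.flatnonzero(~ok)
                if empty_ids.size and self.recycle_threshold is not None:
                    d = np.sqrt(d2[np.arange(n), bmu])
                    rms = np.sqrt(float((d**2).mean()))
                    recycled = 0
                    for node in empty_ids:
                        if recycled >= self.max_recycles_per_epoch:
                            break
                        i = int(d.argmax())
                        if d[i] <= self.recycle_threshold * rms:
                            break
                        codebook[node] = x[i]
                        # events now better served by the new node no
                        # longer count as badly quantized
                        d_new = np.sqrt(
                            ((x - x[i]) ** 2).sum(axis=1)
                        )
                        d = np.minimum(d, d_new)
                        recycled += 1

        d2 = _pairwise_sq_dists(x, codebook)
        self.labels_ = d2.argmin(axis=1)
        qe.append(float(d2[np.arange(n), self.labels_].mean()))
        self.codebook_ = codebook
        self.quantization_errors_ = qe
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Best-matching unit of each event (ties go to the lowest node id)."""
        if not hasattr(self, "codebook_"):
            raise ConfigurationError("BatchSOM instance is not fitted yet")
        x = np.asarray(X, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.codebook_.shape[1]:
            raise ConfigurationError(
                f"expected {self.codebook_.shape[1]} features, got {x.shape}"
            )
        # argmin returns the first minimum -> lowest node id on ties
        return _pairwise_sq_dists(x, self.codebook_).argmin(axis=1)

    def transform(self, X) -> np.ndarray:
        """Distances of events to every codebook vector."""
        if not hasattr(self, "codebook_"):
            raise ConfigurationError("BatchSOM instance is not fitted yet")
        return np.sqrt(_pairwise_sq_dists(np.asarray(X, dtype=float), self.codebook_))


# ----------------------------------------------------------------------
# Frozen model artifact + functional wrappers


@dataclass
class SOMModel:
    """Trained SOM plus everything needed to map new samples reproducibly."""

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray
    scaling: ScalingStats | None
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.grid_rows * self.grid_cols:
            raise ConfigurationError("codebook row count does not match grid size")
        if not np.isfinite(self.codebook).all():
            raise ConfigurationError("codebook contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.codebook.shape[0]

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(self.n_nodes)


def train_som(
    events: EventMatrix,
    grid: tuple[int, int] = (10, 10),
    params: dict | None = None,
    seed: int | None = 0,
    scaling: ScalingStats | None = None,
) -> SOMModel:
    """Train a batch SOM on scaled events; thin wrapper over :class:`BatchSOM`.

    ``scaling`` is the frozen statistics used to produce the scaled
    events; stored in the model so new samples can be mapped in the same
    coordinate system.  When omitted, identity statistics recording only
    the channel order are stored.
    """
    if events.state != "scaled":
        raise ConfigurationError(f"train_som expects scaled events, got {events.state}")
    if events.n_events == 0:
        raise ValidationError("cannot train a SOM on an empty event set")
    params = dict(params or {})
    som = BatchSOM(grid_rows=grid[0], grid_cols=grid[1], random_state=seed, **params)
    som.fit(events.values)
    meta = {
        "seed": seed,
        "n_epochs": som.n_epochs,
        "refine_epochs": som.refine_epochs,
        "initial_radius": som.initial_radius,
        "final_radius": som.final_radius,
        "n_training_events": events.n_events,
        "quantization_errors": som.quantization_errors_,
    }
    if scaling is None:
        scaling = ScalingStats(
            channels=events.display_names(),
            location=np.zeros(events.n_channels),
            spread=np.ones(events.n_channels),
        )
    return SOMModel(
        grid_rows=grid[0],
        grid_cols=grid[1],
        codebook=som.codebook_,
        scaling=scaling,
        training_meta=meta,
    )


def assign_bmu(events: EventMatrix, model: SOMModel) -> np.ndarray:
    """Node id of the nearest codebook vector for each event.

    Ties are broken toward the lowest node id.  Channel order must match
    the model's scaling channels.
    """
    if events.state != "scaled":
        raise ConfigurationError(f"assign_bmu expects scaled events, got {events.state}")
    if model.scaling is not None:
        names = events.display_names()
        if list(model.scaling.channels) != names:
            raise ConfigurationError(
                f"event channels {names} do not match model channels "
                f"{list(model.scaling.channels)}"
            )
    if events.values.shape[1] != model.codebook.shape[1]:
        raise ConfigurationError("event dimensionality does not match codebook")
    return _pairwise_sq_dists(events.values, model.codebook).argmin(axis=1)


def metacluster(model: SOMModel, k: int) -> dict[int, int]:
    """Group nodes into ``k`` metaclusters by average-linkage clustering.

    An aid for display; population assignment proper goes through the
    phenotype rules in :mod:`marrowmap.annotate`.
    """
    n = model.n_nodes
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return {i: i for i in range(n)}
    if n == 1:
        return {0: 0}
    z = linkage(model.codebook, method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return {i: int(lbl) - 1 for i, lbl in enumerate(labels)}
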