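"""Estimator-style front end over the pool/uncertainty machinery.

`DaugsSegmenter` follows scikit-learn conventions (``fit`` / ``predict`` /
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) so it slots into sklearn tooling, while delegating the actual
work to the module-level operations.  ``X`` is a list of preprocessed
:class:`~daugs.core.PerfusionSeries` and ``y`` a parallel list of
:class:`~daugs.core.LabelMask`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .augment import AugmentPolicy
from .core import LabelMask, MYOCARDIUM, PerfusionSeries
from .evaluate import dice
from .patches import build_grid
from .pool import TrainConfig, build_pool, established_select, segment
from .uncertainty import SegmentationSolution, compute_umap, compute_upp, \
    daugs_select

__all__ = ["DaugsSegmenter"]


class DaugsSegmenter(BaseEstimator):
    """Pool-based sliding-patch segmenter with uncertainty-guided selection.

    Parameters mirror :class:`~daugs.pool.TrainConfig`; defaults are the
    desk-scale profile (32-px patches on 64-px series, 2 runs x 3
    checkpoints).  ``method`` chooses the test-time regime: ``"daugs"``
    (per-case minimal-Upp member) or ``"established"`` (single
    best-on-validation member).

    Attributes
    ----------
    pool_ : ModelPool
        Gated checkpoints from all training runs.
    grid_ : PatchGrid
        Inference sliding-window grid.
    best_member_ : PoolMember
        The established-regime (best-on-validation) member.
    """

    def __init__(self, n_runs=2, checkpoints_per_run=3, dice_gate=0.87,
                 epochs=24, learning_rate=3e-3, batch_size=16, width=8,
                 patch_size=32, train_stride=16, infer_stride=8,
                 augment="default", method="daugs", selection_metric="upp",
                 validation_fraction=0.25, random_state=0):
        self.n_runs = n_runs
        self.checkpoints_per_run = checkpoints_per_run
        self.dice_gate = dice_gate
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.width = width
        self.patch_size = patch_size
        self.train_stride = train_stride
        self.infer_stride = infer_stride
        self.augment = augment
        self.method = method
        self.selection_metric = selection_metric
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        augment = AugmentPolicy() if self.augment == "default" else self.augment
        return TrainConfig(
            n_runs=self.n_runs, checkpoints_per_run=self.checkpoints_per_run,
            dice_gate=self.dice_gate, epochs=self.epochs,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            width=self.width, patch_size=self.patch_size,
            train_stride=self.train_stride, infer_stride=self.infer_stride,
            augment=augment, base_seed=self.random_state,
        )

    def fit(self, X: list[PerfusionSeries], y: list[LabelMask]):
        """Train the pool on (series, mask) pairs.

        An internal validation split (``validation_fraction`` of the pairs,
        chosen by a seeded shuffle) drives checkpoint gating and the
        established-regime selection.
        """
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if len(X) < 2:
            raise ValueError("need at least 2 series to split train/validation")
        pairs = list(zip(X, y))
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(pairs))
        n_val = max(1, int(round(self.validation_fraction * len(pairs))))
        val = [pairs[i] for i in order[:n_val]]
        train = [pairs[i] for i in order[n_val:]]
        if not train:
            raise ValueError("validation_fraction leaves no training series")

        self.pool_ = build_pool(train, val, self._train_config())
        h, w, _ = X[0].shape
        self.grid_ = build_grid((h, w), self.patch_size, self.infer_stride)
        self.best_member_ = established_select(self.pool_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "pool_"):
            raise RuntimeError("this DaugsSegmenter instance is not fitted yet")

    def predict_solution(self, series: PerfusionSeries) -> SegmentationSolution:
        """Full solution (mask, probabilities, U-map, Upp) for one series."""
        self._check_fitted()
        if self.method == "daugs":
            return daugs_select(self.pool_, series, self.grid_,
                                selection_metric=self.selection_metric)
        if self.method == "established":
            m = self.best_member_
            probs, stack, mask = segment(m.model, series, self.grid_)
            umap = compute_umap(stack)
            return SegmentationSolution(
                mask=mask, probs=probs, umap=umap,
                upp=compute_upp(umap, mask), member_id=m.member_id,
            )
        raise ValueError(f"unknown method {self.method!r}")

    def predict(self, X: list[PerfusionSeries]) -> list[LabelMask]:
        """Predicted 3-class masks for a list of preprocessed series."""
        return [self.predict_solution(s).mask for s in X]

    def score(self, X: list[PerfusionSeries], y: list[LabelMask]) -> float:
        """Mean myocardium Dice over the given series."""
        preds = self.predict(X)
        return float(np.mean([dice(p, t, MYOCARDIUM) for p, t in zip(preds, y)]))
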