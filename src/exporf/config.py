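"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass


from .exceptions import ParameterError
from .forest import RFHyperParams

__all__ = ["RunConfig"]

DEFAULT_Q_LADDER = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 16, 24, 32, 48, 64, 96)


@dataclass
class RunConfig:
    """Everything that governs one pipeline run.

    ``tuning_grid`` of None means the default grid built from the feature
    count at run time; ``q_grid`` of None means the default ladder clipped
    to the feature count. ``importance_on`` is "train" (ranking computed on
    the training split only, protecting the held-out AUC) or "full"
    (ranking fit on the entire dataset, with a logged leakage warning).
    """

    test_fraction: float = 0.2
    cv_folds: int = 5
    tuning_grid: tuple[RFHyperParams, ...] | None = None
    q_grid: tuple[int, ...] | None = None
    flattening_epsilon: float = 0.005
    pdp_grid_size: int = 50
    ale_bins: int = 20
    percentile_clip: tuple[float, float] = (0.05, 0.95)
    calibration_bins: int = 10
    ci_level: float = 0.95
    importance_on: str = "train"
    importance_repeats: int = 1
    run_ablation: bool = True
    ablation_retune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ParameterError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        lo, hi = self.percentile_clip
        if not 0 <= lo < hi <= 1:
            raise ParameterError("percentile_clip must satisfy 0 <= low < high <= 1")
        if self.importance_on not in ("train", "full"):
            raise ParameterError("importance_on must be 'train' or 'full'")
        if self.flattening_epsilon < 0:
            raise ParameterError("flattening_epsilon must be >= 0")

    def resolved_q_grid(self, p: int) -> tuple[int, ...]:
        grid = self.q_grid if self.q_grid is not None else DEFAULT_Q_LADDER
        out = sorted({q for q in grid if 1 <= q <= p})
        if self.q_grid is None and p not in out:
            out.append(p)
        return tuple(sorted(out))

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.tuning_grid is not None:
            d["tuning_grid"] = [asdict(g) for g in self.tuning_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        grid = d.get("tuning_grid")
        if grid is not None:
            d["tuning_grid"] = tuple(RFHyperParams(**g) for g in grid)
        if d.get("q_grid") is not None:
            d["q_grid"] = tuple(int(q) for q in d["q_grid"])
        if d.get("percentile_clip") is not None:
            d["percentile_clip"] = tuple(d["percentile_clip"])
        return cls(**d)
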