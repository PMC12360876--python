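"""Dataset expansion: small labeled subset -> full-size pseudolabeled set.

The low-annotation protocol samples a fraction (typically 5/10/20%) of the
annotated training set, then generates augmented samples with a single
strategy until the expanded set regains the original training-set size.
Labeled sources are cycled round-robin so each contributes nearly equally;
unlabeled partners are drawn uniformly with replacement from the pool,
never pairing an image with itself. All pairing randomness is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .augment import MIXED_OPS
from .baseline import BASELINE_OPS, BaselineParams
from .types import (
    AugmentedSample,
    GrayImage,
    LabeledSample,
    MixParams,
    Strategy,
)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class ExpansionPlan:
    """One expansion experiment: a single strategy applied until
    ``target_size`` samples exist (subset included)."""

    strategy: Strategy
    target_size: int
    seed: int
    fraction: float = 0.05
    params: Union[MixParams, BaselineParams, None] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in (0, 1], got {self.fraction}")
        if self.target_size < 1:
            raise ValueError("target_size must be positive")
        if self.strategy not in MIXED_OPS and self.strategy not in BASELINE_OPS:
            raise ValueError(f"strategy {self.strategy} cannot be used for expansion")


def subset_size(full_size: int, fraction: float) -> int:
    """Half-up rounding of fraction * full_size (so 5% of 414 -> 21)."""
    return int(math.floor(fraction * full_size + 0.5))


def sample_subset(
    dataset: Sequence[LabeledSample], fraction: float, seed: int
) -> list[LabeledSample]:
    """Seeded simple random sample (without replacement) of a fraction.

    Samples are sorted by ``source_id`` before drawing, so the result does
    not depend on the caller's ordering.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    ordered = sorted(dataset, key=lambda s: s.source_id)
    k = subset_size(len(ordered), fraction)
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {len(ordered)} samples rounds to zero"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=k, replace=False)
    return [ordered[i] for i in sorted(idx)]


@dataclass(frozen=True)
class Pairing:
    """One planned augmented sample: which labeled/unlabeled sources to
    combine and the per-sample seed."""

    labeled_index: int
    unlabeled_index: Optional[int]
    sample_seed: int


def _make_pairings(
    subset: Sequence[LabeledSample],
    pool: Sequence[GrayImage],
    n_augmented: int,
    strategy: Strategy,
    seed: int,
) -> list[Pairing]:
    rng = np.random.default_rng(seed)
    sample_seeds = [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(max(n_augmented, 1))]
    pairings: list[Pairing] = []
    needs_pool = strategy in MIXED_OPS
    for i in range(n_augmented):
        li = i % len(subset)
        ui: Optional[int] = None
        if needs_pool:
            labeled_id = subset[li].source_id
            for _ in range(_MAX_REDRAWS):
                ui = int(rng.integers(0, len(pool)))
                if pool[ui].source_id is None or pool[ui].source_id != labeled_id:
                    break
            else:
                raise ValueError(
                    "could not draw an unlabeled partner distinct from the "
                    f"labeled source '{labeled_id}'"
                )
        pairings.append(Pairing(li, ui, sample_seeds[i]))
    return pairings


def _apply(
    subset: Sequence[LabeledSample],
    pool: Sequence[GrayImage],
    pairing: Pairing,
    strategy: Strategy,
    params: Union[MixParams, BaselineParams],
) -> AugmentedSample:
    labeled = subset[pairing.labeled_index]
    if strategy in MIXED_OPS:
        out = MIXED_OPS[strategy](labeled, pool[pairing.unlabeled_index], params)
        out.seed = pairing.sample_seed
        return out
    return BASELINE_OPS[strategy](labeled, pairing.sample_seed, params)


def expand_dataset(
    subset: Sequence[LabeledSample],
    pool: Sequence[GrayImage],
    plan: ExpansionPlan,
) -> tuple[list[LabeledSample], list[AugmentedSample]]:
    """Expand a labeled subset to ``plan.target_size`` samples.

    Returns the subset unchanged plus ``target_size - len(subset)``
    augmented samples generated with the plan's single strategy. Mixed
    strategies require a non-empty unlabeled pool.
    """
    if plan.target_size < len(subset):
        raise ValueError(
            f"target_size {plan.target_size} smaller than subset size {len(subset)}"
        )
    if plan.strategy in MIXED_OPS and len(pool) == 0:
        raise ValueError("mixed-sample expansion requires a non-empty unlabeled pool")
    if plan.params is None:
        params: Union[MixParams, BaselineParams] = (
            MixParams() if plan.strategy in MIXED_OPS else BaselineParams()
        )
    else:
        params = plan.params
    n_aug = plan.target_size - len(subset)
    pairings = _make_pairings(subset, pool, n_aug, plan.strategy, plan.seed)
    augmented = [_apply(subset, pool, p, plan.strategy, params) for p in pairings]
    return list(subset), augmented


def run_alpha_beta_sweep(
    subset: Sequence[LabeledSample],
    pool: Sequence[GrayImage],
    alphas: Sequence[float],
    seed: int,
    target_size: int,
    sigma: float = 5.0,
) -> dict[float, tuple[list[LabeledSample], list[AugmentedSample]]]:
    """PixMix expansion at several (alpha, beta=1-alpha) settings.

    All settings share one pairing seed, so the datasets differ only in the
    mixing weights — the per-pixel difference between two settings is
    exactly ``(alpha1 - alpha2) * (I_L - I_U)``.
    """
    if any(not 0.0 < a < 1.0 for a in alphas):
        raise ValueError("all alphas must lie strictly in (0, 1)")
    if len(pool) == 0:
        raise ValueError("the sweep requires a non-empty unlabeled pool")
    if target_size < len(subset):
        raise ValueError("target_size smaller than subset size")
    n_aug = target_size - len(subset)
    pairings = _make_pairings(subset, pool, n_aug, Strategy.PIXMIX, seed)
    results = {}
    for alpha in alphas:
        params = MixParams(alpha=alpha, beta=1.0 - alpha, sigma=sigma)
        augmented = [
            _apply(subset, pool, p, Strategy.PIXMIX, params) for p in pairings
        ]
        results[float(alpha)] = (list(subset), augmented)
    return results


def hidden_mask_pool(
    full_dataset: Sequence[LabeledSample], subset: Sequence[LabeledSample]
) -> list[GrayImage]:
    """Unlabeled pool built from the labeled images *not* in the subset,
    with their masks hidden — the fallback when no separate pool exists."""
    subset_ids = {s.source_id for s in subset}
    return [s.image for s in full_dataset if s.source_id not in subset_ids]
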