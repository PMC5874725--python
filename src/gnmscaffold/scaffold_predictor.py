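"""Hot-residue influence spreading and the adjustable mode-count loop.

Hot residues are usually fewer than the contact + first-layer targets, so their
influence is spread to neighbours: sequentially along the chain (1D), within a
sphere around the Cα (3D), or both (combined).  The adjustable protocol then
tunes the number of fast modes per chain until the predicted fraction of the
chain falls inside a length-dependent band of expected target fractions,
starting from the top-decile mode count and moving one mode at a time; a single
direction reversal is allowed before the loop stops.

Length-dependent defaults (s = number of residues with a resolved Cα):

====================  =======================================
1D half-width          4 if s > 100 else 3
3D sphere cutoff       6 Å if s < 250 else 8 Å
too-many band edge     0.60 if s ≤ 300 else 0.50
too-few band edge      0.40 if s ≤ 500 else 0.20
====================  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .structure_io import ChainModel
from .gnm_core import (
    ModeSpectrum,
    fast_mode_profile,
    hot_residues,
    top_decile_mode_count,
    HOT_THRESHOLD,
)

__all__ = [
    "SpreadPolicy",
    "AdjustableConfig",
    "PredictionResult",
    "spread_1d",
    "spread_3d",
    "spread_combined",
    "adjustable_predict",
    "fixed_mode_predict",
    "STRATEGIES",
]

STRATEGIES = ("sequential_1d", "spatial_3d", "combined")


@dataclass(frozen=True)
class SpreadPolicy:
    """How hot-residue influence is spread, with length-derived parameters."""

    strategy: str
    seq_halfwidth: int
    spatial_cutoff: float

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @classmethod
    def for_length(
        cls,
        length: int,
        strategy: str = "combined",
        *,
        halfwidth_long: int = 4,
        halfwidth_short: int = 3,
        halfwidth_break: int = 100,
        cutoff_short: float = 6.0,
        cutoff_long: float = 8.0,
        cutoff_break: int = 250,
    ) -> "SpreadPolicy":
        return cls(
            strategy=strategy,
            seq_halfwidth=halfwidth_long if length > halfwidth_break else halfwidth_short,
            spatial_cutoff=cutoff_short if length < cutoff_break else cutoff_long,
        )


@dataclass(frozen=True)
class AdjustableConfig:
    """Band edges and loop guard of the adjustable protocol."""

    too_many: float
    too_few: float
    max_reversals: int = 1

    def __post_init__(self) -> None:
        if not self.too_few < self.too_many:
            raise ValueError("too_few must be < too_many")

    @classmethod
    def for_length(
        cls,
        length: int,
        *,
        too_many_short: float = 0.60,
        too_many_long: float = 0.50,
        too_many_break: int = 300,
        too_few_short: float = 0.40,
        too_few_long: float = 0.20,
        too_few_break: int = 500,
        max_reversals: int = 1,
    ) -> "AdjustableConfig":
        return cls(
            too_many=too_many_short if length <= too_many_break else too_many_long,
            too_few=too_few_short if length <= too_few_break else too_few_long,
            max_reversals=max_reversals,
        )


@dataclass
class PredictionResult:
    """Predicted scaffold residues plus the trace that produced them."""

    predicted: set[int]
    mode_count: int
    iterations: list[tuple[int, float]]
    strategy: str
    terminated_by: str  # in_band | reversal_limit | mode_bounds | fixed
    hot: set[int] = field(default_factory=set)

    @property
    def fraction(self) -> float:
        return self.iterations[-1][1]


def _ca_positions(chain: ChainModel) -> set[int]:
    return {int(i) for i in chain.ca_indices()}


def _check_hot(hot: Iterable[int], chain: ChainModel) -> None:
    n = chain.n_slots
    bad = [h for h in hot if not 0 <= h < n]
    if bad:
        raise ValueError(f"hot indices out of range: {bad}")


def spread_1d(hot: set[int], chain: ChainModel, policy: SpreadPolicy) -> set[int]:
    """Spread each hot residue to ±seq_halfwidth chain-list positions.

    Positions are slots in the ordered residue list, so residues missing from
    the model absorb window slots; only residues with a resolved Cα are
    returned.
    """
    _check_hot(hot, chain)
    w = policy.seq_halfwidth
    n = chain.n_slots
    out: set[int] = set()
    for h in hot:
        out.update(range(max(0, h - w), min(n, h + w + 1)))
    return out & _ca_positions(chain)


def spread_3d(hot: set[int], chain: ChainModel, policy: SpreadPolicy) -> set[int]:
    """All residues whose Cα lies within ``spatial_cutoff`` Å of a hot Cα.

    The hot residue itself is always included (distance 0).
    """
    _check_hot(hot, chain)
    if not hot:
        return set()
    idx = chain.ca_indices()
    coords = chain.ca_array()
    row_of = {int(i): r for r, i in enumerate(idx)}
    for h in hot:
        if h not in row_of:
            raise ValueError(f"hot residue {h} has no resolved Cα")
    centers = coords[[row_of[h] for h in sorted(hot)]]
    diff = coords[None, :, :] - centers[:, None, :]
    within = (diff ** 2).sum(axis=-1) <= policy.spatial_cutoff ** 2
    cols = np.nonzero(within.any(axis=0))[0]
    return {int(idx[c]) for c in cols}


def spread_combined(hot: set[int], chain: ChainModel, policy: SpreadPolicy) -> set[int]:
    """Union of the sequential and spatial spreads."""
    return spread_1d(hot, chain, policy) | spread_3d(hot, chain, policy)


_SPREADERS = {
    "sequential_1d": spread_1d,
    "spatial_3d": spread_3d,
    "combined": spread_combined,
}


def _predict_once(
    chain: ChainModel,
    spec: ModeSpectrum,
    m: int,
    policy: SpreadPolicy,
    hot_threshold: float,
) -> tuple[set[int], set[int]]:
    profile = fast_mode_profile(spec, m)
    hot = hot_residues(profile, hot_threshold)
    predicted = _SPREADERS[policy.strategy](hot, chain, policy)
    return predicted, hot


def _check_pair(chain: ChainModel, spec: ModeSpectrum) -> None:
    if spec.n != chain.length:
        raise ValueError(
            f"spectrum size {spec.n} does not match chain length {chain.length}"
        )


def fixed_mode_predict(
    chain: ChainModel,
    spec: ModeSpectrum,
    m: int,
    strategy: str = "combined",
    *,
    policy: Optional[SpreadPolicy] = None,
    hot_threshold: float = HOT_THRESHOLD,
) -> PredictionResult:
    """Single-pass prediction with a fixed number of fast modes.

    Baselines: m = 5 (five fastest modes) or m = top-decile count.
    """
    _check_pair(chain, spec)
    if not 1 <= m <= spec.n - 1:
        raise ValueError(f"mode count m={m} out of range [1, {spec.n - 1}]")
    if policy is None:
        policy = SpreadPolicy.for_length(chain.length, strategy)
    predicted, hot = _predict_once(chain, spec, m, policy, hot_threshold)
    fraction = len(predicted) / chain.length
    return PredictionResult(
        predicted=predicted,
        mode_count=m,
        iterations=[(m, fraction)],
        strategy=policy.strategy,
        terminated_by="fixed",
        hot=hot,
    )


def adjustable_predict(
    chain: ChainModel,
    spec: ModeSpectrum,
    strategy: str = "combined",
    config: Optional[AdjustableConfig] = None,
    *,
    policy: Optional[SpreadPolicy] = None,
    hot_threshold: float = HOT_THRESHOLD,
) -> PredictionResult:
    """Adjust the fast-mode count until the predicted fraction is in band.

    Starts from the top-decile mode count; too many predictions (fraction >
    too_many) decrease m by one, too few (fraction < too_few) increase it, and
    the whole profile→hot→spread pipeline is recomputed.  The loop stops when
    the fraction is in band, when the step direction would reverse past the
    allowed number of reversals, or when m would leave its valid range; the
    last computed prediction is returned with ``terminated_by`` flagging the
    stop reason.
    """
    _check_pair(chain, spec)
    if chain.length < 10:
        raise ValueError("adjustable protocol needs a chain of at least 10 residues")
    if config is None:
        config = AdjustableConfig.for_length(chain.length)
    if policy is None:
        policy = SpreadPolicy.for_length(chain.length, strategy)
    m_max = spec.n - spec.n_zero_modes()  # fastest modes must all be non-zero
    m_max = min(m_max, spec.n - 1)
    m = top_decile_mode_count(spec)
    m = max(1, min(m, m_max))

    iterations: list[tuple[int, float]] = []
    reversals = 0
    last_dir = 0
    while True:
        predicted, hot = _predict_once(chain, spec, m, policy, hot_threshold)
        fraction = len(predicted) / chain.length
        iterations.append((m, fraction))
        if config.too_few <= fraction <= config.too_many:
            terminated = "in_band"
            break
        step = -1 if fraction > config.too_many else 1
        if last_dir != 0 and step != last_dir:
            reversals += 1
            if reversals > config.max_reversals:
                terminated = "reversal_limit"
                break
        if not 1 <= m + step <= m_max:
            terminated = "mode_bounds"
            break
        last_dir = step
        m += step
    return PredictionResult(
        predicted=predicted,
        mode_count=iterations[-1][0],
        iterations=iterations,
        strategy=policy.strategy,
        terminated_by=terminated,
        hot=hot,
    )
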